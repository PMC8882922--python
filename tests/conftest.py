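import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the bruteforce oracle helper

from gensor.model import (
    Dataset,
    CompoundOntology,
    GeneProduct,
    Reaction,
    ReactionSet,
    RegulatoryInteraction,
    RegulatoryNetwork,
    TFConformation,
)
from gensor.synthetic import GeneratorConfig, build_dataset, make_paper_fixtures

#: Planted-category mix used across tests: all six categories present.
PLANTED_COUNTS = {
    "DIRECT": 10,
    "CLASS": 3,
    "CASCADE_DOWN": 2,
    "CASCADE_UP": 2,
    "ENZYMATIC_TF": 1,
    "NONE": 2,
}


@pytest.fixture(scope="session")
def fixture_dataset() -> Dataset:
    return make_paper_fixtures()


@pytest.fixture(scope="session")
def planted():
    """One generated 20-TF dataset covering all six categories."""
    config = GeneratorConfig(n_tfs=20, category_counts=PLANTED_COUNTS)
    return build_dataset(config, seed=11)


def random_dataset(rng: random.Random) -> Dataset:
    """A small random (not planted) dataset for oracle-equivalence checks.

    Structure is arbitrary: random ontology DAG, random regulons, random
    catalysts including TFs themselves and effector-binding rows. At most
    a few dozen reactions, so exhaustive search stays instant.
    """
    compounds = [f"c{i}" for i in range(rng.randint(6, 14))]
    edges = [
        (compounds[i], compounds[j])
        for i in range(len(compounds))
        for j in range(i + 1, len(compounds))
        if rng.random() < 0.12
    ]
    tfs = [f"T{i}" for i in range(rng.randint(2, 5))]
    plain_genes = [f"g{i}" for i in range(rng.randint(3, 8))]
    tf_genes = {tf: f"gene_{tf}" for tf in tfs if rng.random() < 0.5}
    genes = plain_genes + list(tf_genes.values())

    products = {}
    enzymes = []
    for i, gene in enumerate(plain_genes):
        if rng.random() < 0.8:
            pid = f"P{i}"
            products[pid] = GeneProduct(pid, (gene,), "enzyme")
            enzymes.append(pid)
    for tf, gene in tf_genes.items():
        products[tf] = GeneProduct(tf, (gene,), "regulator")

    interactions = []
    for tf in tfs:
        for gene in rng.sample(genes, k=min(len(genes), rng.randint(1, 4))):
            interactions.append(
                RegulatoryInteraction(
                    tf, gene, rng.choice(("activation", "repression", "dual"))
                )
            )

    reactions = []
    for i in range(rng.randint(3, 14)):
        catalyst_pool = enzymes + tfs if enzymes else tfs
        catalyst = rng.choice(catalyst_pool + [None])
        if catalyst in tfs and rng.random() < 0.3:
            rxn_type = "tf_effector_binding"
        else:
            rxn_type = rng.choice(("enzymatic", "enzymatic", "transport"))
        reactants = tuple(rng.sample(compounds, k=rng.randint(1, 2)))
        prods = tuple(rng.sample(compounds, k=rng.randint(1, 2)))
        if rxn_type == "transport":
            prods = reactants
        reactions.append(
            Reaction(
                f"r{i}",
                reactants,
                prods,
                catalyst,
                rxn_type,
                reversible=rng.random() < 0.3,
            )
        )

    conformations = []
    for tf in tfs:
        if rng.random() < 0.2:
            conformations.append(TFConformation(tf, "apo", frozenset(), "active"))
        else:
            effs = frozenset(rng.sample(compounds, k=rng.randint(1, 2)))
            conformations.append(TFConformation(tf, "holo", effs, "active"))
            conformations.append(TFConformation(tf, "apo", frozenset(), "inactive"))

    dataset = Dataset(
        network=RegulatoryNetwork(interactions),
        conformations=tuple(conformations),
        products=products,
        reactions=ReactionSet(reactions),
        ontology=CompoundOntology(edges),
    )
    dataset.validate()
    return dataset
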