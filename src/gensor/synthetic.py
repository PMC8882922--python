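"""Synthetic five-table datasets with planted, known-truth feedback.

The generator emulates the statistical shape of a curated bacterial
regulatory/metabolic extract — one allosteric effector for most TFs with
a small right tail, a handful of genes per regulon, roughly half of all
promoters co-regulated by more than one TF — while planting, per TF, one
of six feedback categories:

``DIRECT``        the effector sits in a reaction of the TF's own unit;
``CLASS``         only an is-a relative of the effector does;
``CASCADE_DOWN``  the match lives in the unit of a TF the focal TF regulates;
``CASCADE_UP``    ... of a TF regulating the focal TF;
``ENZYMATIC_TF``  the TF protein itself catalyses the matching reaction;
``NONE``          negative control — the effector occurs nowhere.

Every TF additionally carries decoy genes, decoy reactions over unique
decoy compounds, and its effector–TF binding reaction, so that negative
results are non-vacuous and the binding-reaction exclusion is exercised.
Generation is a pure function of (config, seed): one named random stream,
insertion-ordered tables, byte-identical files for equal inputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .model import (
    Compound,
    CompoundOntology,
    Dataset,
    GeneProduct,
    Reaction,
    ReactionSet,
    RegulatoryInteraction,
    RegulatoryNetwork,
    TFConformation,
    ValidationError,
)

__all__ = [
    "CATEGORIES",
    "GeneratorConfig",
    "default_category_counts",
    "build_dataset",
    "generate_dataset",
    "make_paper_fixtures",
    "EXPECTED_FIXTURE_STATUS",
]

PathLike = Union[str, Path]

CATEGORIES = ("DIRECT", "CLASS", "CASCADE_DOWN", "CASCADE_UP", "ENZYMATIC_TF", "NONE")

#: Status each planted category must map to under a full-tier scan.
CATEGORY_STATUS = {
    "DIRECT": "DIRECT",
    "CLASS": "CLASS_SUGGESTED",
    "CASCADE_DOWN": "CASCADE",
    "CASCADE_UP": "CASCADE",
    "ENZYMATIC_TF": "ENZYMATIC_TF",
    "NONE": "NOT_FOUND",
}

#: Category mix mirroring the curated compendium: of 87 effector-bearing
#: units, 71 show direct feedback, 7 class-level matches, 3 TF-cascade
#: cases (1 upstream, 2 downstream), 2 enzymatic TFs, 4 with insufficient
#: data.
_REFERENCE_MIX = {
    "DIRECT": 71,
    "CLASS": 7,
    "CASCADE_DOWN": 2,
    "CASCADE_UP": 1,
    "ENZYMATIC_TF": 2,
    "NONE": 4,
}


def default_category_counts(n_tfs: int) -> dict[str, int]:
    """Scale the reference category mix to *n_tfs* by largest remainder."""
    total = sum(_REFERENCE_MIX.values())
    quotas = {c: n_tfs * v / total for c, v in _REFERENCE_MIX.items()}
    counts = {c: int(q) for c, q in quotas.items()}
    remainder = n_tfs - sum(counts.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True):
        if remainder <= 0:
            break
        counts[c] += 1
        remainder -= 1
    return counts


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one generated dataset.

    ``effector_count_dist`` gives P(number of distinct effectors) per TF
    (default: 88% single-effector, mean 1.16); ``promoter_coreg_prob`` is
    the chance that a regulated promoter picks up a second, global
    co-regulator (~50% multi-TF promoters); ``class_hop_distance`` is the
    is-a distance between a planted CLASS effector and the reaction
    compound standing in for it.
    """

    n_tfs: int = 20
    category_counts: Optional[Mapping[str, int]] = None
    genes_per_tf: tuple[int, int] = (2, 5)
    effector_count_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.88, 2: 0.09, 3: 0.02, 4: 0.01}
    )
    promoter_coreg_prob: float = 0.5
    class_hop_distance: int = 1
    n_global_regulators: int = 2

    def resolved_counts(self) -> dict[str, int]:
        if self.category_counts is None:
            counts = default_category_counts(self.n_tfs)
        else:
            counts = {c: 0 for c in CATEGORIES}
            for c, v in self.category_counts.items():
                if c not in CATEGORIES:
                    raise ValueError(f"unknown category {c!r}")
                counts[c] = int(v)
        total = sum(counts.values())
        if total > self.n_tfs:
            raise ValueError(
                f"category counts sum to {total} > n_tfs={self.n_tfs}"
            )
        counts["NONE"] += self.n_tfs - total  # unassigned TFs are negatives
        return counts


class _Builder:
    """Accumulates table rows in insertion order."""

    def __init__(self) -> None:
        self.compounds: dict[str, Compound] = {}
        self.interactions: list[RegulatoryInteraction] = []
        self.conformations: list[TFConformation] = []
        self.products: dict[str, GeneProduct] = {}
        self.reactions: list[Reaction] = []
        self.ontology_edges: list[tuple[str, str]] = []

    def compound(self, cid: str, name: str = "", synonyms: Sequence[str] = ()) -> str:
        if cid not in self.compounds:
            self.compounds[cid] = Compound(cid, name or cid, frozenset(synonyms))
        return cid

    def to_dataset(self) -> Dataset:
        dataset = Dataset(
            network=RegulatoryNetwork(self.interactions),
            conformations=tuple(self.conformations),
            products=dict(self.products),
            reactions=ReactionSet(self.reactions),
            ontology=CompoundOntology(self.ontology_edges),
            compounds=dict(self.compounds),
        )
        dataset.validate()
        return dataset

    # -- flat-file emission -------------------------------------------------

    def write(self, directory: PathLike) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)

        def dump(name: str, header: list[str], rows: list[list[str]]) -> None:
            lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
            (directory / name).write_text("\n".join(lines) + "\n", encoding="utf-8")

        dump(
            "network.tsv",
            ["tf_id", "target_gene_id", "effect", "promoter_id"],
            [
                [it.tf_id, it.target_gene_id, it.effect, it.promoter_id or ""]
                for it in self.interactions
            ],
        )
        dump(
            "conformations.tsv",
            ["tf_id", "state", "functional", "effector_ids"],
            [
                [c.tf_id, c.state, c.functional, ";".join(sorted(c.effectors))]
                for c in self.conformations
            ],
        )
        dump(
            "products.tsv",
            ["product_id", "gene_ids", "kind"],
            [
                [p.product_id, ";".join(p.gene_ids), p.kind]
                for p in self.products.values()
            ],
        )
        dump(
            "reactions.tsv",
            ["reaction_id", "reactants", "products", "catalyst", "rxn_type", "reversible"],
            [
                [
                    r.reaction_id,
                    ";".join(r.reactants),
                    ";".join(r.products),
                    r.catalyst or "",
                    r.rxn_type,
                    "true" if r.reversible else "false",
                ]
                for r in self.reactions
            ],
        )
        dump("ontology.tsv", ["child_id", "parent_id"], [list(e) for e in self.ontology_edges])
        dump(
            "compounds.tsv",
            ["compound_id", "name", "synonyms"],
            [
                [c.compound_id, c.name, ";".join(sorted(c.synonyms))]
                for c in self.compounds.values()
            ],
        )


def _draw_from(dist: Mapping[int, float], rng: random.Random) -> int:
    u = rng.random()
    acc = 0.0
    last = 1
    for value in sorted(dist):
        acc += dist[value]
        last = value
        if u < acc:
            return value
    return last


def build_dataset(
    config: GeneratorConfig, seed: int
) -> tuple[Dataset, list[dict[str, str]]]:
    """Generate a dataset in memory; returns (dataset, ground-truth rows)."""
    rng = random.Random(seed)
    counts = config.resolved_counts()
    labels: list[str] = []
    for category in CATEGORIES:
        labels += [category] * counts[category]
    rng.shuffle(labels)

    b = _Builder()
    ground_truth: list[dict[str, str]] = []

    global_tfs = [f"TFG{g:02d}" for g in range(config.n_global_regulators)]
    for gtf in global_tfs:
        b.conformations.append(TFConformation(gtf, "apo", frozenset(), "active"))

    for i, category in enumerate(labels):
        tf = f"TF{i:04d}"
        effector = b.compound(f"eff{i:04d}", f"effector-{i:04d}")
        n_eff = _draw_from(config.effector_count_dist, rng)
        extras = [
            b.compound(f"eff{i:04d}x{j}", f"effector-{i:04d}-alt{j}")
            for j in range(1, n_eff)
        ]
        # regulatory logic combination (activator/repressor x apo/holo active)
        holo_active = rng.random() < 0.5
        b.conformations.append(
            TFConformation(
                tf, "holo", frozenset([effector, *extras]),
                "active" if holo_active else "inactive",
            )
        )
        b.conformations.append(
            TFConformation(tf, "apo", frozenset(), "inactive" if holo_active else "active")
        )

        # decoy regulon: genes, enzymes, reactions over unique decoy compounds
        n_genes = rng.randint(*config.genes_per_tf)
        decoy_rxn_ids = []
        for j in range(n_genes):
            gene = f"g{i:04d}_{j}"
            enzyme = f"E{i:04d}_{j}"
            promoter = f"p_{gene}"
            effect = rng.choice(("activation", "repression"))
            b.interactions.append(RegulatoryInteraction(tf, gene, effect, promoter))
            b.products[enzyme] = GeneProduct(enzyme, (gene,), "enzyme")
            rxn_id = f"rx{i:04d}_{j}"
            b.reactions.append(
                Reaction(
                    rxn_id,
                    (b.compound(f"d{i:04d}_{j}a"),),
                    (b.compound(f"d{i:04d}_{j}b"),),
                    catalyst=enzyme,
                )
            )
            decoy_rxn_ids.append(rxn_id)
            if rng.random() < config.promoter_coreg_prob:
                b.interactions.append(
                    RegulatoryInteraction(
                        rng.choice(global_tfs), gene, "activation", promoter
                    )
                )

        # the effector-TF binding reaction (excluded from every scan)
        b.reactions.append(
            Reaction(
                f"rxbind{i:04d}",
                (effector,),
                (b.compound(f"cpx{i:04d}", f"{tf}-{effector} complex"),),
                catalyst=tf,
                rxn_type="tf_effector_binding",
            )
        )

        evidence_note = ""
        if category == "DIRECT":
            # rebuild the TF's first decoy reaction so it produces the effector
            target = f"rx{i:04d}_0"
            for k, r in enumerate(b.reactions):
                if r.reaction_id == target:
                    b.reactions[k] = Reaction(
                        target, r.reactants, r.products + (effector,), r.catalyst
                    )
                    break
            evidence_note = target
        elif category == "CLASS":
            parent = effector
            for h in range(1, config.class_hop_distance + 1):
                child = b.compound(f"sub{i:04d}_{h}", f"subclass-{h} of effector-{i:04d}")
                b.ontology_edges.append((child, parent))
                parent = child
            target = f"rx{i:04d}_0"
            for k, r in enumerate(b.reactions):
                if r.reaction_id == target:
                    b.reactions[k] = Reaction(
                        target, (parent,) + r.reactants, r.products, r.catalyst
                    )
                    break
            evidence_note = f"{target}:{parent}"
        elif category in ("CASCADE_DOWN", "CASCADE_UP"):
            mediator = f"TFM{i:04d}"
            b.conformations.append(TFConformation(mediator, "apo", frozenset(), "active"))
            med_gene = f"gmt{i:04d}"
            med_enzyme = f"EM{i:04d}"
            b.products[med_enzyme] = GeneProduct(med_enzyme, (med_gene,), "enzyme")
            b.interactions.append(
                RegulatoryInteraction(mediator, med_gene, "activation", f"p_{med_gene}")
            )
            b.reactions.append(
                Reaction(
                    f"rxm{i:04d}",
                    (effector,),
                    (b.compound(f"dm{i:04d}"),),
                    catalyst=med_enzyme,
                )
            )
            if category == "CASCADE_DOWN":
                # focal TF regulates the gene encoding the mediator
                enc_gene = f"gm{i:04d}"
                b.products[mediator] = GeneProduct(mediator, (enc_gene,), "regulator")
                b.interactions.append(
                    RegulatoryInteraction(tf, enc_gene, "activation", f"p_{enc_gene}")
                )
            else:
                # mediator regulates the gene encoding the focal TF
                enc_gene = f"gf{i:04d}"
                b.products[tf] = GeneProduct(tf, (enc_gene,), "regulator")
                b.interactions.append(
                    RegulatoryInteraction(mediator, enc_gene, "activation", f"p_{enc_gene}")
                )
            evidence_note = f"rxm{i:04d}:{mediator}"
        elif category == "ENZYMATIC_TF":
            b.reactions.append(
                Reaction(
                    f"rxenz{i:04d}",
                    (effector, b.compound(f"dz{i:04d}a")),
                    (b.compound(f"dz{i:04d}b"),),
                    catalyst=tf,
                )
            )
            evidence_note = f"rxenz{i:04d}"
        elif category == "NONE" and i % 3 == 0:
            # decoy is-a edge so the ontology is non-trivial for negatives
            b.ontology_edges.append(
                (f"d{i:04d}_0a", b.compound(f"dcls{i:04d}", f"decoy class {i:04d}"))
            )

        ground_truth.append(
            {
                "tf_id": tf,
                "planted_category": category,
                "expected_status": CATEGORY_STATUS[category],
                "planted_evidence": evidence_note,
            }
        )

    return b.to_dataset(), ground_truth


def generate_dataset(
    config: GeneratorConfig, seed: int, out_dir: PathLike
) -> Dataset:
    """Generate and write the six flat files plus ground_truth.tsv."""
    rng_probe = config.resolved_counts()  # raises early on bad config
    del rng_probe
    dataset, ground_truth = build_dataset(config, seed)
    builder = _dataset_to_builder(dataset)
    builder.write(out_dir)
    header = ["tf_id", "planted_category", "expected_status", "planted_evidence"]
    lines = ["\t".join(header)] + [
        "\t".join(row[c] for c in header) for row in ground_truth
    ]
    (Path(out_dir) / "ground_truth.tsv").write_text(
        "\n".join(lines) + "\n", encoding="utf-8"
    )
    return dataset


def _dataset_to_builder(dataset: Dataset) -> _Builder:
    b = _Builder()
    b.compounds = dict(dataset.compounds)
    b.interactions = list(dataset.network.interactions)
    b.conformations = list(dataset.conformations)
    b.products = dict(dataset.products)
    b.reactions = sorted(dataset.reactions, key=lambda r: r.reaction_id)
    b.ontology_edges = sorted(dataset.ontology.edges)
    return b


# ---------------------------------------------------------------------------
# hand-written fixture: the ten worked systems from the E. coli compendium
# ---------------------------------------------------------------------------

#: Status expected for each named system under a full-tier scan
#: (depth 1, direction both).
EXPECTED_FIXTURE_STATUS = {
    "LacI": "DIRECT",
    "CRP": "DIRECT",
    "GalR": "CLASS_SUGGESTED",
    "AllS": "CASCADE",  # upstream, via AllR
    "Cbl": "CASCADE",  # downstream, via CysB
    "RhaR": "CASCADE",  # downstream, via RhaS (class-level match)
    "BirA": "ENZYMATIC_TF",
    "DnaA": "ENZYMATIC_TF",
    "MarR": "NOT_FOUND",
    "PyrR": "NOT_FOUND",
}


def make_paper_fixtures(out_dir: Optional[PathLike] = None) -> Dataset:
    """Small E. coli dataset encoding ten well-characterised sensory systems.

    LacI/allolactose and CRP/cAMP close their loops directly (β-gal
    isomerises lactose to allolactose; CRP represses cyaA, whose product
    synthesises cAMP). GalR only reaches a stereoisomer subclass of its
    effector (α-D-galactopyranose is-a D-galactose). AllS, Cbl and RhaR
    need a second TF: AllR (which regulates allS and the
    allantoin-consuming allB), CysB (regulating the APS-synthesising
    cysDN), and RhaS (regulating the L-rhamnose transporter rhaT).
    BirA and DnaA are enzymatic TFs whose own catalysis regenerates or
    consumes the effector. MarR (salicylate) and PyrR (pyruvate) lack any
    annotated reaction touching their effector — negative controls.
    """
    b = _Builder()

    def conf(tf: str, active_state: str, effector: Optional[str]) -> None:
        holo_active = active_state == "holo"
        if effector is None:
            b.conformations.append(TFConformation(tf, "apo", frozenset(), "active"))
            return
        b.conformations.append(
            TFConformation(
                tf, "holo", frozenset([effector]),
                "active" if holo_active else "inactive",
            )
        )
        b.conformations.append(
            TFConformation(tf, "apo", frozenset(), "inactive" if holo_active else "active")
        )

    c = b.compound
    for cid, name in [
        ("lactose", "lactose"),
        ("allolactose", "allolactose"),
        ("laci-allolactose", "LacI-allolactose complex"),
        ("camp", "cyclic AMP"),
        ("atp", "ATP"),
        ("adp", "ADP"),
        ("pi", "phosphate"),
        ("ppi", "diphosphate"),
        ("h2o", "water"),
        ("d-galactose", "D-galactose"),
        ("alpha-d-galactopyranose", "alpha-D-galactopyranose"),
        ("galactose-1-phosphate", "galactose 1-phosphate"),
        ("allantoin", "allantoin"),
        ("allantoate", "allantoate"),
        ("sulfate", "sulfate"),
        ("aps", "adenosine 5'-phosphosulfate"),
        ("l-rhamnose", "L-rhamnose"),
        ("alpha-l-rhamnopyranose", "alpha-L-rhamnopyranose"),
        ("dethiobiotin", "dethiobiotin"),
        ("biotin", "biotin"),
        ("biotinyl-5-adenylate", "biotinyl-5'-adenylate"),
        ("salicylate", "salicylate"),
        ("pyruvate", "pyruvate"),
    ]:
        c(cid, name)

    conf("LacI", "apo", "allolactose")
    conf("CRP", "holo", "camp")
    conf("GalR", "apo", "d-galactose")
    conf("AllS", "holo", "allantoin")
    conf("AllR", "apo", "allantoin")
    conf("Cbl", "holo", "aps")
    conf("CysB", "apo", None)
    conf("RhaR", "holo", "alpha-l-rhamnopyranose")
    conf("RhaS", "apo", None)
    conf("BirA", "holo", "biotinyl-5-adenylate")
    conf("DnaA", "holo", "atp")
    conf("MarR", "apo", "salicylate")
    conf("PyrR", "holo", "pyruvate")

    net = [
        ("LacI", "lacZ", "repression", "lacZp"),
        ("LacI", "lacY", "repression", "lacZp"),
        ("CRP", "lacZ", "activation", "lacZp"),
        ("CRP", "cyaA", "repression", "cyaAp"),
        ("GalR", "galK", "repression", "galKp"),
        ("AllR", "allS", "repression", "allSp"),
        ("AllR", "allB", "repression", "allBp"),
        ("AllS", "allD", "activation", "allDp"),
        ("Cbl", "cysB", "activation", "cysBp"),
        ("CysB", "cysD", "activation", "cysDNp"),
        ("CysB", "cysN", "activation", "cysDNp"),
        ("RhaR", "rhaS", "activation", "rhaSp"),
        ("RhaS", "rhaT", "activation", "rhaTp"),
        ("BirA", "bioB", "repression", "bioBp"),
        ("DnaA", "mioC", "repression", "mioCp"),
        ("MarR", "marB", "repression", "marBp"),
        ("PyrR", "yhjX", "activation", "yhjXp"),
    ]
    for tf, gene, effect, promoter in net:
        b.interactions.append(RegulatoryInteraction(tf, gene, effect, promoter))

    for pid, genes, kind in [
        ("LacZ", ("lacZ",), "enzyme"),
        ("LacY", ("lacY",), "transporter"),
        ("CyaA", ("cyaA",), "enzyme"),
        ("GalK", ("galK",), "enzyme"),
        ("AllB", ("allB",), "enzyme"),
        ("AllS", ("allS",), "regulator"),
        ("AllD", ("allD",), "other"),
        ("CysB", ("cysB",), "regulator"),
        ("CysDN", ("cysD", "cysN"), "enzyme"),
        ("RhaS", ("rhaS",), "regulator"),
        ("RhaT", ("rhaT",), "transporter"),
        ("BioB", ("bioB",), "enzyme"),
        ("MioC", ("mioC",), "other"),
        ("MarB", ("marB",), "other"),
        ("YhjX", ("yhjX",), "transporter"),
    ]:
        b.products[pid] = GeneProduct(pid, genes, kind)

    rxns = [
        ("rx_lacZ", ("lactose",), ("allolactose",), "LacZ", "enzymatic", True),
        ("rx_lacY", ("lactose",), ("lactose",), "LacY", "transport", False),
        ("rx_cyaA", ("atp",), ("camp", "ppi"), "CyaA", "enzymatic", False),
        (
            "rx_galK",
            ("alpha-d-galactopyranose", "atp"),
            ("galactose-1-phosphate", "adp"),
            "GalK",
            "enzymatic",
            False,
        ),
        ("rx_allB", ("allantoin", "h2o"), ("allantoate",), "AllB", "enzymatic", False),
        ("rx_cysDN", ("sulfate", "atp"), ("aps", "ppi"), "CysDN", "enzymatic", False),
        ("rx_rhaT", ("l-rhamnose",), ("l-rhamnose",), "RhaT", "transport", False),
        ("rx_bioB", ("dethiobiotin",), ("biotin",), "BioB", "enzymatic", False),
        (
            "rx_birA",
            ("biotin", "atp"),
            ("biotinyl-5-adenylate", "ppi"),
            "BirA",
            "enzymatic",
            False,
        ),
        ("rx_dnaA", ("atp", "h2o"), ("adp", "pi"), "DnaA", "enzymatic", False),
        (
            "rx_bind_lacI",
            ("allolactose",),
            ("laci-allolactose",),
            "LacI",
            "tf_effector_binding",
            False,
        ),
    ]
    for rid, reactants, products, catalyst, rxn_type, reversible in rxns:
        b.reactions.append(
            Reaction(rid, reactants, products, catalyst, rxn_type, reversible)
        )

    b.ontology_edges = [
        ("alpha-d-galactopyranose", "d-galactose"),
        ("alpha-l-rhamnopyranose", "l-rhamnose"),
    ]

    dataset = b.to_dataset()
    if out_dir is not None:
        b.write(out_dir)
    return dataset
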