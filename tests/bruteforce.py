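"""Independent brute-force oracle for the feedback scan.

Everything here re-derives the answer from the raw tables with naive
loops: exhaustive filtering for unit membership, a fixpoint iteration
for the is-a transitive closure, and explicit path enumeration for the
regulatory cascade. No assembly or scan code from the package is used.
"""

from __future__ import annotations

from gensor.model import Dataset

PRIORITY = ["DIRECT", "ENZYMATIC_TF", "CLASS_SUGGESTED", "CASCADE", "NOT_FOUND"]


def closure_pairs(edges):
    """Strict transitive closure of child→parent edges by fixpoint."""
    reach = set(edges)
    changed = True
    while changed:
        changed = False
        for a, b in list(reach):
            for c, d in list(reach):
                if b == c and (a, d) not in reach:
                    reach.add((a, d))
                    changed = True
    return reach


def brute_effectors(tf_id: str, dataset: Dataset) -> set[str]:
    out: set[str] = set()
    for conf in dataset.conformations:
        if conf.tf_id == tf_id and conf.state == "holo":
            out |= set(conf.effectors)
    return out


def brute_unit_reactions(tf_id: str, dataset: Dataset):
    genes = {
        it.target_gene_id
        for it in dataset.network.interactions
        if it.tf_id == tf_id
    }
    product_ids = {
        p.product_id
        for p in dataset.products.values()
        if any(g in genes for g in p.gene_ids)
    }
    return [
        r
        for r in dataset.reactions
        if r.catalyst in product_ids
        and r.catalyst != tf_id
        and r.rxn_type != "tf_effector_binding"
    ]


def _related(effector: str, closure: set[tuple[str, str]]) -> set[str]:
    return {b for a, b in closure if a == effector} | {
        a for a, b in closure if b == effector
    }


def _neighbours(tf_id: str, dataset: Dataset, direction: str) -> set[str]:
    def encoding_genes(t):
        genes = set()
        p = dataset.products.get(t)
        if p is not None and p.kind == "regulator":
            genes |= set(p.gene_ids)
        if t in dataset.network.gene_ids:
            genes.add(t)
        return genes

    all_tfs = dataset.network.tf_ids
    out: set[str] = set()
    if direction in ("down", "both"):
        targets = {
            it.target_gene_id
            for it in dataset.network.interactions
            if it.tf_id == tf_id
        }
        for other in all_tfs:
            if other != tf_id and targets & encoding_genes(other):
                out.add(other)
    if direction in ("up", "both"):
        mine = encoding_genes(tf_id)
        for other in all_tfs:
            if other == tf_id:
                continue
            their_targets = {
                it.target_gene_id
                for it in dataset.network.interactions
                if it.tf_id == other
            }
            if their_targets & mine:
                out.add(other)
    return out


def brute_detect(
    tf_id: str,
    dataset: Dataset,
    depth: int = 1,
    direction: str = "both",
    tiers=("direct", "enzymatic", "class", "cascade"),
):
    """Return (status, {(reaction_id, compound_id)}) for the winning tier."""
    effectors = brute_effectors(tf_id, dataset)
    if not effectors:
        return "NO_EFFECTOR", set()
    closure = closure_pairs(dataset.ontology.edges)
    unit_rxns = brute_unit_reactions(tf_id, dataset)

    if "direct" in tiers:
        hits = {
            (r.reaction_id, e)
            for r in unit_rxns
            for e in effectors
            if e in set(r.reactants) | set(r.products)
        }
        if hits:
            return "DIRECT", hits
    if "enzymatic" in tiers:
        hits = {
            (r.reaction_id, e)
            for r in dataset.reactions
            if r.catalyst == tf_id and r.rxn_type != "tf_effector_binding"
            for e in effectors
            if e in set(r.reactants) | set(r.products)
        }
        if hits:
            return "ENZYMATIC_TF", hits
    if "class" in tiers:
        hits = set()
        for e in effectors:
            relatives = _related(e, closure)
            for r in unit_rxns:
                for c in set(r.reactants) | set(r.products):
                    if c in relatives:
                        hits.add((r.reaction_id, c))
        if hits:
            return "CLASS_SUGGESTED", hits
    if "cascade" in tiers:
        mediators: set[str] = set()
        frontier = {tf_id}
        seen = {tf_id}
        for _ in range(depth):
            nxt = set()
            for node in frontier:
                for n in _neighbours(node, dataset, direction):
                    if n not in seen:
                        seen.add(n)
                        nxt.add(n)
            mediators |= nxt
            frontier = nxt
        hits = set()
        for med in mediators:
            for r in brute_unit_reactions(med, dataset):
                for c in set(r.reactants) | set(r.products):
                    for e in effectors:
                        if c == e:
                            hits.add((r.reaction_id, c))
                        elif (e, c) in closure or (c, e) in closure:
                            hits.add((r.reaction_id, c))
        if hits:
            return "CASCADE", hits
    return "NOT_FOUND", set()
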