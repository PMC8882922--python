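"""Assembly of elementary and complex GENSOR units.

An elementary unit joins, around one TF: the genes it regulates, their
products (including hetero-complexes sharing a regulated component), the
reactions those products catalyse or transport, and the TF's known
allosteric effectors. A complex unit does the same around a *complex
regulon*: the exact set of TFs jointly regulating a block of genes, with
genes partitioned by their exact regulator set.

Effector–TF binding reactions are never part of a unit, and reactions
catalysed by the anchor TF itself (enzymatic TFs such as BirA) are kept
outside the unit as well; the feedback scanner has a dedicated tier for
them.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    Dataset,
    DatasetLookupError,
    GeneProduct,
    GensorUnit,
    Reaction,
    ReactionSet,
    RegulatoryNetwork,
    TFConformation,
)

__all__ = [
    "assemble_gensor_unit",
    "assemble_all",
    "assemble_complex_units",
    "unit_for",
]


def _effectors_of(
    tf_ids: Iterable[str], conformations: Iterable[TFConformation]
) -> frozenset[str]:
    wanted = set(tf_ids)
    eff: set[str] = set()
    for conf in conformations:
        if conf.tf_id in wanted and conf.state == "holo":
            eff |= conf.effectors
    return frozenset(eff)


def _join_response(
    regulated_genes: frozenset[str],
    anchor: Sequence[str],
    products: Mapping[str, GeneProduct],
    reactions: ReactionSet,
    require_all_genes: bool,
) -> tuple[tuple[GeneProduct, ...], tuple[Reaction, ...]]:
    anchor_set = set(anchor)
    selected: list[GeneProduct] = []
    for product in products.values():
        genes = set(product.gene_ids)
        hit = genes <= regulated_genes if require_all_genes else genes & regulated_genes
        if hit:
            selected.append(product)
    product_ids = {p.product_id for p in selected}
    unit_reactions = [
        r
        for r in reactions
        if r.catalyst in product_ids
        and r.catalyst not in anchor_set
        and r.rxn_type != "tf_effector_binding"
    ]
    return tuple(selected), tuple(unit_reactions)


def assemble_gensor_unit(
    tf_id: str,
    network: RegulatoryNetwork,
    products: Mapping[str, GeneProduct],
    reactions: ReactionSet,
    conformations: Iterable[TFConformation] = (),
    *,
    require_all_complex_genes: bool = False,
) -> GensorUnit:
    """Assemble the elementary unit anchored at *tf_id*.

    A hetero-complex product joins the unit when any of its component
    genes is regulated by the TF; ``require_all_complex_genes=True``
    demands all of them.

    Raises :class:`DatasetLookupError` when the TF has no interaction in
    the network.
    """
    regulated = network.targets_of(tf_id)
    selected, unit_reactions = _join_response(
        regulated, (tf_id,), products, reactions, require_all_complex_genes
    )
    return GensorUnit(
        anchor=(tf_id,),
        regulated_genes=regulated,
        products=selected,
        reactions=unit_reactions,
        effectors=_effectors_of((tf_id,), conformations),
    )


def assemble_all(
    network: RegulatoryNetwork,
    products: Mapping[str, GeneProduct],
    reactions: ReactionSet,
    conformations: Iterable[TFConformation] = (),
    **kwargs,
) -> dict[str, GensorUnit]:
    """One elementary unit per TF with >=1 interaction, keyed by sorted tf_id."""
    conformations = tuple(conformations)
    return {
        tf_id: assemble_gensor_unit(
            tf_id, network, products, reactions, conformations, **kwargs
        )
        for tf_id in sorted(network.tf_ids)
    }


def assemble_complex_units(
    network: RegulatoryNetwork,
    products: Mapping[str, GeneProduct],
    reactions: ReactionSet,
    conformations: Iterable[TFConformation] = (),
    *,
    include_singletons: bool = False,
    require_all_complex_genes: bool = False,
) -> list[GensorUnit]:
    """Assemble complex units from complex regulons.

    Genes are partitioned by their exact regulating-TF set; each block
    with at least two anchor TFs (or any block when
    ``include_singletons``) yields one unit. The blocks are disjoint and
    jointly cover every regulated gene.
    """
    conformations = tuple(conformations)
    blocks: dict[frozenset[str], set[str]] = {}
    for gene in network.gene_ids:
        blocks.setdefault(network.regulators_of(gene), set()).add(gene)
    units: list[GensorUnit] = []
    for anchor in sorted(blocks, key=lambda a: tuple(sorted(a))):
        if len(anchor) < 2 and not include_singletons:
            continue
        genes = frozenset(blocks[anchor])
        selected, unit_reactions = _join_response(
            genes, tuple(anchor), products, reactions, require_all_complex_genes
        )
        units.append(
            GensorUnit(
                anchor=tuple(sorted(anchor)),
                regulated_genes=genes,
                products=selected,
                reactions=unit_reactions,
                effectors=_effectors_of(anchor, conformations),
            )
        )
    return units


def unit_for(tf_id: str, dataset: Dataset, **kwargs) -> GensorUnit:
    """Dataset-level convenience wrapper around :func:`assemble_gensor_unit`."""
    return assemble_gensor_unit(
        tf_id,
        dataset.network,
        dataset.products,
        dataset.reactions,
        dataset.conformations,
        **kwargs,
    )
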