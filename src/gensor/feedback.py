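"""Tiered detection of feedback from a GENSOR unit's response to its signal.

A sensory-response unit is expected to feed back on the molecule that
triggered it: the TF's allosteric effector should be produced, consumed
or transported by the very gene products the TF regulates. The scan runs
in tiers of decreasing confidence:

``DIRECT``
    the effector itself is a reactant or product of a unit reaction;
``ENZYMATIC_TF``
    the effector participates in a reaction catalysed by the TF protein
    itself (enzymatic TFs such as the biotin ligase BirA or the
    replication initiator/ATPase DnaA);
``CLASS_SUGGESTED``
    a sub- or superclass of the effector in the compound is-a ontology
    appears in a unit reaction — stereoisomer-level naming mismatches
    make this tier a suggestion that requires manual curation;
``CASCADE``
    the match (exact or class-level) appears in the unit of a TF one or
    more regulatory hops away — a TF the anchor regulates (downstream)
    or a TF regulating the anchor (upstream).

Effector–TF binding reactions never count as feedback at any tier, and
matching is direction-blind (consumption and production both close the
loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .assembly import assemble_all
from .model import (
    CompoundOntology,
    Dataset,
    DatasetLookupError,
    Evidence,
    FeedbackResult,
    FeedbackStatus,
    GensorUnit,
    ReactionSet,
    RegulatoryNetwork,
)

__all__ = [
    "FeedbackConfig",
    "scan_direct",
    "scan_class",
    "scan_cascade",
    "scan_enzymatic_tf",
    "detect_feedback",
    "detect_all",
    "summarize",
]

TIERS = ("direct", "enzymatic", "class", "cascade")

#: Tier priority, highest first; NO_EFFECTOR short-circuits everything.
STATUS_PRIORITY = (
    FeedbackStatus.DIRECT,
    FeedbackStatus.ENZYMATIC_TF,
    FeedbackStatus.CLASS_SUGGESTED,
    FeedbackStatus.CASCADE,
)


@dataclass(frozen=True)
class FeedbackConfig:
    """Which tiers run and how far the class/cascade searches reach.

    ``class_max_hops=None`` means the full transitive closure of the
    is-a hierarchy; ``cascade_direction`` is ``"down"`` (TFs the anchor
    regulates), ``"up"`` (TFs regulating the anchor) or ``"both"``.
    """

    tiers: tuple[str, ...] = TIERS
    class_max_hops: Optional[int] = None
    cascade_depth: int = 1
    cascade_direction: str = "both"

    def __post_init__(self) -> None:
        for tier in self.tiers:
            if tier not in TIERS:
                raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
        if self.cascade_depth < 1:
            raise ValueError("cascade_depth must be >= 1")
        if self.cascade_direction not in ("down", "up", "both"):
            raise ValueError("cascade_direction must be 'down', 'up' or 'both'")


def _result(unit_label: str, status: FeedbackStatus, evidence=(), notes="") -> FeedbackResult:
    return FeedbackResult(unit_label, status, tuple(evidence), notes)


def _direct_evidence(unit: GensorUnit) -> list[Evidence]:
    rows = []
    for reaction in unit.reactions:
        for effector in sorted(unit.effectors & reaction.compounds):
            rows.append(Evidence(reaction.reaction_id, effector))
    return rows


def scan_direct(unit: GensorUnit) -> FeedbackResult:
    """Direct tier: an effector is a reactant or product of a unit reaction."""
    if not unit.effectors:
        return _result(unit.label, FeedbackStatus.NO_EFFECTOR)
    evidence = _direct_evidence(unit)
    if evidence:
        return _result(unit.label, FeedbackStatus.DIRECT, evidence)
    return _result(unit.label, FeedbackStatus.NOT_FOUND)


def _class_evidence(
    unit: GensorUnit, ontology: CompoundOntology, max_hops: Optional[int]
) -> list[Evidence]:
    rows = []
    for reaction in unit.reactions:
        for compound in sorted(reaction.compounds):
            for effector in sorted(unit.effectors):
                if compound == effector:
                    continue  # exact matches belong to the direct tier
                path = ontology.path(effector, compound)
                if path is None:
                    continue
                if max_hops is not None and len(path) - 1 > max_hops:
                    continue
                rows.append(Evidence(reaction.reaction_id, compound, path))
    return rows


def scan_class(
    unit: GensorUnit,
    ontology: CompoundOntology,
    max_hops: Optional[int] = None,
) -> FeedbackResult:
    """Class tier: a sub/superclass of an effector occurs in a unit reaction.

    Matches are suggestions (`CLASS_SUGGESTED`) because compound naming
    may differ only at the stereoisomer level; each evidence row carries
    the is-a path from the effector to the matched compound.
    """
    if not unit.effectors:
        return _result(unit.label, FeedbackStatus.NO_EFFECTOR)
    evidence = _class_evidence(unit, ontology, max_hops)
    if evidence:
        return _result(unit.label, FeedbackStatus.CLASS_SUGGESTED, evidence)
    return _result(unit.label, FeedbackStatus.NOT_FOUND)


def _tf_adjacency(
    network: RegulatoryNetwork,
    tf_ids: Iterable[str],
    encoding: Mapping[str, frozenset[str]],
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """TF→TF edges: X regulates Y iff X targets a gene encoding Y."""
    gene_to_tfs: dict[str, set[str]] = {}
    for tf, genes in encoding.items():
        for gene in genes:
            gene_to_tfs.setdefault(gene, set()).add(tf)
    down: dict[str, set[str]] = {}
    up: dict[str, set[str]] = {}
    for tf in tf_ids:
        down[tf] = set()
        for gene in network.targets_of(tf):
            for other in gene_to_tfs.get(gene, ()):
                if other != tf:
                    down[tf].add(other)
    for tf, neighbours in down.items():
        for other in neighbours:
            up.setdefault(other, set()).add(tf)
    return down, up


def scan_cascade(
    tf_id: str,
    network: RegulatoryNetwork,
    units: Mapping[str, GensorUnit],
    ontology: Optional[CompoundOntology] = None,
    depth: int = 1,
    direction: str = "both",
    *,
    tf_encoding: Optional[Mapping[str, frozenset[str]]] = None,
    class_max_hops: Optional[int] = None,
) -> FeedbackResult:
    """Cascade tier: search the units of regulatory neighbours of *tf_id*.

    Neighbours within *depth* hops are found by breadth-first search over
    the TF→TF graph, following downstream edges (TFs whose encoding gene
    the anchor regulates), upstream edges (TFs regulating the anchor's
    encoding gene), or both. Each mediator unit is scanned for an exact
    effector match and, when an ontology is given, class-level matches.

    *tf_encoding* maps each TF to its encoding gene(s); by default a TF's
    id doubles as its gene id when it appears as a network target.
    """
    if depth < 1:
        raise ValueError("cascade depth must be >= 1")
    if direction not in ("down", "up", "both"):
        raise ValueError("direction must be 'down', 'up' or 'both'")
    if tf_id not in units:
        raise DatasetLookupError(f"no assembled unit for TF {tf_id!r}")
    unit = units[tf_id]
    if not unit.effectors:
        return _result(tf_id, FeedbackStatus.NO_EFFECTOR)

    if tf_encoding is None:
        tf_encoding = {
            tf: frozenset({tf} if tf in network.gene_ids else set())
            for tf in network.tf_ids
        }
    down, up = _tf_adjacency(network, network.tf_ids, tf_encoding)

    # BFS over mediator TFs, remembering the hop path and its directions
    frontier: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = [(tf_id, (), ())]
    visited = {tf_id}
    evidence: list[Evidence] = []
    for _ in range(depth):
        next_frontier = []
        for node, path, dirs in frontier:
            neighbours: list[tuple[str, str]] = []
            if direction in ("down", "both"):
                neighbours += [(n, "down") for n in sorted(down.get(node, ()))]
            if direction in ("up", "both"):
                neighbours += [(n, "up") for n in sorted(up.get(node, ()))]
            for mediator, hop_dir in neighbours:
                if mediator in visited:
                    continue
                visited.add(mediator)
                med_path = path + (mediator,)
                med_dirs = dirs + (hop_dir,)
                next_frontier.append((mediator, med_path, med_dirs))
                med_unit = units.get(mediator)
                if med_unit is None:
                    continue
                probe = GensorUnit(
                    anchor=med_unit.anchor,
                    regulated_genes=med_unit.regulated_genes,
                    products=med_unit.products,
                    reactions=med_unit.reactions,
                    effectors=unit.effectors,  # the anchor's effectors, not the mediator's
                )
                rows = _direct_evidence(probe)
                if ontology is not None:
                    rows += _class_evidence(probe, ontology, class_max_hops)
                for row in rows:
                    evidence.append(
                        replace(row, mediators=med_path, direction=">".join(med_dirs))
                    )
        frontier = next_frontier
    if evidence:
        return _result(tf_id, FeedbackStatus.CASCADE, evidence)
    return _result(tf_id, FeedbackStatus.NOT_FOUND)


def scan_enzymatic_tf(
    tf_id: str, unit: GensorUnit, reactions: ReactionSet
) -> FeedbackResult:
    """Enzymatic-TF tier: the TF protein itself catalyses a matching reaction.

    Reactions with ``catalyst == tf_id`` sit outside the assembled unit;
    the effector–TF binding reaction is excluded as always.
    """
    if not unit.effectors:
        return _result(tf_id, FeedbackStatus.NO_EFFECTOR)
    evidence = []
    for reaction in reactions.catalysed_by(tf_id):
        if reaction.rxn_type == "tf_effector_binding":
            continue
        for effector in sorted(unit.effectors & reaction.compounds):
            evidence.append(Evidence(reaction.reaction_id, effector))
    if evidence:
        return _result(tf_id, FeedbackStatus.ENZYMATIC_TF, evidence)
    return _result(tf_id, FeedbackStatus.NOT_FOUND)


def detect_feedback(
    tf_id: str,
    dataset: Dataset,
    config: Optional[FeedbackConfig] = None,
    *,
    units: Optional[Mapping[str, GensorUnit]] = None,
) -> FeedbackResult:
    """Run the enabled tiers in priority order and return the best status.

    Priority: DIRECT > ENZYMATIC_TF > CLASS_SUGGESTED > CASCADE >
    NOT_FOUND, with NO_EFFECTOR short-circuiting. All evidence of the
    winning tier is returned. Pass precomputed *units* when scanning many
    TFs.
    """
    config = config or FeedbackConfig()
    if units is None:
        units = assemble_all(
            dataset.network, dataset.products, dataset.reactions, dataset.conformations
        )
    if tf_id not in units:
        raise DatasetLookupError(f"TF {tf_id!r} has no assembled unit")
    unit = units[tf_id]
    if not unit.effectors:
        return _result(tf_id, FeedbackStatus.NO_EFFECTOR)

    if "direct" in config.tiers:
        result = scan_direct(unit)
        if result.status is FeedbackStatus.DIRECT:
            return result
    if "enzymatic" in config.tiers:
        result = scan_enzymatic_tf(tf_id, unit, dataset.reactions)
        if result.status is FeedbackStatus.ENZYMATIC_TF:
            return result
    if "class" in config.tiers:
        result = scan_class(unit, dataset.ontology, config.class_max_hops)
        if result.status is FeedbackStatus.CLASS_SUGGESTED:
            return result
    if "cascade" in config.tiers:
        encoding = {tf: dataset.encoding_genes_of(tf) for tf in dataset.tf_ids}
        result = scan_cascade(
            tf_id,
            dataset.network,
            units,
            dataset.ontology,
            depth=config.cascade_depth,
            direction=config.cascade_direction,
            tf_encoding=encoding,
            class_max_hops=config.class_max_hops,
        )
        if result.status is FeedbackStatus.CASCADE:
            return result
    return _result(tf_id, FeedbackStatus.NOT_FOUND)


def detect_all(
    dataset: Dataset, config: Optional[FeedbackConfig] = None
) -> list[FeedbackResult]:
    """detect_feedback over every TF with an assembled unit, sorted by tf_id."""
    units = assemble_all(
        dataset.network, dataset.products, dataset.reactions, dataset.conformations
    )
    return [
        detect_feedback(tf_id, dataset, config, units=units)
        for tf_id in sorted(units)
    ]


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10 ** ndigits
    return int(x * scale + 0.5) / scale if x >= 0 else -int(-x * scale + 0.5) / scale


def summarize(results: Sequence[FeedbackResult]) -> dict:
    """Counts per status plus the direct-tier feedback fraction.

    The headline fraction is |DIRECT| over results with a known effector
    (everything except NO_EFFECTOR), reported both to one decimal and as
    the conventionally rounded integer percentage; ``None`` when no TF
    has an effector. NOT_FOUND TFs are listed for manual follow-up.
    """
    counts = {status.value: 0 for status in FeedbackStatus}
    for result in results:
        counts[result.status.value] += 1
    n_with_effector = len(results) - counts[FeedbackStatus.NO_EFFECTOR.value]
    if n_with_effector:
        fraction = counts[FeedbackStatus.DIRECT.value] / n_with_effector
        percent_1dp = _round_half_up(100.0 * fraction, 1)
        percent_int = int(_round_half_up(100.0 * fraction))
    else:
        fraction = percent_1dp = percent_int = None
    return {
        "n_results": len(results),
        "n_with_effector": n_with_effector,
        "counts": counts,
        "fraction_direct": fraction,
        "percent_direct": percent_1dp,
        "percent_direct_int": percent_int,
        "not_found_tfs": sorted(
            r.tf_id for r in results if r.status is FeedbackStatus.NOT_FOUND
        ),
    }
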