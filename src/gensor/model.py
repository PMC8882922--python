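"""Domain types for genetic sensory-response (GENSOR) unit analysis.

The object model mirrors the two data layers the pipeline joins:

* the *genetic switch* layer — a signed transcription-factor (TF) → gene
  regulatory network plus the curated apo/holo conformations of each TF
  and the allosteric effector compounds bound in the holo states;
* the *response* layer — gene products (enzymes, transporters,
  hetero-complexes), the reactions they catalyse, and a compound is-a
  ontology used for class-level matching of effectors against reaction
  participants.

All types are immutable; validation happens at construction time so that
any loaded dataset satisfies the invariants the downstream algorithms
rely on (referential closure, ontology acyclicity, apo/holo consistency).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "GensorError",
    "FormatError",
    "ValidationError",
    "DatasetLookupError",
    "Compound",
    "CompoundOntology",
    "Gene",
    "GeneProduct",
    "Reaction",
    "TFConformation",
    "RegulatoryInteraction",
    "RegulatoryNetwork",
    "ReactionSet",
    "GensorUnit",
    "FeedbackStatus",
    "Evidence",
    "FeedbackResult",
    "Dataset",
]


class GensorError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GensorError):
    """A flat file does not conform to the expected tabular dialect."""


class ValidationError(GensorError):
    """A loaded record violates a domain invariant."""


class DatasetLookupError(GensorError, KeyError):
    """An identifier does not resolve within the loaded dataset."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


# ---------------------------------------------------------------------------
# compounds and ontology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Compound:
    """A small molecule (metabolite, effector) with canonical name."""

    compound_id: str
    name: str
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        if not self.name:
            raise ValidationError(
                f"compound {self.compound_id!r}: canonical name must be non-empty"
            )
        object.__setattr__(self, "synonyms", frozenset(self.synonyms))


class CompoundOntology:
    """Is-a hierarchy over compounds, stored as child → parent edges.

    The graph must be a DAG: class matching walks the transitive closure
    up (superclasses) and down (subclasses) of an effector, and a cycle
    would make "sub/superclass of" ill-defined.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = ()):
        graph = nx.DiGraph()
        for child, parent in edges:
            if not child or not parent:
                raise ValidationError("ontology edge endpoints must be non-empty")
            graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise ValidationError(f"compound ontology contains a cycle: {path}")
        self._graph = graph

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._graph.edges())

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._graph

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CompoundOntology) and self.edges == other.edges

    def __hash__(self) -> int:
        return hash(self.edges)

    def ancestors(self, compound_id: str) -> set[str]:
        """All strict superclasses of *compound_id* (transitive)."""
        if compound_id not in self._graph:
            return set()
        return set(nx.descendants(self._graph, compound_id))

    def descendants(self, compound_id: str) -> set[str]:
        """All strict subclasses of *compound_id* (transitive)."""
        if compound_id not in self._graph:
            return set()
        return set(nx.ancestors(self._graph, compound_id))

    def path(self, compound_id: str, other: str) -> Optional[tuple[str, ...]]:
        """Shortest is-a path from *compound_id* to *other*, either direction.

        The returned tuple starts at ``compound_id`` and ends at ``other``;
        ``None`` when the two are not hierarchically related (or equal).
        """
        if compound_id == other:
            return None
        if compound_id not in self._graph or other not in self._graph:
            return None
        if nx.has_path(self._graph, compound_id, other):  # other is ancestor
            return tuple(nx.shortest_path(self._graph, compound_id, other))
        if nx.has_path(self._graph, other, compound_id):  # other is descendant
            return tuple(reversed(nx.shortest_path(self._graph, other, compound_id)))
        return None


# ---------------------------------------------------------------------------
# genes, products, reactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    gene_id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")


PRODUCT_KINDS = ("enzyme", "transporter", "regulator", "other")


@dataclass(frozen=True)
class GeneProduct:
    """A polypeptide or complex; >1 encoding gene means a hetero-complex."""

    product_id: str
    gene_ids: tuple[str, ...]
    kind: str = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if not self.product_id:
            raise ValidationError("product_id must be non-empty")
        if len(self.gene_ids) < 1:
            raise ValidationError(
                f"product {self.product_id!r} must list at least one encoding gene"
            )
        if self.kind not in PRODUCT_KINDS:
            raise ValidationError(
                f"product {self.product_id!r}: kind {self.kind!r} not one of {PRODUCT_KINDS}"
            )


RXN_TYPES = ("enzymatic", "transport", "tf_effector_binding", "other")


@dataclass(frozen=True)
class Reaction:
    """A metabolic, transport or effector-binding reaction.

    Compartments are collapsed: a transport event is a reaction with the
    moved compound on both sides. ``tf_effector_binding`` rows represent
    the effector–TF association itself and are excluded from every
    feedback scan.
    """

    reaction_id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    catalyst: Optional[str] = None
    rxn_type: str = "enzymatic"
    reversible: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))
        if not self.reaction_id:
            raise ValidationError("reaction_id must be non-empty")
        if self.rxn_type not in RXN_TYPES:
            raise ValidationError(
                f"reaction {self.reaction_id!r}: rxn_type {self.rxn_type!r} "
                f"not one of {RXN_TYPES}"
            )
        if self.rxn_type not in ("transport", "tf_effector_binding"):
            if not self.reactants or not self.products:
                raise ValidationError(
                    f"reaction {self.reaction_id!r}: reactant and product lists "
                    "must be non-empty"
                )
        elif not self.reactants and not self.products:
            raise ValidationError(
                f"reaction {self.reaction_id!r}: no participants at all"
            )
        if self.rxn_type == "tf_effector_binding" and not self.catalyst:
            raise ValidationError(
                f"reaction {self.reaction_id!r}: tf_effector_binding must name "
                "the TF as catalyst"
            )

    @property
    def compounds(self) -> frozenset[str]:
        """All participants, direction-blind."""
        return frozenset(self.reactants) | frozenset(self.products)

    def reversed(self) -> "Reaction":
        return Reaction(
            reaction_id=self.reaction_id,
            reactants=self.products,
            products=self.reactants,
            catalyst=self.catalyst,
            rxn_type=self.rxn_type,
            reversible=self.reversible,
        )


class ReactionSet:
    """Immutable collection of reactions, indexed by id and catalyst."""

    def __init__(self, reactions: Iterable[Reaction] = ()):
        self._reactions: tuple[Reaction, ...] = tuple(
            sorted(reactions, key=lambda r: r.reaction_id)
        )
        seen: dict[str, Reaction] = {}
        for r in self._reactions:
            if r.reaction_id in seen and seen[r.reaction_id] != r:
                raise ValidationError(f"duplicate reaction_id {r.reaction_id!r}")
            seen[r.reaction_id] = r
        self._by_id = seen
        self._by_catalyst: dict[str, list[Reaction]] = {}
        for r in self._by_id.values():
            if r.catalyst:
                self._by_catalyst.setdefault(r.catalyst, []).append(r)

    def __iter__(self) -> Iterator[Reaction]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ReactionSet) and self._by_id == other._by_id

    def __getitem__(self, reaction_id: str) -> Reaction:
        try:
            return self._by_id[reaction_id]
        except KeyError:
            raise DatasetLookupError(f"unknown reaction_id {reaction_id!r}") from None

    def __contains__(self, reaction_id: str) -> bool:
        return reaction_id in self._by_id

    def catalysed_by(self, catalyst_id: str) -> tuple[Reaction, ...]:
        return tuple(self._by_catalyst.get(catalyst_id, ()))


# ---------------------------------------------------------------------------
# TF conformations and the regulatory network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TFConformation:
    """One apo or holo conformation row of a TF.

    ``functional`` marks the DNA-binding-competent state: an apo-active
    repressor (LacI-like) unbinds when its effector appears, a holo-active
    activator (CRP-like) binds only as the TF–effector complex.
    """

    tf_id: str
    state: str  # "apo" | "holo"
    effectors: frozenset[str] = frozenset()
    functional: str = "active"  # "active" | "inactive"

    def __post_init__(self) -> None:
        object.__setattr__(self, "effectors", frozenset(self.effectors))
        if not self.tf_id:
            raise ValidationError("tf_id must be non-empty")
        if self.state not in ("apo", "holo"):
            raise ValidationError(
                f"TF {self.tf_id!r}: state must be 'apo' or 'holo', got {self.state!r}"
            )
        if self.functional not in ("active", "inactive"):
            raise ValidationError(
                f"TF {self.tf_id!r}: functional must be 'active' or 'inactive'"
            )
        if self.state == "holo" and not self.effectors:
            raise ValidationError(
                f"TF {self.tf_id!r}: holo conformation must list >=1 effector"
            )
        if self.state == "apo" and self.effectors:
            raise ValidationError(
                f"TF {self.tf_id!r}: apo conformation must not list effectors"
            )


EFFECTS = ("activation", "repression", "dual")


@dataclass(frozen=True)
class RegulatoryInteraction:
    tf_id: str
    target_gene_id: str
    effect: str
    promoter_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.tf_id or not self.target_gene_id:
            raise ValidationError("tf_id and target_gene_id must be non-empty")
        if self.effect not in EFFECTS:
            raise ValidationError(
                f"interaction {self.tf_id}->{self.target_gene_id}: effect "
                f"{self.effect!r} not one of {EFFECTS}"
            )


class RegulatoryNetwork:
    """Signed TF → gene interaction network ("TF-gene" format)."""

    def __init__(self, interactions: Iterable[RegulatoryInteraction] = ()):
        unique: dict[tuple[str, str, Optional[str]], RegulatoryInteraction] = {}
        for it in interactions:
            unique[(it.tf_id, it.target_gene_id, it.promoter_id)] = it
        self._interactions = tuple(
            sorted(
                unique.values(),
                key=lambda it: (it.tf_id, it.target_gene_id, it.promoter_id or ""),
            )
        )
        self._targets: dict[str, set[str]] = {}
        self._regulators: dict[str, set[str]] = {}
        for it in self._interactions:
            self._targets.setdefault(it.tf_id, set()).add(it.target_gene_id)
            self._regulators.setdefault(it.target_gene_id, set()).add(it.tf_id)

    @property
    def interactions(self) -> tuple[RegulatoryInteraction, ...]:
        return self._interactions

    @property
    def tf_ids(self) -> frozenset[str]:
        return frozenset(self._targets)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self._regulators)

    def __len__(self) -> int:
        return len(self._interactions)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, RegulatoryNetwork)
            and self._interactions == other._interactions
        )

    def targets_of(self, tf_id: str) -> frozenset[str]:
        if tf_id not in self._targets:
            raise DatasetLookupError(f"TF {tf_id!r} not present in the network")
        return frozenset(self._targets[tf_id])

    def regulators_of(self, gene_id: str) -> frozenset[str]:
        return frozenset(self._regulators.get(gene_id, ()))


# ---------------------------------------------------------------------------
# assembled units and feedback results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GensorUnit:
    """An assembled genetic sensory-response unit.

    Elementary units are anchored at a single TF; complex units at the
    exact TF set jointly regulating a block of genes. ``effectors`` is the
    union over the anchor TFs' holo conformations and may be empty when no
    effector is known.
    """

    anchor: tuple[str, ...]
    regulated_genes: frozenset[str]
    products: tuple[GeneProduct, ...]
    reactions: tuple[Reaction, ...]
    effectors: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchor", tuple(sorted(set(self.anchor))))
        object.__setattr__(self, "regulated_genes", frozenset(self.regulated_genes))
        object.__setattr__(
            self, "products", tuple(sorted(self.products, key=lambda p: p.product_id))
        )
        object.__setattr__(
            self, "reactions", tuple(sorted(self.reactions, key=lambda r: r.reaction_id))
        )
        object.__setattr__(self, "effectors", frozenset(self.effectors))
        if not self.anchor:
            raise ValidationError("unit anchor must contain at least one TF")
        for r in self.reactions:
            if r.rxn_type == "tf_effector_binding":
                raise ValidationError(
                    f"unit {self.label}: effector-binding reaction "
                    f"{r.reaction_id!r} must not be part of the unit"
                )

    @property
    def is_complex(self) -> bool:
        return len(self.anchor) > 1

    @property
    def label(self) -> str:
        return "+".join(self.anchor)


class FeedbackStatus(str, enum.Enum):
    """Tiered outcome of the feedback scan, in decreasing priority."""

    DIRECT = "DIRECT"
    ENZYMATIC_TF = "ENZYMATIC_TF"
    CLASS_SUGGESTED = "CLASS_SUGGESTED"
    CASCADE = "CASCADE"
    NOT_FOUND = "NOT_FOUND"
    NO_EFFECTOR = "NO_EFFECTOR"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class Evidence:
    """One matched (reaction, compound) pair supporting a feedback call.

    ``ontology_path`` is empty for an exact compound match and otherwise
    runs from the effector to the matched compound along is-a edges.
    ``mediators`` lists intermediate TFs for cascade matches, with
    ``direction`` recording the regulatory hop orientation ("down" =
    the anchor regulates the mediator, "up" = the mediator regulates
    the anchor).
    """

    reaction_id: str
    compound_id: str
    ontology_path: tuple[str, ...] = ()
    mediators: tuple[str, ...] = ()
    direction: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "ontology_path", tuple(self.ontology_path))
        object.__setattr__(self, "mediators", tuple(self.mediators))


@dataclass(frozen=True)
class FeedbackResult:
    tf_id: str
    status: FeedbackStatus
    evidence: tuple[Evidence, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "evidence", tuple(self.evidence))
        object.__setattr__(self, "status", FeedbackStatus(self.status))
        if self.status is FeedbackStatus.NO_EFFECTOR and self.evidence:
            raise ValidationError(
                f"{self.tf_id}: NO_EFFECTOR results carry no evidence"
            )
        if self.status is FeedbackStatus.DIRECT and not any(
            not e.ontology_path and not e.mediators for e in self.evidence
        ):
            raise ValidationError(
                f"{self.tf_id}: DIRECT requires >=1 exact, unmediated evidence row"
            )


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """A fully loaded five-table dataset plus the compound dictionary."""

    network: RegulatoryNetwork
    conformations: tuple[TFConformation, ...]
    products: Mapping[str, GeneProduct]
    reactions: ReactionSet
    ontology: CompoundOntology
    compounds: Mapping[str, Compound] = field(default_factory=dict)
    genes: Mapping[str, Gene] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.conformations = tuple(self.conformations)
        self.products = dict(self.products)
        self.compounds = dict(self.compounds)
        self.genes = dict(self.genes)

    def effectors_of(self, tf_id: str) -> frozenset[str]:
        """Union of effector compounds over the TF's holo conformations."""
        eff: set[str] = set()
        for conf in self.conformations:
            if conf.tf_id == tf_id and conf.state == "holo":
                eff |= conf.effectors
        return frozenset(eff)

    @property
    def tf_ids(self) -> frozenset[str]:
        return self.network.tf_ids

    def encoding_genes_of(self, tf_id: str) -> frozenset[str]:
        """Genes encoding the TF's polypeptide(s).

        A product row with ``kind=regulator`` whose product_id equals the
        TF id maps the TF to its gene(s); a gene sharing the TF's id is
        accepted as a fallback so minimal networks remain analysable.
        """
        genes: set[str] = set()
        prod = self.products.get(tf_id)
        if prod is not None and prod.kind == "regulator":
            genes |= set(prod.gene_ids)
        if tf_id in self.network.gene_ids:
            genes.add(tf_id)
        return frozenset(genes)

    def tfs_encoded_by(self, gene_id: str) -> frozenset[str]:
        tfs = {
            p.product_id
            for p in self.products.values()
            if p.kind == "regulator" and gene_id in p.gene_ids
        }
        if gene_id in self.network.tf_ids:
            tfs.add(gene_id)
        return frozenset(tfs)

    def validate(self) -> None:
        """Cross-table referential checks; raises ValidationError on failure."""
        if self.compounds:
            for child, parent in self.ontology.edges:
                for cid in (child, parent):
                    if cid not in self.compounds:
                        raise ValidationError(
                            f"ontology references unknown compound {cid!r}"
                        )
            for conf in self.conformations:
                for eff in conf.effectors:
                    if eff not in self.compounds:
                        raise ValidationError(
                            f"TF {conf.tf_id!r}: unknown effector compound {eff!r}"
                        )
            for r in self.reactions:
                for cid in r.compounds:
                    if cid not in self.compounds:
                        raise ValidationError(
                            f"reaction {r.reaction_id!r}: unknown compound {cid!r}"
                        )
        tf_like = self.network.tf_ids | {
            c.tf_id for c in self.conformations
        }
        for r in self.reactions:
            if r.catalyst and r.catalyst not in self.products and r.catalyst not in tf_like:
                raise ValidationError(
                    f"reaction {r.reaction_id!r}: catalyst {r.catalyst!r} is "
                    "neither a gene product nor a known TF"
                )
        by_tf: dict[str, list[TFConformation]] = {}
        for conf in self.conformations:
            by_tf.setdefault(conf.tf_id, []).append(conf)
        for tf_id, confs in by_tf.items():
            if not any(c.functional == "active" for c in confs):
                raise ValidationError(
                    f"TF {tf_id!r}: no conformation is marked active"
                )
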