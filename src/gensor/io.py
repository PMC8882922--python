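"""Readers and writers for the flat-file tables and JSON serialisation.

The pinned dialect is tab-separated UTF-8 with fixed lowercase
snake_case headers and ``#`` comment lines; a ``column_map`` argument on
each reader aliases differently-named columns onto the pinned ones.
Multi-valued cells (gene lists, reaction participants, synonyms,
effector sets) are semicolon-separated.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .model import (
    Compound,
    CompoundOntology,
    Dataset,
    FeedbackResult,
    FormatError,
    Gene,
    GeneProduct,
    GensorUnit,
    Reaction,
    ReactionSet,
    RegulatoryInteraction,
    RegulatoryNetwork,
    TFConformation,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

DATASET_FILES = {
    "network": "network.tsv",
    "conformations": "conformations.tsv",
    "products": "products.tsv",
    "reactions": "reactions.tsv",
    "ontology": "ontology.tsv",
    "compounds": "compounds.tsv",
}


def _read_table(
    path: PathLike,
    required: Sequence[str],
    optional: Sequence[str] = (),
    column_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=list(required) + list(optional))
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in optional:
        if col not in frame.columns:
            frame[col] = ""
    return frame


def _split_multi(cell: str) -> tuple[str, ...]:
    return tuple(part.strip() for part in str(cell).split(";") if part.strip())


# ---------------------------------------------------------------------------
# compound dictionary and synonym resolution
# ---------------------------------------------------------------------------


def read_compounds(
    path: PathLike, column_map: Optional[Mapping[str, str]] = None
) -> dict[str, Compound]:
    frame = _read_table(path, ["compound_id", "name"], ["synonyms"], column_map)
    compounds: dict[str, Compound] = {}
    for row in frame.itertuples(index=False):
        cid = row.compound_id.strip()
        if cid in compounds:
            raise ValidationError(f"{path}: duplicate compound_id {cid!r}")
        compounds[cid] = Compound(cid, row.name.strip(), frozenset(_split_multi(row.synonyms)))
    return compounds


class CompoundResolver:
    """Maps ids, canonical names and synonyms onto compound_ids.

    Matching effectors against reaction participants is only computable
    when both sides use one canonical identifier per molecule, so every
    compound reference is normalised through this resolver at load time
    and raw strings never reach the scan algorithms.
    """

    def __init__(self, compounds: Mapping[str, Compound]):
        self._by_key: dict[str, str] = {}
        for c in compounds.values():
            for key in (c.compound_id, c.name, *c.synonyms):
                existing = self._by_key.setdefault(key.lower(), c.compound_id)
                if existing != c.compound_id:
                    logger.warning(
                        "ambiguous compound key %r (%s vs %s); keeping %s",
                        key, existing, c.compound_id, existing,
                    )

    def resolve(self, token: str) -> str:
        return self._by_key.get(token.strip().lower(), token.strip())


# ---------------------------------------------------------------------------
# table readers
# ---------------------------------------------------------------------------


def read_regulatory_network(
    path: PathLike, column_map: Optional[Mapping[str, str]] = None
) -> RegulatoryNetwork:
    """Read a TF-gene interaction table into a RegulatoryNetwork.

    Duplicate (tf, gene, promoter) rows are collapsed with a warning;
    an unknown effect value reports the offending row number.
    """
    frame = _read_table(
        path, ["tf_id", "target_gene_id", "effect"], ["promoter_id"], column_map
    )
    interactions = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        promoter = row.promoter_id.strip() or None
        key = (row.tf_id.strip(), row.target_gene_id.strip(), promoter or "")
        if key in seen:
            logger.warning("%s: duplicate interaction row collapsed: %s", path, key)
            continue
        seen.add(key)
        try:
            interactions.append(
                RegulatoryInteraction(
                    tf_id=key[0],
                    target_gene_id=key[1],
                    effect=row.effect.strip(),
                    promoter_id=promoter,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
    return RegulatoryNetwork(interactions)


def read_conformations(
    path: PathLike,
    resolver: Optional[CompoundResolver] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> tuple[TFConformation, ...]:
    """Read the curated apo/holo conformation table.

    Effector tokens are resolved against the compound dictionary when a
    resolver is supplied, so synonym spellings collapse onto one id.
    """
    frame = _read_table(
        path, ["tf_id", "state", "functional"], ["effector_ids"], column_map
    )
    confs = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        tokens = _split_multi(row.effector_ids)
        if resolver is not None:
            tokens = tuple(resolver.resolve(t) for t in tokens)
        try:
            confs.append(
                TFConformation(
                    tf_id=row.tf_id.strip(),
                    state=row.state.strip(),
                    effectors=frozenset(tokens),
                    functional=row.functional.strip(),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
    return tuple(confs)


def read_products(
    path: PathLike, column_map: Optional[Mapping[str, str]] = None
) -> dict[str, GeneProduct]:
    frame = _read_table(path, ["product_id", "gene_ids"], ["kind"], column_map)
    products: dict[str, GeneProduct] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        pid = row.product_id.strip()
        if pid in products:
            raise ValidationError(f"{path}: row {i}: duplicate product_id {pid!r}")
        try:
            products[pid] = GeneProduct(
                product_id=pid,
                gene_ids=_split_multi(row.gene_ids),
                kind=row.kind.strip() or "other",
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
    return products


def read_reactions(
    path: PathLike,
    resolver: Optional[CompoundResolver] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> ReactionSet:
    frame = _read_table(
        path,
        ["reaction_id", "reactants", "products"],
        ["catalyst", "rxn_type", "reversible"],
        column_map,
    )
    reactions = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        reactants = _split_multi(row.reactants)
        products = _split_multi(row.products)
        if resolver is not None:
            reactants = tuple(resolver.resolve(t) for t in reactants)
            products = tuple(resolver.resolve(t) for t in products)
        try:
            reactions.append(
                Reaction(
                    reaction_id=row.reaction_id.strip(),
                    reactants=reactants,
                    products=products,
                    catalyst=row.catalyst.strip() or None,
                    rxn_type=row.rxn_type.strip() or "enzymatic",
                    reversible=str(row.reversible).strip().lower()
                    in ("1", "true", "yes"),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
    return ReactionSet(reactions)


def read_ontology(
    path: PathLike,
    resolver: Optional[CompoundResolver] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> CompoundOntology:
    frame = _read_table(path, ["child_id", "parent_id"], (), column_map)
    edges = []
    for row in frame.itertuples(index=False):
        child, parent = row.child_id.strip(), row.parent_id.strip()
        if resolver is not None:
            child, parent = resolver.resolve(child), resolver.resolve(parent)
        edges.append((child, parent))
    return CompoundOntology(edges)


def load_dataset(directory: PathLike, validate: bool = True) -> Dataset:
    """Load the full five-table dataset (plus compounds.tsv) from a directory."""
    directory = Path(directory)
    compounds_path = directory / DATASET_FILES["compounds"]
    compounds: dict[str, Compound] = {}
    resolver = None
    if compounds_path.exists():
        compounds = read_compounds(compounds_path)
        resolver = CompoundResolver(compounds)
    dataset = Dataset(
        network=read_regulatory_network(directory / DATASET_FILES["network"]),
        conformations=read_conformations(
            directory / DATASET_FILES["conformations"], resolver
        ),
        products=read_products(directory / DATASET_FILES["products"]),
        reactions=read_reactions(directory / DATASET_FILES["reactions"], resolver),
        ontology=read_ontology(directory / DATASET_FILES["ontology"], resolver),
        compounds=compounds,
    )
    if validate:
        dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# writers and JSON serialisation
# ---------------------------------------------------------------------------


def unit_to_dict(unit: GensorUnit) -> dict:
    return {
        "anchor": list(unit.anchor),
        "regulated_genes": sorted(unit.regulated_genes),
        "products": [
            {"product_id": p.product_id, "gene_ids": list(p.gene_ids), "kind": p.kind}
            for p in unit.products
        ],
        "reactions": [
            {
                "reaction_id": r.reaction_id,
                "reactants": list(r.reactants),
                "products": list(r.products),
                "catalyst": r.catalyst,
                "rxn_type": r.rxn_type,
                "reversible": r.reversible,
            }
            for r in unit.reactions
        ],
        "effectors": sorted(unit.effectors),
    }


def unit_from_dict(payload: Mapping) -> GensorUnit:
    return GensorUnit(
        anchor=tuple(payload["anchor"]),
        regulated_genes=frozenset(payload["regulated_genes"]),
        products=tuple(
            GeneProduct(p["product_id"], tuple(p["gene_ids"]), p["kind"])
            for p in payload["products"]
        ),
        reactions=tuple(
            Reaction(
                r["reaction_id"],
                tuple(r["reactants"]),
                tuple(r["products"]),
                r.get("catalyst"),
                r.get("rxn_type", "enzymatic"),
                bool(r.get("reversible", False)),
            )
            for r in payload["reactions"]
        ),
        effectors=frozenset(payload["effectors"]),
    )


def write_unit_json(unit: GensorUnit, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(unit_to_dict(unit), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_unit_json(path: PathLike) -> GensorUnit:
    return unit_from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


REPORT_COLUMNS = [
    "tf_id",
    "status",
    "n_evidence",
    "matched_reactions",
    "matched_compounds",
    "ontology_paths",
    "mediators",
    "notes",
]


def result_to_row(result: FeedbackResult) -> dict[str, str]:
    return {
        "tf_id": result.tf_id,
        "status": str(result.status),
        "n_evidence": str(len(result.evidence)),
        "matched_reactions": ";".join(
            sorted({e.reaction_id for e in result.evidence})
        ),
        "matched_compounds": ";".join(
            sorted({e.compound_id for e in result.evidence})
        ),
        "ontology_paths": ";".join(
            sorted({">".join(e.ontology_path) for e in result.evidence if e.ontology_path})
        ),
        "mediators": ";".join(
            sorted({",".join(e.mediators) for e in result.evidence if e.mediators})
        ),
        "notes": result.notes,
    }


def write_report(results: Sequence[FeedbackResult], path: PathLike) -> None:
    """Write one TSV row per TF with status and an evidence summary."""
    frame = pd.DataFrame(
        [result_to_row(r) for r in results], columns=REPORT_COLUMNS
    )
    frame.to_csv(path, sep="\t", index=False)


def write_summary_json(summary: Mapping, path: PathLike) -> None:
    Path(path).write_text(
        json.dumps(dict(summary), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
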