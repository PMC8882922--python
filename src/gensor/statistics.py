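"""Descriptive statistics over the sensing layer and regulatory-logic rules.

Covers three summaries of the compendium: how many allosteric effectors
each TF binds, how many TFs converge on each promoter, how many TFs
anchor each complex unit — plus the qualitative four-panel logic of
activator/repressor × apo/holo regulation.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

from .model import GensorUnit, RegulatoryNetwork, TFConformation

__all__ = [
    "effectors_per_tf",
    "tfs_per_promoter",
    "tfs_per_complex_unit",
    "predict_response",
    "response_truth_table",
]


def effectors_per_tf(conformations: Iterable[TFConformation]) -> dict:
    """Histogram of distinct effector count per TF, with the mean.

    TFs without any holo conformation (no known effector) are excluded,
    matching how the effector compendium counts only metabolite-binding
    TFs.
    """
    per_tf: dict[str, set[str]] = {}
    for conf in conformations:
        if conf.state == "holo":
            per_tf.setdefault(conf.tf_id, set()).update(conf.effectors)
    counts = Counter(len(effs) for effs in per_tf.values())
    n_tfs = len(per_tf)
    mean = sum(k * v for k, v in counts.items()) / n_tfs if n_tfs else None
    return {"histogram": dict(sorted(counts.items())), "n_tfs": n_tfs, "mean": mean}


def tfs_per_promoter(network: RegulatoryNetwork) -> dict:
    """Histogram of distinct regulating TFs per promoter.

    Interactions lacking a promoter_id cannot be placed and are excluded;
    their count is reported as coverage information.
    """
    per_promoter: dict[str, set[str]] = {}
    n_missing = 0
    for it in network.interactions:
        if it.promoter_id is None:
            n_missing += 1
            continue
        per_promoter.setdefault(it.promoter_id, set()).add(it.tf_id)
    counts = Counter(len(tfs) for tfs in per_promoter.values())
    n_promoters = len(per_promoter)
    n_multi = sum(v for k, v in counts.items() if k >= 2)
    return {
        "histogram": dict(sorted(counts.items())),
        "n_promoters": n_promoters,
        "n_interactions_without_promoter": n_missing,
        "fraction_multi_tf": n_multi / n_promoters if n_promoters else None,
    }


def tfs_per_complex_unit(units: Sequence[GensorUnit]) -> dict:
    """Histogram of anchor-set size over complex units."""
    counts = Counter(len(u.anchor) for u in units)
    return {"histogram": dict(sorted(counts.items())), "n_units": len(units)}


def predict_response(
    mode: str, active_state: str, effector_present: bool
) -> str:
    """Direction of transcription for one regulatory-logic combination.

    The TF is in its DNA-binding-active form exactly when its state
    matches the effector's presence (holo needs the effector bound, apo
    needs it absent). An active activator or an inactive repressor means
    transcription goes up; otherwise down. E.g. a holo activator with
    effector present activates (CRP–cAMP), an apo repressor with
    effector present derepresses (LacI–allolactose).
    """
    if mode not in ("activator", "repressor"):
        raise ValueError(f"mode must be 'activator' or 'repressor', got {mode!r}")
    if active_state not in ("apo", "holo"):
        raise ValueError(f"active_state must be 'apo' or 'holo', got {active_state!r}")
    active = (active_state == "holo") == bool(effector_present)
    increased = active == (mode == "activator")
    return "increased" if increased else "decreased"


def response_truth_table() -> list[dict]:
    """The full 8-row enumeration of predict_response."""
    rows = []
    for mode in ("activator", "repressor"):
        for active_state in ("apo", "holo"):
            for effector_present in (False, True):
                rows.append(
                    {
                        "mode": mode,
                        "active_state": active_state,
                        "effector_present": effector_present,
                        "transcription": predict_response(
                            mode, active_state, effector_present
                        ),
                    }
                )
    return rows
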