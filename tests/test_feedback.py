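"""Tiered feedback detection: each tier, priority, summary, invariants."""

import random

import pytest

from gensor.assembly import assemble_all, unit_for
from gensor.feedback import (
    FeedbackConfig,
    detect_all,
    detect_feedback,
    scan_cascade,
    scan_class,
    scan_direct,
    scan_enzymatic_tf,
    summarize,
)
from gensor.model import (
    CompoundOntology,
    Dataset,
    FeedbackStatus,
    GensorUnit,
    Reaction,
    ReactionSet,
)
from gensor.synthetic import GeneratorConfig, build_dataset

from conftest import random_dataset


def _units(dataset):
    return assemble_all(
        dataset.network, dataset.products, dataset.reactions, dataset.conformations
    )


class TestScanDirect:
    def test_laci_allolactose_direct(self, fixture_dataset):
        result = scan_direct(unit_for("LacI", fixture_dataset))
        assert result.status is FeedbackStatus.DIRECT
        assert any(
            e.reaction_id == "rx_lacZ" and e.compound_id == "allolactose"
            for e in result.evidence
        )
        assert all(not e.ontology_path and not e.mediators for e in result.evidence)

    def test_empty_reaction_set_not_found(self):
        unit = GensorUnit(("X",), frozenset(), (), (), frozenset({"eff"}))
        assert scan_direct(unit).status is FeedbackStatus.NOT_FOUND

    def test_no_effector_short_circuits(self):
        unit = GensorUnit(("X",), frozenset(), (), ())
        result = scan_direct(unit)
        assert result.status is FeedbackStatus.NO_EFFECTOR
        assert result.evidence == ()

    def test_marr_salicylate_untouched(self, fixture_dataset):
        assert scan_direct(unit_for("MarR", fixture_dataset)).status is FeedbackStatus.NOT_FOUND


class TestScanClass:
    def test_galr_subclass_match_path_length_one(self, fixture_dataset):
        result = scan_class(unit_for("GalR", fixture_dataset), fixture_dataset.ontology)
        assert result.status is FeedbackStatus.CLASS_SUGGESTED
        (ev,) = result.evidence
        assert ev.ontology_path == ("d-galactose", "alpha-d-galactopyranose")

    def test_effector_without_ontology_neighbours(self, fixture_dataset):
        result = scan_class(unit_for("MarR", fixture_dataset), fixture_dataset.ontology)
        assert result.status is FeedbackStatus.NOT_FOUND

    def test_exact_match_not_reported_at_class_tier(self, fixture_dataset):
        result = scan_class(unit_for("LacI", fixture_dataset), fixture_dataset.ontology)
        assert all(e.compound_id != "allolactose" for e in result.evidence)

    def test_max_hops_limits_reach(self):
        ontology = CompoundOntology([("c1", "c2"), ("c2", "c3")])
        rxn = Reaction("r", ("c3",), ("x",), "P")
        unit = GensorUnit(("T",), frozenset({"g"}), (), (rxn,), frozenset({"c1"}))
        assert scan_class(unit, ontology, max_hops=1).status is FeedbackStatus.NOT_FOUND
        assert scan_class(unit, ontology, max_hops=2).status is FeedbackStatus.CLASS_SUGGESTED

    def test_matches_transitive_closure_oracle(self):
        from bruteforce import brute_detect

        rng = random.Random(5)
        for _ in range(30):
            dataset = random_dataset(rng)
            units = _units(dataset)
            for tf, unit in units.items():
                result = scan_class(unit, dataset.ontology)
                status, hits = brute_detect(
                    tf, dataset, tiers=("class",)
                )
                assert result.status.value == status
                assert {(e.reaction_id, e.compound_id) for e in result.evidence} == hits


class TestScanCascade:
    def test_rhar_downstream_via_rhas_with_class_match(self, fixture_dataset):
        result = scan_cascade(
            "RhaR",
            fixture_dataset.network,
            _units(fixture_dataset),
            fixture_dataset.ontology,
            tf_encoding={
                tf: fixture_dataset.encoding_genes_of(tf)
                for tf in fixture_dataset.tf_ids
            },
        )
        assert result.status is FeedbackStatus.CASCADE
        (ev,) = result.evidence
        assert ev.mediators == ("RhaS",) and ev.direction == "down"
        assert ev.ontology_path == ("alpha-l-rhamnopyranose", "l-rhamnose")

    @pytest.mark.parametrize(
        "direction,expected",
        [("up", FeedbackStatus.CASCADE), ("down", FeedbackStatus.NOT_FOUND)],
    )
    def test_alls_requires_upstream_direction(self, fixture_dataset, direction, expected):
        result = scan_cascade(
            "AllS",
            fixture_dataset.network,
            _units(fixture_dataset),
            fixture_dataset.ontology,
            direction=direction,
            tf_encoding={
                tf: fixture_dataset.encoding_genes_of(tf)
                for tf in fixture_dataset.tf_ids
            },
        )
        assert result.status is expected

    def test_depth_zero_rejected(self, fixture_dataset):
        with pytest.raises(ValueError):
            scan_cascade("LacI", fixture_dataset.network, _units(fixture_dataset), depth=0)

    def test_isolated_tf_not_found(self, fixture_dataset):
        result = scan_cascade(
            "MarR", fixture_dataset.network, _units(fixture_dataset)
        )
        assert result.status is FeedbackStatus.NOT_FOUND

    def test_depth_monotonicity_of_evidence(self):
        """Evidence at depth d is a subset of evidence at depth d+1."""
        rng = random.Random(13)
        checked = 0
        for _ in range(40):
            dataset = random_dataset(rng)
            units = _units(dataset)
            encoding = {
                tf: dataset.encoding_genes_of(tf) for tf in dataset.tf_ids
            }
            for tf in units:
                if not units[tf].effectors:
                    continue
                r1 = scan_cascade(
                    tf, dataset.network, units, dataset.ontology,
                    depth=1, tf_encoding=encoding,
                )
                r2 = scan_cascade(
                    tf, dataset.network, units, dataset.ontology,
                    depth=2, tf_encoding=encoding,
                )
                assert set(r1.evidence) <= set(r2.evidence)
                checked += 1
        assert checked > 20


class TestScanEnzymaticTF:
    def test_bira_self_catalysis(self, fixture_dataset):
        result = scan_enzymatic_tf(
            "BirA", unit_for("BirA", fixture_dataset), fixture_dataset.reactions
        )
        assert result.status is FeedbackStatus.ENZYMATIC_TF
        assert result.evidence[0].reaction_id == "rx_birA"

    def test_dnaa_atp_hydrolysis(self, fixture_dataset):
        result = scan_enzymatic_tf(
            "DnaA", unit_for("DnaA", fixture_dataset), fixture_dataset.reactions
        )
        assert result.status is FeedbackStatus.ENZYMATIC_TF

    def test_tf_without_self_reactions(self, fixture_dataset):
        result = scan_enzymatic_tf(
            "GalR", unit_for("GalR", fixture_dataset), fixture_dataset.reactions
        )
        assert result.status is FeedbackStatus.NOT_FOUND

    def test_binding_reaction_never_counts(self, fixture_dataset):
        # LacI's only self-"catalysed" row is the effector-binding reaction
        result = scan_enzymatic_tf(
            "LacI", unit_for("LacI", fixture_dataset), fixture_dataset.reactions
        )
        assert result.status is FeedbackStatus.NOT_FOUND


class TestDetectFeedback:
    def test_direct_wins_regardless_of_other_tiers(self, fixture_dataset):
        for tiers in (("direct",), ("direct", "class"), ("direct", "enzymatic", "class", "cascade")):
            result = detect_feedback(
                "LacI", fixture_dataset, FeedbackConfig(tiers=tiers)
            )
            assert result.status is FeedbackStatus.DIRECT

    def test_pyrr_like_uncharacterised_transporter(self, fixture_dataset):
        assert (
            detect_feedback("PyrR", fixture_dataset).status is FeedbackStatus.NOT_FOUND
        )

    def test_unknown_tf_raises(self, fixture_dataset):
        from gensor.model import DatasetLookupError

        with pytest.raises(DatasetLookupError):
            detect_feedback("NoSuchTF", fixture_dataset)

    def test_tier_toggles_respected(self, fixture_dataset):
        only_direct = detect_feedback(
            "GalR", fixture_dataset, FeedbackConfig(tiers=("direct",))
        )
        assert only_direct.status is FeedbackStatus.NOT_FOUND
        with_class = detect_feedback(
            "GalR", fixture_dataset, FeedbackConfig(tiers=("direct", "class"))
        )
        assert with_class.status is FeedbackStatus.CLASS_SUGGESTED

    def test_tier_monotonicity_never_downgrades(self):
        """Adding a tier preserves DIRECT results and never lowers priority."""
        rank = {
            FeedbackStatus.DIRECT: 4,
            FeedbackStatus.ENZYMATIC_TF: 3,
            FeedbackStatus.CLASS_SUGGESTED: 2,
            FeedbackStatus.CASCADE: 1,
            FeedbackStatus.NOT_FOUND: 0,
            FeedbackStatus.NO_EFFECTOR: 0,
        }
        chains = [
            ("direct",),
            ("direct", "enzymatic"),
            ("direct", "enzymatic", "class"),
            ("direct", "enzymatic", "class", "cascade"),
        ]
        rng = random.Random(99)
        for _ in range(25):
            dataset = random_dataset(rng)
            for tf in dataset.network.tf_ids:
                previous = None
                for tiers in chains:
                    result = detect_feedback(
                        tf, dataset, FeedbackConfig(tiers=tiers)
                    )
                    if previous is not None:
                        assert rank[result.status] >= rank[previous.status]
                        if previous.status is FeedbackStatus.DIRECT:
                            assert result == previous
                    previous = result

    def test_adding_binding_reaction_is_a_noop(self, planted):
        """An extra effector-TF binding reaction changes no result."""
        dataset, _ = planted
        base = detect_all(dataset)
        extra = Reaction(
            "rx_extra_binding",
            ("eff0000",),
            ("cpx_extra",),
            catalyst="TF0000",
            rxn_type="tf_effector_binding",
        )
        compounds = dict(dataset.compounds)
        from gensor.model import Compound

        compounds["cpx_extra"] = Compound("cpx_extra", "extra complex")
        modified = Dataset(
            network=dataset.network,
            conformations=dataset.conformations,
            products=dataset.products,
            reactions=ReactionSet(list(dataset.reactions) + [extra]),
            ontology=dataset.ontology,
            compounds=compounds,
        )
        assert detect_all(modified) == base

    def test_reversing_reversible_reactions_is_a_noop(self, planted):
        """Direction-blind matching: swapping reactant/product lists of
        reversible reactions changes no result."""
        dataset, _ = planted
        flipped = ReactionSet(
            [r.reversed() if r.reversible else r for r in dataset.reactions]
        )
        modified = Dataset(
            network=dataset.network,
            conformations=dataset.conformations,
            products=dataset.products,
            reactions=flipped,
            ontology=dataset.ontology,
            compounds=dataset.compounds,
        )
        base = [(r.tf_id, r.status) for r in detect_all(dataset)]
        after = [(r.tf_id, r.status) for r in detect_all(modified)]
        assert base == after


class TestSummarize:
    def test_headline_fraction_71_of_87(self):
        from gensor.model import Evidence, FeedbackResult

        results = (
            [FeedbackResult(f"tf{i}", FeedbackStatus.DIRECT, (Evidence("r", "c"),)) for i in range(71)]
            + [FeedbackResult(f"nf{i}", FeedbackStatus.NOT_FOUND) for i in range(16)]
        )
        summary = summarize(results)
        assert summary["n_with_effector"] == 87
        assert summary["percent_direct"] == 81.6
        assert summary["percent_direct_int"] == 82
        assert len(summary["not_found_tfs"]) == 16

    def test_empty_input_not_applicable(self):
        summary = summarize([])
        assert summary["percent_direct"] is None
        assert all(v == 0 for v in summary["counts"].values())

    def test_counts_match_planted_composition(self, planted):
        from conftest import PLANTED_COUNTS

        dataset, ground_truth = planted
        planted_tfs = {row["tf_id"] for row in ground_truth}
        results = [r for r in detect_all(dataset) if r.tf_id in planted_tfs]
        summary = summarize(results)
        assert summary["counts"]["DIRECT"] == PLANTED_COUNTS["DIRECT"]
        assert summary["counts"]["CLASS_SUGGESTED"] == PLANTED_COUNTS["CLASS"]
        assert (
            summary["counts"]["CASCADE"]
            == PLANTED_COUNTS["CASCADE_DOWN"] + PLANTED_COUNTS["CASCADE_UP"]
        )
        assert summary["counts"]["ENZYMATIC_TF"] == PLANTED_COUNTS["ENZYMATIC_TF"]
        assert summary["counts"]["NOT_FOUND"] == PLANTED_COUNTS["NONE"]

    def test_direct_tier_false_positive_rate_zero_on_negatives(self):
        """With only NONE planted, the direct tier never fires."""
        config = GeneratorConfig(n_tfs=12, category_counts={"NONE": 12})
        for seed in range(5):
            dataset, ground_truth = build_dataset(config, seed)
            planted_tfs = {row["tf_id"] for row in ground_truth}
            results = [
                r
                for r in detect_all(dataset, FeedbackConfig(tiers=("direct",)))
                if r.tf_id in planted_tfs
            ]
            assert all(r.status is FeedbackStatus.NOT_FOUND for r in results)
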