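"""Effector/promoter/complex-unit distributions and the regulatory-logic rule."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gensor.model import (
    RegulatoryInteraction,
    RegulatoryNetwork,
    TFConformation,
)
from gensor.statistics import (
    effectors_per_tf,
    predict_response,
    response_truth_table,
    tfs_per_complex_unit,
    tfs_per_promoter,
)


def conf(tf, *effectors):
    rows = [TFConformation(tf, "apo", frozenset(), "active")]
    if effectors:
        rows.append(TFConformation(tf, "holo", frozenset(effectors), "inactive"))
    return rows


class TestEffectorsPerTF:
    def test_hand_enumerated_histogram(self):
        confs = (
            conf("A", "e1")
            + conf("B", "e2")
            + conf("C", "e3", "e4")
            + conf("D", "e5", "e6", "e7")
        )
        out = effectors_per_tf(confs)
        assert out["histogram"] == {1: 2, 2: 1, 3: 1}
        assert out["mean"] == pytest.approx(1.75)

    def test_all_single_effector_degenerate(self):
        confs = conf("A", "x") + conf("B", "y")
        out = effectors_per_tf(confs)
        assert out["histogram"] == {1: 2}
        assert out["mean"] == 1.0

    def test_apo_only_tfs_excluded(self):
        confs = conf("A", "x") + conf("NoEff")
        out = effectors_per_tf(confs)
        assert out["n_tfs"] == 1

    def test_mass_conservation(self, planted):
        dataset, _ = planted
        out = effectors_per_tf(dataset.conformations)
        assert sum(out["histogram"].values()) == out["n_tfs"]


class TestTFsPerPromoter:
    def test_hand_enumerated(self):
        net = RegulatoryNetwork(
            [
                RegulatoryInteraction("A", "g1", "activation", "p1"),
                RegulatoryInteraction("A", "g2", "activation", "p2"),
                RegulatoryInteraction("B", "g2", "activation", "p2"),
                RegulatoryInteraction("A", "g3", "activation", "p3"),
                RegulatoryInteraction("B", "g3", "activation", "p3"),
                RegulatoryInteraction("C", "g3", "activation", "p3"),
            ]
        )
        out = tfs_per_promoter(net)
        assert out["histogram"] == {1: 1, 2: 1, 3: 1}
        assert out["fraction_multi_tf"] == pytest.approx(2 / 3)

    def test_single_tf_network_all_count_one(self):
        net = RegulatoryNetwork(
            [
                RegulatoryInteraction("A", "g1", "activation", "p1"),
                RegulatoryInteraction("A", "g2", "activation", "p2"),
            ]
        )
        out = tfs_per_promoter(net)
        assert set(out["histogram"]) == {1}

    def test_missing_promoters_counted_in_coverage(self):
        net = RegulatoryNetwork(
            [
                RegulatoryInteraction("A", "g1", "activation", "p1"),
                RegulatoryInteraction("A", "g2", "activation", None),
            ]
        )
        out = tfs_per_promoter(net)
        assert out["n_interactions_without_promoter"] == 1
        assert out["n_promoters"] == 1

    def test_mass_conservation(self, planted):
        dataset, _ = planted
        out = tfs_per_promoter(dataset.network)
        assert sum(out["histogram"].values()) == out["n_promoters"]


class TestTFsPerComplexUnit:
    def test_partition_example(self):
        from gensor.assembly import assemble_complex_units
        from gensor.model import ReactionSet

        net = RegulatoryNetwork(
            [
                RegulatoryInteraction("A", "g1", "activation"),
                RegulatoryInteraction("B", "g1", "activation"),
                RegulatoryInteraction("A", "g2", "activation"),
                RegulatoryInteraction("B", "g2", "activation"),
                RegulatoryInteraction("A", "g3", "activation"),
            ]
        )
        units = assemble_complex_units(net, {}, ReactionSet(), include_singletons=True)
        out = tfs_per_complex_unit(units)
        assert out["histogram"] == {1: 1, 2: 1}
        assert sum(out["histogram"].values()) == out["n_units"]


class TestPredictResponse:
    # full 8-row enumeration of the activator/repressor x apo/holo rule:
    # the TF is active iff (active_state == holo) == effector_present;
    # transcription rises iff (active and activator) or (inactive and repressor)
    TRUTH = {
        ("activator", "holo", True): "increased",
        ("activator", "holo", False): "decreased",
        ("activator", "apo", True): "decreased",
        ("activator", "apo", False): "increased",
        ("repressor", "holo", True): "decreased",
        ("repressor", "holo", False): "increased",
        ("repressor", "apo", True): "increased",  # LacI derepression
        ("repressor", "apo", False): "decreased",
    }

    @pytest.mark.parametrize("key,expected", sorted(TRUTH.items()))
    def test_truth_table(self, key, expected):
        assert predict_response(*key) == expected

    def test_response_truth_table_enumerates_all_eight(self):
        rows = response_truth_table()
        assert len(rows) == 8
        for row in rows:
            key = (row["mode"], row["active_state"], row["effector_present"])
            assert row["transcription"] == self.TRUTH[key]

    @given(
        mode=st.sampled_from(["activator", "repressor"]),
        active_state=st.sampled_from(["apo", "holo"]),
        effector_present=st.booleans(),
    )
    @settings(derandomize=True)
    def test_mode_state_double_flip_symmetry(self, mode, active_state, effector_present):
        """Flipping both mode and active_state leaves the output unchanged."""
        flip_mode = "repressor" if mode == "activator" else "activator"
        flip_state = "holo" if active_state == "apo" else "apo"
        assert predict_response(mode, active_state, effector_present) == predict_response(
            flip_mode, flip_state, effector_present
        )

    @given(
        mode=st.sampled_from(["activator", "repressor"]),
        active_state=st.sampled_from(["apo", "holo"]),
        effector_present=st.booleans(),
    )
    @settings(derandomize=True)
    def test_effector_flip_antisymmetry(self, mode, active_state, effector_present):
        """Toggling effector presence flips the predicted direction."""
        a = predict_response(mode, active_state, effector_present)
        b = predict_response(mode, active_state, not effector_present)
        assert {a, b} == {"increased", "decreased"}

    def test_invalid_enum_rejected(self):
        with pytest.raises(ValueError):
            predict_response("dual", "apo", True)
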