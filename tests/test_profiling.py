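import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_cohort
from senseprint.presets import get_preset
from senseprint.profiling import (
    DEFAULT_BANDS,
    ModalityBands,
    adjusted_rand,
    categorical_composition,
    characterize_clusters,
    cross_cluster_table,
    match_clusters,
    severity_label,
)
from senseprint.recovery import run_recovery
from senseprint.synthetic import attach_demographics, generate_cohort


class TestSeverityLabel:
    @pytest.mark.parametrize(
        "modality, score, expected",
        [
            ("tdt", 80.0, "none"),       # above the just-noticeable cut
            ("tdt", 73.1, "mild"),       # boundary is impaired
            ("tdt", 73.2, "none"),
            ("tdt", 30.0, "extreme"),    # at/below extreme threshold
            ("tdt", 33.3, "extreme"),
            ("tdt", 33.4, "severe"),
            ("wpst", 11.3, "mild"),      # boundary is impaired
            ("wpst", 11.2, "none"),
            ("wpst", 36.0, "extreme"),
            ("wpst", 35.9, "severe"),
            ("ftort", 42.0, "none"),     # maximum score
            ("ftort", 39.5, "mild"),
            ("ftort", 1.5, "extreme"),
        ],
    )
    def test_published_threshold_behaviour(self, modality, score, expected):
        assert severity_label(score, getattr(DEFAULT_BANDS, modality)) == expected

    def test_score_outside_instrument_range_rejected(self):
        with pytest.raises(ValueError):
            severity_label(101.0, DEFAULT_BANDS.tdt)

    def test_band_edges_take_the_more_severe_label(self):
        # TDT interior (33.3, 73.1] splits at 59.833.. and 46.566..
        width = (73.1 - 33.3) / 3
        assert severity_label(73.1 - width + 1e-9, DEFAULT_BANDS.tdt) == "mild"
        assert severity_label(73.1 - width, DEFAULT_BANDS.tdt) == "moderate"
        assert severity_label(73.1 - 2 * width, DEFAULT_BANDS.tdt) == "severe"

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        lo=st.floats(0, 100, allow_nan=False),
        delta=st.floats(0.0, 50, allow_nan=False),
    )
    def test_monotone_worse_score_never_improves_label(self, lo, delta):
        order = {s: i for i, s in enumerate(["none", "mild", "moderate", "severe", "extreme"])}
        hi = min(lo + delta, 100.0)
        # TDT: lower is worse
        sev_hi = severity_label(hi, DEFAULT_BANDS.tdt)
        sev_lo = severity_label(lo, DEFAULT_BANDS.tdt)
        assert order[sev_lo] >= order[sev_hi]
        # WPST: higher is worse
        w_lo, w_hi = 0.4 * lo, 0.4 * hi
        assert order[severity_label(w_hi, DEFAULT_BANDS.wpst)] >= order[
            severity_label(w_lo, DEFAULT_BANDS.wpst)
        ]

    def test_misordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ModalityBands("higher_better", just_noticeable=30.0, extreme=70.0,
                          bounds=(0, 100))


def labelled(cohort, labels):
    return pd.Series(labels, index=cohort["participant_id"], name="cluster")


class TestCharacterizeClusters:
    def test_single_cluster_equals_whole_sample_stats(self):
        cohort = make_cohort({"tdt_contra": [70.0, 50, 30, 90],
                              "wpst_contra": [8.0, 12, 30, 5]})
        report = characterize_clusters(cohort, labelled(cohort, [0] * 4),
                                       score_columns=["tdt_contra", "wpst_contra"])
        tdt = report[report["measure"] == "tdt_contra"].iloc[0]
        assert tdt["n"] == 4 and tdt["pct"] == 100.0
        assert tdt["mean"] == pytest.approx(60.0)
        assert tdt["sd"] == pytest.approx(np.std([70, 50, 30, 90], ddof=1))

    def test_hand_built_two_cluster_stats(self):
        cohort = make_cohort({"tdt_contra": [80.0, 76, 40, 44]})
        report = characterize_clusters(cohort, labelled(cohort, [0, 0, 1, 1]),
                                       score_columns=["tdt_contra"])
        c0 = report[report["cluster"] == 0].iloc[0]
        c1 = report[report["cluster"] == 1].iloc[0]
        assert c0["mean"] == pytest.approx(78.0)
        assert c0["sd"] == pytest.approx(np.sqrt(8.0))
        assert c0["severity"] == "none"
        assert c1["mean"] == pytest.approx(42.0)
        assert c1["severity"] == "severe"
        assert c0["pct"] + c1["pct"] == pytest.approx(100.0)

    def test_generated_cohort_true_label_means_near_generating_means(self):
        preset = get_preset("table3a")
        cohort = generate_cohort(preset["spec"], 2000, seed=42)
        labels = labelled(cohort, cohort["true_component"].astype(int).to_numpy())
        report = characterize_clusters(cohort, labels,
                                       score_columns=list(preset["spec"].features))
        for ci, comp in enumerate(preset["spec"].components):
            for f in preset["spec"].features:
                row = report[(report["cluster"] == ci) & (report["measure"] == f)].iloc[0]
                se = comp.sds[f] / np.sqrt(row["n"])
                # 4 SE + truncation allowance
                assert abs(row["mean"] - comp.means[f]) < 4 * se + 0.6

    def test_report_means_equal_direct_recomputation(self):
        rng = np.random.default_rng(0)
        cohort = make_cohort({"tdt_contra": rng.uniform(5, 95, 30)})
        lab = rng.integers(0, 3, 30)
        report = characterize_clusters(cohort, labelled(cohort, lab),
                                       score_columns=["tdt_contra"])
        for c in range(3):
            row = report[report["cluster"] == c].iloc[0]
            direct = cohort.loc[lab == c, "tdt_contra"]
            assert row["mean"] == pytest.approx(direct.mean(), abs=1e-9)
            assert row["sd"] == pytest.approx(direct.std(ddof=1), abs=1e-9)


class TestCategoricalComposition:
    def test_uniform_level_is_total(self):
        cohort = make_cohort({"tdt_contra": [50.0] * 4}, dominant_hand=["R"] * 4)
        comp = categorical_composition(cohort, labelled(cohort, [0, 0, 1, 1]),
                                       "dominant_hand")
        assert (comp["level"] == "R").all()
        assert (comp["pct"] == 100.0).all()

    def test_hand_tally(self):
        cohort = make_cohort(
            {"tdt_contra": [50.0] * 10},
            dominant_hand=["R", "R", "L", "R", "unknown", "L", "L", "R", "R", "R"],
        )
        lab = [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]
        comp = categorical_composition(cohort, labelled(cohort, lab), "dominant_hand")
        c0 = comp[comp["cluster"] == 0].set_index("level")["count"]
        c1 = comp[comp["cluster"] == 1].set_index("level")["count"]
        assert c0["R"] == 3 and c0["L"] == 1 and c0["unknown"] == 1
        assert c1["R"] == 3 and c1["L"] == 2

    def test_per_component_generator_rates_show_up_in_composition(self):
        preset = get_preset("table5b")
        cohort = generate_cohort(preset["spec"], 400, seed=1)
        cohort = attach_demographics(cohort, preset["demographics"], seed=2)
        labels = labelled(cohort, cohort["true_component"].astype(int).to_numpy())
        comp = categorical_composition(cohort, labels, "dominant_affected")
        middle = comp[(comp["cluster"] == 1) & (comp["level"] == "yes")].iloc[0]
        assert middle["pct"] == 100.0

    def test_unknown_variable_rejected(self):
        cohort = make_cohort({"tdt_contra": [50.0]})
        with pytest.raises(KeyError):
            categorical_composition(cohort, labelled(cohort, [0]), "lesion_side")


class TestCrossClusterTable:
    def test_identical_labelings_are_diagonal(self):
        cohort = make_cohort({"tdt_contra": [50.0] * 6})
        a = labelled(cohort, [0, 0, 1, 1, 2, 2])
        t = cross_cluster_table(a, a)
        assert np.array_equal(np.diag(np.diag(t.to_numpy())), t.to_numpy())

    def test_constant_b_holds_all_a_sizes_in_one_row(self):
        cohort = make_cohort({"tdt_contra": [50.0] * 5})
        a = labelled(cohort, [0, 0, 1, 2, 2])
        b = labelled(cohort, [7] * 5)
        t = cross_cluster_table(a, b)
        assert t.shape == (1, 3)
        assert t.loc[7].tolist() == [2, 1, 2]

    def test_marginals_reconcile_on_random_instance(self):
        rng = np.random.default_rng(5)
        cohort = make_cohort({"tdt_contra": [50.0] * 20})
        a = labelled(cohort, rng.integers(0, 4, 20))
        b = labelled(cohort, rng.integers(0, 3, 20))
        t = cross_cluster_table(a, b)
        assert t.to_numpy().sum() == 20
        for cb, size in b.value_counts().items():
            assert t.loc[cb].sum() == size
        for ca, size in a.value_counts().items():
            assert t[ca].sum() == size
        # brute-force pair counting
        for cb in t.index:
            for ca in t.columns:
                assert t.loc[cb, ca] == sum(
                    (a[pid] == ca) and (b[pid] == cb) for pid in a.index
                )

    def test_mismatched_participant_sets_rejected(self):
        cohort = make_cohort({"tdt_contra": [50.0] * 3})
        a = labelled(cohort, [0, 1, 1])
        b = a.iloc[:2]
        with pytest.raises(ValueError):
            cross_cluster_table(a, b)


class TestMatchClusters:
    def test_identity_on_identical_sets(self):
        c = np.array([[0.0, 0], [1, 1], [2, 2]])
        assert match_clusters(c, c).tolist() == [0, 1, 2]

    def test_swapped_pair_is_a_transposition(self):
        ref = np.array([[0.0, 0], [1, 1]])
        est = ref[[1, 0]]
        assert match_clusters(est, ref).tolist() == [1, 0]

    def test_noisy_copies_recover_the_construction(self):
        rng = np.random.default_rng(3)
        ref = rng.uniform(0, 100, (3, 2))
        shuffle = np.array([2, 0, 1])
        est = ref[shuffle] + rng.normal(0, 0.5, (3, 2))
        assert match_clusters(est, ref).tolist() == shuffle.tolist()

    def test_unequal_k_rejected(self):
        with pytest.raises(ValueError):
            match_clusters(np.zeros((2, 2)), np.zeros((3, 2)))


class TestAdjustedRand:
    def test_identical_labelings_score_one(self):
        assert adjusted_rand([0, 0, 1, 1, 2], [5, 5, 9, 9, 1]) == pytest.approx(1.0)

    def test_six_point_instance_matches_pair_counting(self):
        a = [0, 0, 0, 1, 1, 1]
        b = [0, 0, 1, 1, 2, 2]
        # pair-counting oracle: ARI = (sum_ij C(n_ij,2) - E) / (M - E)
        from math import comb
        n = 6
        nij = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
        sum_ij = sum(comb(v, 2) for v in nij.ravel())
        sum_a = sum(comb(v, 2) for v in nij.sum(1))
        sum_b = sum(comb(v, 2) for v in nij.sum(0))
        expected_idx = sum_a * sum_b / comb(n, 2)
        oracle = (sum_ij - expected_idx) / ((sum_a + sum_b) / 2 - expected_idx)
        assert adjusted_rand(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_independent_labelings_score_near_zero(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 3, 5000)
        b = rng.integers(0, 3, 5000)
        assert abs(adjusted_rand(a, b)) < 0.05

    def test_mismatched_sets_rejected(self):
        a = pd.Series([0, 1], index=["x", "y"])
        b = pd.Series([0, 1], index=["x", "z"])
        with pytest.raises(ValueError):
            adjusted_rand(a, b)


class TestEndToEndRecoverySanity:
    """One-seed smoke checks that the full pipeline recovers mixture
    structure far above chance; the 20-seed median benchmarks live in the
    acceptance suite."""

    @pytest.mark.parametrize("preset_name", ["table3a", "table3c", "table4a"])
    def test_recovery_is_far_above_chance(self, preset_name):
        p = get_preset(preset_name)
        rec = run_recovery(p["spec"], p["n"], p["k"], seed=1)
        assert rec["ari"] > 0.3
        assert sum(c["n"] for c in rec["components"].values()) == rec["n"]

    def test_recovery_is_deterministic(self):
        p = get_preset("table3a")
        a = run_recovery(p["spec"], p["n"], p["k"], seed=9)
        b = run_recovery(p["spec"], p["n"], p["k"], seed=9)
        assert np.array_equal(a["labels"], b["labels"])
        assert a["components"] == b["components"]
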