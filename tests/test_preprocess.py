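"""Normalization and differential-expression chain."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings, strategies as hst

import pbarray as pb
from pbarray.errors import DataError
from pbarray.preprocess import _pooled_ttest

from conftest import make_matrix, sheet
from oracles import bh_stepup, quantile_linear


def two_array_sheet():
    rows = [
        {"sample_id": "a", "species": "tolerant", "tissue": "roots",
         "treatment": "control", "replicate": 1},
        {"sample_id": "b", "species": "tolerant", "tissue": "roots",
         "treatment": "Pb", "replicate": 1},
    ]
    return pd.DataFrame(rows).set_index("sample_id")


class TestQuartileNormalize:
    def test_hand_computed_two_arrays(self):
        """A=(1,2,3,4), B=2A: both 75th percentiles end at sqrt(q75_A * q75_B)."""
        m = make_matrix(np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]]),
                        two_array_sheet())
        out = pb.quartile_normalize(m)
        qa = quantile_linear([1, 2, 3, 4], 0.75)   # 3.25
        qb = quantile_linear([2, 4, 6, 8], 0.75)   # 6.5
        target = math.sqrt(qa * qb)
        for col in ("a", "b"):
            assert np.quantile(out.values[col], 0.75) == pytest.approx(target, rel=1e-12)
        # within-array ratios preserved: B/A constant per probe
        ratio = out.values["b"] / out.values["a"]
        assert np.allclose(ratio, ratio.iloc[0])

    def test_identity_when_quartiles_already_equal(self):
        m = make_matrix(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]]),
                        two_array_sheet())
        out = pb.quartile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_single_array_unchanged(self):
        s = two_array_sheet().iloc[:1]
        m = make_matrix(np.array([[1.0], [5.0], [9.0]]), s)
        out = pb.quartile_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_idempotent(self, sim_small):
        _, matrix, _, _ = sim_small
        once = pb.quartile_normalize(matrix)
        twice = pb.quartile_normalize(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-9)

    def test_nonpositive_rejected(self):
        s = two_array_sheet()
        v = pd.DataFrame({"a": [1.0, -1.0], "b": [1.0, 2.0]},
                         index=pd.Index(["P0", "P1"], name="probe_id"))
        with pytest.raises(DataError):
            pb.ExpressionMatrix(v, s)
        # a log-scale matrix (values may be <= 0) is rejected by the op itself
        logm = pb.ExpressionMatrix(v.abs(), s)
        with pytest.raises(DataError):
            pb.quartile_normalize(pb.log_transform(logm))

    def test_full_quantile_mode_equalizes_distributions(self, sim_small):
        _, matrix, _, _ = sim_small
        out = pb.quartile_normalize(matrix, mode="quantile")
        sorted_cols = np.sort(out.values.to_numpy(), axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]])


class TestMedianCenter:
    def test_direct_definition(self):
        m = make_matrix(np.array([[2.0, 4.0, 8.0], [5.0, 5.0, 5.0]]),
                        sheet(n_reps=3, species=("tolerant",), tissues=("roots",)).iloc[:3])
        out = pb.median_center_probes(m)
        assert list(out.values.iloc[0]) == [0.5, 1.0, 2.0]
        assert list(out.values.iloc[1]) == [1.0, 1.0, 1.0]

    def test_row_medians_become_one(self, sim_small):
        _, matrix, _, _ = sim_small
        out = pb.median_center_probes(matrix)
        assert np.allclose(out.values.median(axis=1), 1.0, atol=1e-12)


class TestLogTransform:
    def test_known_values(self):
        m = make_matrix(np.array([[8.0, 1.0]]), two_array_sheet())
        out = pb.log_transform(m, base=2)
        assert out.values.iloc[0, 0] == pytest.approx(3.0)
        assert out.values.iloc[0, 1] == pytest.approx(0.0)
        assert out.log_scale

    def test_round_trip(self, sim_small):
        _, matrix, _, _ = sim_small
        logm = pb.log_transform(matrix, base=2)
        back = 2.0 ** logm.values.to_numpy()
        assert np.allclose(back, matrix.values.to_numpy(), rtol=1e-12)

    def test_rejects_log_scale_input(self, sim_small):
        _, matrix, _, _ = sim_small
        logm = pb.log_transform(matrix)
        with pytest.raises(DataError):
            pb.log_transform(logm)


class TestBackgroundFilter:
    @pytest.fixture()
    def matrix6(self):
        s = sheet(n_reps=3, species=("tolerant",), tissues=("roots",))
        # columns: control_1..3, Pb_1..3
        vals = np.array([
            [60, 70, 80, 10, 20, 30],   # control all above 50 -> retained
            [60, 40, 80, 10, 20, 30],   # no full condition above -> removed
            [10, 20, 30, 55, 66, 77],   # treated all above -> retained
        ], dtype=float)
        cols = [f"tolerant_roots_control_{i}" for i in (1, 2, 3)] + \
               [f"tolerant_roots_Pb_{i}" for i in (1, 2, 3)]
        v = pd.DataFrame(vals, index=pd.Index(["P0", "P1", "P2"], name="probe_id"),
                         columns=cols)
        return pb.ExpressionMatrix(v, s)

    def test_exists_condition_rule(self, matrix6):
        kept = pb.background_filter(matrix6, 50, "tolerant", "roots")
        assert kept == ["P0", "P2"]

    def test_zero_background_keeps_all(self, matrix6):
        assert pb.background_filter(matrix6, 0, "tolerant", "roots") == ["P0", "P1", "P2"]

    def test_empty_condition_errors(self, matrix6):
        with pytest.raises(DataError):
            pb.background_filter(matrix6, 50, "sensitive", "roots")

    def test_dropped_probes_filtered_out(self, sim_small):
        cfg, matrix, _, truth = sim_small
        mq = pb.quartile_normalize(matrix)
        kept = set(pb.background_filter(mq, cfg.background, "tolerant", "roots"))
        # quartile scaling moves values slightly; allow the handful of dropout
        # probes whose rescaled signal crosses the floor
        assert len(kept & truth.dropped_probes["tolerant"]) <= 0.05 * len(
            truth.dropped_probes["tolerant"]
        )


class TestDeTest:
    def test_identical_groups_p_one(self):
        s = sheet(n_reps=3, species=("tolerant",), tissues=("roots",))
        vals = np.array([[2.0, 4.0, 8.0, 2.0, 4.0, 8.0]])
        cols = [f"tolerant_roots_control_{i}" for i in (1, 2, 3)] + \
               [f"tolerant_roots_Pb_{i}" for i in (1, 2, 3)]
        v = pd.DataFrame(vals, index=pd.Index(["P0"], name="probe_id"), columns=cols)
        de = pb.de_test(pb.ExpressionMatrix(v, s), "tolerant", "roots")
        row = de.iloc[0]
        assert row["p"] == 1.0
        assert not row["regulated"]
        assert row["fc"] == pytest.approx(1.0)

    def test_zero_variance_unequal_means_flagged(self):
        s = sheet(n_reps=3, species=("tolerant",), tissues=("roots",))
        cols = [f"tolerant_roots_control_{i}" for i in (1, 2, 3)] + \
               [f"tolerant_roots_Pb_{i}" for i in (1, 2, 3)]
        v = pd.DataFrame(np.array([[2.0, 2.0, 2.0, 8.0, 8.0, 8.0]]),
                         index=pd.Index(["P0"], name="probe_id"), columns=cols)
        de = pb.de_test(pb.ExpressionMatrix(v, s), "tolerant", "roots")
        assert de.iloc[0]["p"] == 0.0
        assert de.iloc[0]["zero_variance"]

    def test_too_few_replicates_errors(self):
        s = sheet(n_reps=1, species=("tolerant",), tissues=("roots",))
        cols = ["tolerant_roots_control_1", "tolerant_roots_Pb_1"]
        v = pd.DataFrame(np.array([[2.0, 3.0]]),
                         index=pd.Index(["P0"], name="probe_id"), columns=cols)
        with pytest.raises(DataError):
            pb.de_test(pb.ExpressionMatrix(v, s), "tolerant", "roots")

    def test_pooled_ttest_matches_scipy(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 4)) + 0.5
        t, p, _ = _pooled_ttest(a, b)
        ref = st.ttest_ind(b, a, axis=1, equal_var=True)
        assert np.allclose(t, ref.statistic, rtol=1e-12)
        assert np.allclose(p, ref.pvalue, rtol=1e-10)

    def test_planted_gene_called_up(self):
        """A 4-fold planted gene at noise_sd=0.1, n=3 is called up in >= 95% of seeds."""
        hits = 0
        seeds = range(40)
        for seed in seeds:
            cfg = pb.SimulationConfig(
                n_probes=100, n_genes=100, n_up=5, n_down=0, fc_planted=4.0,
                noise_sd=0.1, dropout_rate=0.0, seed=seed,
            )
            m, ann, truth = pb.simulate_experiment(cfg)
            centered = pb.median_center_probes(pb.quartile_normalize(m))
            de = pb.de_test(centered, "tolerant", "roots",
                            probe_to_gene=dict(zip(ann.probe_id, ann.gene_id)))
            up = set(de[de["direction"] == "up"]["gene_id"])
            planted = truth.planted_up[("tolerant", "roots")]
            hits += len(up & planted) / len(planted)
        assert hits / len(seeds) >= 0.95

    def test_q_at_least_p_and_threshold_monotonicity(self, de_small):
        de = de_small[("tolerant", "roots")]
        assert (de["q"] >= de["p"] - 1e-12).all()
        sets = [set(de[de["q"] < a]["gene_id"]) for a in (0.01, 0.05, 0.1)]
        assert sets[0] <= sets[1] <= sets[2]

    def test_fc_invariant_under_normalization(self, sim_small):
        """Quartile + median-centering rescale cancels in the treated/control mean ratio
        up to the array-scale factors the normalization removes."""
        cfg, matrix, annotation, _ = sim_small
        p2g = dict(zip(annotation.probe_id, annotation.gene_id))
        raw = pb.de_test(matrix, "sensitive", "roots", probe_to_gene=p2g)
        norm = pb.de_test(
            pb.median_center_probes(pb.quartile_normalize(matrix)),
            "sensitive", "roots", probe_to_gene=p2g,
        )
        merged = raw.merge(norm, on="gene_id", suffixes=("_raw", "_norm"))
        # per-probe median centering divides both condition means by the same
        # constant; quartile scaling rescales arrays. log-fc shifts by a common
        # per-contrast constant, so the spread of the difference is tiny
        delta = np.log2(merged["fc_norm"]) - np.log2(merged["fc_raw"])
        assert delta.std() < 0.05


class TestBenjaminiHochberg:
    """The BH step behind de_test against the literal step-up oracle."""

    def adjusted(self, pvec):
        from statsmodels.stats.multitest import multipletests

        return multipletests(pvec, method="fdr_bh")[1]

    def test_hand_case(self):
        """(0.01, 0.02, 0.03, 0.04) with m=4 all adjust to 0.04."""
        assert np.allclose(self.adjusted([0.01, 0.02, 0.03, 0.04]), 0.04)

    @given(
        hst.lists(hst.integers(min_value=0, max_value=100), min_size=1, max_size=6)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_stepup_oracle_on_grid(self, grid_ints):
        pvec = [i / 100 for i in grid_ints]
        assert np.allclose(self.adjusted(pvec), bh_stepup(pvec), atol=1e-12)


class TestSummarizeRegulated:
    def test_tolerant_species_accounting(self):
        out = pb.summarize_regulated(
            {("tolerant", "roots"): (795, 648), ("tolerant", "shoots"): (369, 296)}
        )
        row = out.iloc[0]
        assert row["total"] == 2108
        assert row["pct_roots"] == 68.5
        assert row["pct_shoots"] == 31.5

    def test_sensitive_species_accounting(self):
        out = pb.summarize_regulated(
            {("sensitive", "roots"): (6737, 7095), ("sensitive", "shoots"): (407, 561)}
        )
        row = out.iloc[0]
        assert row["total"] == 14800
        assert row["pct_roots"] == 93.5
        assert row["pct_shoots"] == 6.5

    def test_symmetric_counts(self):
        out = pb.summarize_regulated(
            {("tolerant", "roots"): (1, 0), ("tolerant", "shoots"): (0, 1)}
        )
        assert out.iloc[0]["pct_roots"] == 50.0
        assert out.iloc[0]["pct_shoots"] == 50.0

    def test_zero_total_reports_missing(self):
        out = pb.summarize_regulated({("tolerant", "roots"): (0, 0)})
        assert np.isnan(out.iloc[0]["pct_roots"])

    def test_percentages_sum_to_100(self, de_small):
        out = pb.summarize_regulated(de_small)
        for _, row in out.iterrows():
            if row["total"]:
                assert row["pct_roots"] + row["pct_shoots"] == pytest.approx(100.0, abs=0.1)

    def test_accepts_de_tables(self, de_small):
        out = pb.summarize_regulated(de_small)
        de = de_small[("tolerant", "roots")]
        row = out[out["species"] == "tolerant"].iloc[0]
        assert row["up_roots"] == (de["direction"] == "up").sum()
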