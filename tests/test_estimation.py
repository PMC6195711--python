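"""Transition estimation: classification, counting, matrix roots, pooling."""

import numpy as np
import pandas as pd
import pytest

from asthmacea import estimation as est
from asthmacea import synthdata
from asthmacea.params import HealthState


def panel(rows):
    return pd.DataFrame(rows, columns=["patient_id", "month_index",
                                       "act_score", "adherence_score"])


class TestClassify:
    @pytest.mark.parametrize("act,adh,state", [
        (20, 6.0, HealthState.A),
        (19, 6.0, HealthState.C),       # ACT 19 and below is poor control
        (25, 5.5, HealthState.B),       # adherence below 6 is low
        (19, 5.9, HealthState.D),
        (25, 8.0, HealthState.A),
        (5, 0.0, HealthState.D),
    ])
    def test_mapping(self, act, adh, state):
        assert est.classify_state(act, adh) == state

    @pytest.mark.parametrize("act,adh", [(4, 6.0), (26, 6.0), (20, -0.1), (20, 8.1)])
    def test_out_of_scale_rejected(self, act, adh):
        with pytest.raises(ValueError):
            est.classify_state(act, adh)


class TestTabulate:
    def test_single_pair(self):
        # D at month 0, A at month 1
        records = panel([("p1", 0, 10, 2.0), ("p1", 1, 25, 7.0)])
        tabs = est.tabulate_transitions(records)
        assert set(tabs) == {1}
        expected = np.zeros((4, 4), dtype=int)
        expected[3, 0] = 1
        np.testing.assert_array_equal(tabs[1].counts, expected)

    def test_gap_three_pairs(self):
        records = panel([("p1", 0, 25, 7.0), ("p1", 3, 25, 7.0), ("p1", 6, 25, 7.0)])
        tabs = est.tabulate_transitions(records)
        assert set(tabs) == {3}
        assert tabs[3].n_pairs == 2

    def test_long_gaps_discarded(self):
        records = panel([("p1", 0, 25, 7.0), ("p1", 1, 25, 7.0), ("p1", 30, 25, 7.0)])
        tabs = est.tabulate_transitions(records, max_gap=12)
        assert set(tabs) == {1}

    def test_no_usable_pairs_errors(self):
        records = panel([("p1", 0, 25, 7.0), ("p2", 5, 20, 6.0)])
        with pytest.raises(ValueError, match="no usable"):
            est.tabulate_transitions(records)

    def test_order_invariance(self, true_matrix):
        spec = synthdata.PanelSpec(n_patients=40, n_months=12, schedule="monthly",
                                   true_matrix=true_matrix, seed=3)
        records = synthdata.simulate_patient_records(spec)
        shuffled = records.sample(frac=1.0, random_state=9)
        a = est.tabulate_transitions(records)
        b = est.tabulate_transitions(shuffled)
        for k in a:
            np.testing.assert_array_equal(a[k].counts, b[k].counts)


class TestWilson:
    def test_boundaries(self):
        assert est.wilson_interval(0, 10)[0] == 0.0
        assert est.wilson_interval(10, 10)[1] == 1.0

    def test_closed_form_value(self):
        low, high = est.wilson_interval(2, 16)
        assert low == pytest.approx(0.0349777, abs=1e-6)
        assert high == pytest.approx(0.3602281, abs=1e-6)

    def test_against_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint
        for k, n in [(2, 16), (5, 20), (0, 7), (13, 13), (1, 100)]:
            lo, hi = est.wilson_interval(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(slo, abs=1e-6)
            assert hi == pytest.approx(shi, abs=1e-6)

    def test_contains_point_estimate(self):
        for k, n in [(3, 11), (7, 9), (1, 50)]:
            lo, hi = est.wilson_interval(k, n)
            assert lo <= k / n <= hi

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            est.wilson_interval(0, 0)


class TestMatrixRoot:
    def test_identity(self):
        root, diag = est.monthly_from_k_step(np.eye(4), 3)
        np.testing.assert_allclose(root, np.eye(4), atol=1e-12)
        assert diag.max_clipped_mass == 0.0

    def test_round_trip_recovers_monthly(self, true_matrix):
        P3 = np.linalg.matrix_power(true_matrix, 3)
        root, _ = est.monthly_from_k_step(P3, 3)
        np.testing.assert_allclose(root, true_matrix, atol=1e-6)

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_round_trip_random_positive(self, k):
        # diagonally dominant rows keep the eigenvalues positive, so the
        # principal root is the unique stochastic one at any k
        rng = np.random.default_rng(11)
        P = 0.7 * np.eye(4) + 0.3 * rng.dirichlet(np.full(4, 5.0), size=4)
        root, _ = est.monthly_from_k_step(np.linalg.matrix_power(P, k), k)
        np.testing.assert_allclose(root, P, atol=1e-6)

    def test_negative_root_regularized(self):
        # brute-force search for a 3-step matrix whose principal cube root
        # has a negative entry; output must still be stochastic and the
        # clipped mass reported
        rng = np.random.default_rng(0)
        found = False
        for _ in range(500):
            P3 = rng.dirichlet(np.full(4, 0.5), size=4)
            try:
                root, diag = est.monthly_from_k_step(P3, 3)
            except ValueError:
                continue
            if diag.max_clipped_mass > 0:
                found = True
                break
        assert found, "no clipped case found in search"
        assert np.all(root >= 0)
        np.testing.assert_allclose(root.sum(axis=1), 1.0, atol=1e-9)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            est.monthly_from_k_step(np.full((4, 4), 0.3), 2)

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            est.monthly_from_k_step(np.eye(4), 1)


class TestEstimateMonthlyMatrix:
    def test_add_one_smoothing_worked_example(self):
        # one patient sits in D for 6 consecutive months: 5 observed stays,
        # zero off-diagonal counts -> smoothed counts (1, 1, 1, 6)
        records = panel([("p1", m, 10, 2.0) for m in range(6)])
        res = est.estimate_monthly_matrix(records)
        np.testing.assert_allclose(res.matrix[3],
                                   [1 / 9, 1 / 9, 1 / 9, 6 / 9], atol=1e-12)
        assert "D" in res.smoothed_rows
        assert set(res.inestimable_rows) == {"A", "B", "C"}

    def test_monthly_only_panel_equals_k1_proportions(self, true_matrix):
        spec = synthdata.PanelSpec(n_patients=150, n_months=18, schedule="monthly",
                                   true_matrix=true_matrix, seed=5)
        records = synthdata.simulate_patient_records(spec)
        tabs = est.tabulate_transitions(records)
        assert set(tabs) == {1}
        res = est.estimate_monthly_matrix(records)
        counts = tabs[1].counts
        for i in range(4):
            if est.CHRONIC_NAMES[i] in res.smoothed_rows:
                continue
            np.testing.assert_allclose(res.matrix[i],
                                       counts[i] / counts[i].sum(), atol=1e-12)

    def test_rows_stochastic_and_smoothing_removes_zeros(self, true_matrix):
        spec = synthdata.PanelSpec(n_patients=30, n_months=10, schedule="monthly",
                                   true_matrix=true_matrix, seed=6)
        res = est.estimate_monthly_matrix(synthdata.simulate_patient_records(spec))
        np.testing.assert_allclose(res.matrix.sum(axis=1), 1.0, atol=1e-9)
        for i, name in enumerate(est.CHRONIC_NAMES):
            if name in res.inestimable_rows:
                continue
            off = [res.matrix[i, j] for j in range(4) if j != i]
            assert min(off) > 0.0

    def test_mixed_gap_recovery(self, true_matrix):
        # patients seen monthly and quarterly; pooled estimate near truth
        errors = []
        for seed in range(3):
            spec = synthdata.PanelSpec(n_patients=300, n_months=24,
                                       schedule="monthly" if seed % 2 else "rmtac",
                                       true_matrix=true_matrix, seed=seed)
            res = est.estimate_monthly_matrix(synthdata.simulate_patient_records(spec))
            errors.append(np.abs(res.matrix - true_matrix).max())
        assert np.median(errors) < 0.05

    def test_csv_export_shape(self, true_matrix, tmp_path):
        spec = synthdata.PanelSpec(n_patients=50, n_months=12, schedule="monthly",
                                   true_matrix=true_matrix, seed=2)
        res = est.estimate_monthly_matrix(synthdata.simulate_patient_records(spec))
        out = tmp_path / "est.csv"
        res.to_csv(out)
        df = pd.read_csv(out)
        assert list(df.columns) == ["origin", "destination", "estimate",
                                    "low", "high", "n_effective"]
        assert len(df) == 16
        assert ((df["low"] <= df["estimate"]) & (df["estimate"] <= df["high"])).all()

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            est.estimate_monthly_matrix(panel([]))
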