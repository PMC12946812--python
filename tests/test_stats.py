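import numpy as np
import pandas as pd
import pytest

from bcaccum.stats import (
    AssocSimConfig,
    bh_fdr,
    build_assoc_table,
    fe_model,
    ols_slope_per10,
    simulate_association_cohort,
    spearman_bca,
)


class TestSpearman:
    def test_perfect_monotone(self, rng):
        x = rng.uniform(0, 50, 20)
        y = np.exp(x / 10.0)  # strictly increasing, nonlinear
        out = spearman_bca(x, y, n_boot=200, seed=0)
        assert out["rho"] == pytest.approx(1.0)

    def test_antisymmetry_under_reversal(self, rng):
        x = rng.uniform(0, 50, 15)
        y = rng.normal(size=15) + 0.1 * x
        a = spearman_bca(x, y, n_boot=200, seed=0)
        b = spearman_bca(-x, y, n_boot=200, seed=0)
        assert a["rho"] == pytest.approx(-b["rho"], abs=1e-12)

    def test_null_distribution_centred_at_zero(self):
        """Monte-Carlo null oracle: independent x, y at n=28."""
        rng = np.random.default_rng(7)
        rhos = []
        for _ in range(300):
            x = rng.normal(size=28)
            y = rng.normal(size=28)
            rhos.append(float(np.corrcoef(
                np.argsort(np.argsort(x)), np.argsort(np.argsort(y)))[0, 1]))
        assert abs(np.mean(rhos)) < 0.05
        # large-sample null sd ~ 1/sqrt(n-1); 95th percentile consistent with it
        assert np.quantile(np.abs(rhos), 0.95) < 2.5 / np.sqrt(27)

    def test_ci_reproducible_and_covers_estimate(self, rng):
        x = rng.uniform(0, 60, 28)
        y = 0.03 * x + rng.normal(0, 0.4, 28)
        a = spearman_bca(x, y, n_boot=500, seed=3)
        b = spearman_bca(x, y, n_boot=500, seed=3)
        assert a == b
        assert a["ci_lo"] <= a["rho"] <= a["ci_hi"]

    def test_constant_margin_rejected(self):
        with pytest.raises(ValueError):
            spearman_bca([1, 1, 1, 1], [1, 2, 3, 4])


class TestOLS:
    def test_exact_line_slope_per10(self, rng):
        x = rng.uniform(-10, 60, 20)
        out = ols_slope_per10(x, 0.03 * x)
        assert out["slope_per10"] == pytest.approx(0.30, abs=1e-10)
        assert out["ci_lo"] == pytest.approx(0.30, abs=1e-6)

    def test_constant_response_flat(self, rng):
        x = rng.uniform(0, 50, 15)
        out = ols_slope_per10(x, np.full(15, 2.0))
        assert out["slope_per10"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] > 0.9

    def test_zero_variance_regressor_rejected(self):
        with pytest.raises(ValueError):
            ols_slope_per10([5, 5, 5, 5], [1, 2, 3, 4])

    def test_hc3_interval_widens_under_heteroskedasticity(self, rng):
        x = np.linspace(0, 60, 40)
        y = 0.03 * x + rng.normal(0, 0.05 + 0.02 * x, 40)
        out = ols_slope_per10(x, y)
        assert out["ci_lo"] < out["slope_per10"] < out["ci_hi"]


class TestFEModel:
    @staticmethod
    def _panel(slope_pct=0.04, n_pat=4, n_frac=6, noise=0.0, trend=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_pat):
            alpha = rng.normal(0, 1.0)
            dv = rng.uniform(-20, 60, n_frac)
            for t in range(n_frac):
                rows.append({
                    "patient": f"p{i}", "fraction": t + 1, "dv_bc_pct": dv[t],
                    "delta_gy": alpha + slope_pct * dv[t] + trend * (t + 1)
                    + rng.normal(0, noise)})
        return pd.DataFrame(rows)

    def test_recovers_noiseless_constructed_slope(self):
        out = fe_model(self._panel(slope_pct=0.04))
        assert out["fe_slope_per10"] == pytest.approx(0.40, abs=1e-9)

    def test_equals_demeaned_within_estimator(self):
        """Independent oracle: two-way demeaning (patient means removed from
        x, t and y) must give the identical coefficient to 1e-8."""
        panel = self._panel(slope_pct=0.031, noise=0.15, trend=0.01, seed=4)
        out = fe_model(panel)
        g = panel.groupby("patient")
        x = (panel["dv_bc_pct"] - g["dv_bc_pct"].transform("mean")).to_numpy() / 10.0
        t = (panel["fraction"] - g["fraction"].transform("mean")).to_numpy(float)
        y = (panel["delta_gy"] - g["delta_gy"].transform("mean")).to_numpy()
        coef = np.linalg.lstsq(np.column_stack([x, t]), y, rcond=None)[0][0]
        assert out["fe_slope_per10"] == pytest.approx(coef, abs=1e-8)

    def test_between_patient_confounding_removed(self):
        """Patient intercepts correlated with exposure bias pooled OLS but
        not the fixed-effects estimator."""
        rng = np.random.default_rng(5)
        rows = []
        for i in range(8):
            mu = 10.0 * i
            alpha = -0.05 * mu  # confounded intercept
            dv = mu + rng.uniform(-15, 15, 10)
            for t in range(10):
                rows.append({"patient": f"p{i}", "fraction": t + 1,
                             "dv_bc_pct": dv[t],
                             "delta_gy": alpha + 0.04 * dv[t]})
        panel = pd.DataFrame(rows)
        fe = fe_model(panel)["fe_slope_per10"]
        pooled = ols_slope_per10(panel["dv_bc_pct"], panel["delta_gy"])["slope_per10"]
        assert fe == pytest.approx(0.40, abs=1e-6)
        assert abs(pooled - 0.40) > 0.05

    def test_no_within_variance_rejected(self):
        panel = self._panel()
        panel["dv_bc_pct"] = panel["patient"].map({"p0": 5.0, "p1": 10.0,
                                                   "p2": 15.0, "p3": 20.0})
        with pytest.raises(ValueError):
            fe_model(panel)

    def test_single_patient_rejected(self):
        panel = self._panel(n_pat=1)
        with pytest.raises(ValueError):
            fe_model(panel)


class TestBHFDR:
    def test_hand_computed_step_up(self):
        """p = (0.01..0.05), m = 5: step-up gives min over j>=i of p_j*m/j,
        which equals 0.05 for every position."""
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        np.testing.assert_allclose(adj, 0.05)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw_and_order_invariant(self, rng):
        p = rng.uniform(0, 1, 10)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-12)
        perm = rng.permutation(10)
        np.testing.assert_allclose(bh_fdr(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestSimulatorAndTable:
    def test_simulator_is_seed_deterministic(self):
        cfg = AssocSimConfig(n_patients=6, n_fractions=8)
        a = simulate_association_cohort(cfg, seed=9)
        b = simulate_association_cohort(cfg, seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_injected_slope_recovered_in_one_cohort(self):
        cfg = AssocSimConfig(n_patients=28, n_fractions=25, slope_per10=0.39,
                             noise_sd=0.15)
        _, frows = simulate_association_cohort(cfg, seed=2)
        out = fe_model(frows)
        assert out["ci_lo"] <= 0.39 <= out["ci_hi"]

    def test_assoc_table_null_cohort_has_no_signal(self):
        cfg = AssocSimConfig(n_patients=16, n_fractions=10, slope_per10=0.0,
                             noise_sd=0.2)
        prows, frows = simulate_association_cohort(cfg, seed=11)
        for ep in ("D2%", "D50%", "D98%", "D0.03cc", "D150cc"):
            prows[f"delta_{ep}"] = prows["delta_gy"]
            frows[f"delta_{ep}"] = frows["delta_gy"]
        table = build_assoc_table(prows, frows, n_boot=100, seed=1)
        assert (table["p_spearman_fdr"] >= table["p_spearman"] - 1e-12).all()
        assert (table["p_ols_fdr"] >= table["p_ols"] - 1e-12).all()
        assert np.all(np.abs(table["ols_slope_per10"]) < 0.2)
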