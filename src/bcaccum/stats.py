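"""Statistics linking bowel-cavity volume change to accumulated dose change.

The battery mirrors a two-level design:

* patient level (n patients, one row each): Spearman's rho between the
  within-patient median bowel-cavity volume change (percent) and the
  accumulated endpoint difference (Gy), with BCa bootstrap CIs, plus an
  OLS slope expressed in Gy per 10% expansion with HC3 robust CIs;
* fraction level (balanced panel, 25 rows per patient): a fixed-effects
  linear model with patient-specific intercepts, a fraction-index
  covariate and the per-10% slope, with patient-clustered robust SEs.

p-values for the five primary endpoints form a single family per test
type and are adjusted with the Benjamini-Hochberg step-up FDR procedure;
fixed-effects estimates are confirmatory and left unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from bcaccum.dvh import ALL_ENDPOINTS


# ---------------------------------------------------------------------------
# Spearman with BCa bootstrap
# ---------------------------------------------------------------------------

def _bca_interval(theta_hat: float, boots: np.ndarray, jacks: np.ndarray,
                  alpha: float = 0.05) -> tuple[float, float]:
    """Bias-corrected and accelerated percentile interval."""
    boots = boots[np.isfinite(boots)]
    if boots.size == 0 or np.allclose(boots, boots[0]):
        return float(theta_hat), float(theta_hat)
    # bias correction from the fraction of bootstrap replicates below the estimate
    prop = np.mean(boots < theta_hat)
    prop = min(max(prop, 1.0 / (boots.size + 1)), 1.0 - 1.0 / (boots.size + 1))
    z0 = sps.norm.ppf(prop)
    # acceleration from the jackknife skewness
    jm = jacks.mean()
    num = np.sum((jm - jacks) ** 3)
    den = 6.0 * np.sum((jm - jacks) ** 2) ** 1.5
    a = num / den if den > 0 else 0.0
    lo_hi = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        z = z0 + sps.norm.ppf(q)
        adj = sps.norm.cdf(z0 + z / (1.0 - a * z))
        lo_hi.append(float(np.quantile(boots, adj)))
    return tuple(lo_hi)


def spearman_bca(x, y, n_boot: int = 2000, seed: int = 0,
                 alpha: float = 0.05) -> dict:
    """Spearman's rho with a BCa bootstrap confidence interval.

    Ranks use midranks on ties; the two-sided p comes from the standard
    rank test.  Bootstrap resamples draw patients (pairs) with
    replacement; replicates where either margin is constant are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("NaN/inf in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant margin")

    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    rng = np.random.default_rng(seed)
    n = x.size
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.full(n_boot, np.nan)
    for b in range(n_boot):
        xb, yb = x[idx[b]], y[idx[b]]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            continue
        boots[b] = sps.spearmanr(xb, yb).statistic
    jacks = np.array([sps.spearmanr(np.delete(x, i), np.delete(y, i)).statistic
                      for i in range(n)])
    lo, hi = _bca_interval(rho, boots, jacks, alpha)
    return {"rho": rho, "ci_lo": lo, "ci_hi": hi, "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# OLS and fixed-effects slopes per 10% expansion
# ---------------------------------------------------------------------------

def ols_slope_per10(x_pct, y_gy, alpha: float = 0.05) -> dict:
    """OLS slope of endpoint difference on volume change, per 10% expansion.

    The regressor is rescaled to units of 10 percentage points before the
    fit; the CI uses the HC3 heteroskedasticity-consistent covariance with
    t(n-2) critical values (cohorts here are small, where normal quantiles
    visibly undercover).
    """
    x = np.asarray(x_pct, dtype=float) / 10.0
    y = np.asarray(y_gy, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the regressor")
    if np.ptp(y) == 0:
        # exactly constant response: slope identically 0, no evidence at all
        return {"slope_per10": 0.0, "ci_lo": 0.0, "ci_hi": 0.0, "p": 1.0}
    model = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC3", use_t=True)
    ci = model.conf_int(alpha=alpha)
    return {
        "slope_per10": float(model.params[1]),
        "ci_lo": float(ci[1, 0]),
        "ci_hi": float(ci[1, 1]),
        "p": float(model.pvalues[1]),
    }


def fe_model(panel: pd.DataFrame, endpoint_col: str = "delta_gy",
             x_col: str = "dv_bc_pct", patient_col: str = "patient",
             fraction_col: str = "fraction", alpha: float = 0.05) -> dict:
    """Fixed-effects slope per 10% expansion with patient-clustered SEs.

    Equivalent to dummy-variable OLS with one intercept per patient plus
    a linear fraction-index covariate.  Cluster-robust (CR1) covariance
    by patient; inference uses the t distribution with G-1 degrees of
    freedom where G is the number of patients.
    """
    df = panel[[patient_col, fraction_col, x_col, endpoint_col]].dropna()
    patients = df[patient_col].unique()
    if patients.size < 2:
        raise ValueError("fixed-effects model needs at least two patients")
    counts = df.groupby(patient_col).size()
    if (counts < 2).any():
        raise ValueError("each patient needs at least two fractions")
    within_var = df.groupby(patient_col)[x_col].var(ddof=0)
    if np.allclose(within_var, 0):
        raise ValueError("no within-patient variance in the regressor")

    x10 = df[x_col].to_numpy(float) / 10.0
    dummies = pd.get_dummies(df[patient_col].astype("category"), dtype=float)
    X = np.column_stack([x10, df[fraction_col].to_numpy(float), dummies.to_numpy()])
    y = df[endpoint_col].to_numpy(float)
    groups = df[patient_col].to_numpy()
    fit = sm.OLS(y, X).fit(
        cov_type="cluster",
        cov_kwds={"groups": groups, "use_correction": True, "df_correction": True},
        use_t=True,
    )
    se = float(fit.bse[0])
    slope = float(fit.params[0])
    dof = patients.size - 1
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, dof)
    pval = 2.0 * sps.t.sf(abs(slope / se), dof)
    return {"fe_slope_per10": slope, "se": se, "ci_lo": slope - tcrit * se,
            "ci_hi": slope + tcrit * se, "p": float(pval), "df": dof}


def bh_fdr(p_values, family: str = "endpoints") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one test family."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Cohort-level association table
# ---------------------------------------------------------------------------

def build_assoc_table(
    patient_rows: pd.DataFrame,
    fraction_rows: pd.DataFrame,
    endpoints: tuple[str, ...] = ALL_ENDPOINTS,
    n_boot: int = 2000,
    seed: int = 0,
    pool_fdr_families: bool = False,
) -> pd.DataFrame:
    """Per-endpoint association summary (rho, OLS slope, FE slope, FDR).

    ``patient_rows``: one row per patient with ``median_dv_bc_pct`` and a
    ``delta_<endpoint>`` column per endpoint (accumulated minus planned,
    Gy).  ``fraction_rows``: one row per patient-fraction with
    ``dv_bc_pct``, ``fraction`` and the same ``delta_<endpoint>`` columns
    holding per-fraction differences.  Spearman and OLS p-values are
    FDR-adjusted as two separate five-endpoint families by default, or as
    one pooled family when ``pool_fdr_families`` is set.
    """
    rows = []
    for i, ep in enumerate(endpoints):
        col = f"delta_{ep}"
        sp = spearman_bca(patient_rows["median_dv_bc_pct"], patient_rows[col],
                          n_boot=n_boot, seed=seed + i)
        ols = ols_slope_per10(patient_rows["median_dv_bc_pct"], patient_rows[col])
        fe = fe_model(fraction_rows.drop(columns=["delta_gy"], errors="ignore")
                      .rename(columns={col: "delta_gy"}), endpoint_col="delta_gy")
        rows.append({
            "endpoint": ep,
            "rho": sp["rho"], "rho_ci_lo": sp["ci_lo"], "rho_ci_hi": sp["ci_hi"],
            "p_spearman": sp["p"],
            "ols_slope_per10": ols["slope_per10"],
            "ols_ci_lo": ols["ci_lo"], "ols_ci_hi": ols["ci_hi"], "p_ols": ols["p"],
            "fe_slope_per10": fe["fe_slope_per10"],
            "fe_ci_lo": fe["ci_lo"], "fe_ci_hi": fe["ci_hi"], "p_fe": fe["p"],
        })
    table = pd.DataFrame(rows)
    if pool_fdr_families:
        pooled = bh_fdr(np.concatenate([table["p_spearman"], table["p_ols"]]))
        table["p_spearman_fdr"] = pooled[: len(table)]
        table["p_ols_fdr"] = pooled[len(table):]
    else:
        table["p_spearman_fdr"] = bh_fdr(table["p_spearman"])
        table["p_ols_fdr"] = bh_fdr(table["p_ols"])
    return table


# ---------------------------------------------------------------------------
# Endpoint-level simulator for statistical validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssocSimConfig:
    """Generator for endpoint-level cohorts with a known dose-response slope.

    Volume changes are drawn hierarchically: each patient gets a mean
    change ~ Uniform(lo, hi) percent and per-fraction Gaussian noise, so
    both between-patient (OLS) and within-patient (FE) analyses see
    signal.  Endpoint differences follow the linear model
    ``delta = intercept_i + slope_per10 * dv/10 + trend * fraction + noise``.
    """

    n_patients: int = 28
    n_fractions: int = 25
    dv_mean_lo: float = -10.0
    dv_mean_hi: float = 60.0
    dv_frac_sd: float = 12.0
    slope_per10: float = 0.39
    #: course-level (between-patient) slope; defaults to the fraction slope
    course_slope_per10: float | None = None
    intercept_sd: float = 0.3
    fraction_trend: float = 0.0
    noise_sd: float = 0.25


def simulate_association_cohort(cfg: AssocSimConfig, seed: int = 0
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw (patient_rows, fraction_rows) with a known injected slope.

    Returns tables shaped for :func:`ols_slope_per10` / :func:`fe_model`:
    fraction rows with ``dv_bc_pct`` and ``delta_gy``; patient rows with
    ``median_dv_bc_pct`` and ``delta_gy`` (the course-level difference,
    generated from the same slope on the patient median with independent
    noise).
    """
    rng = np.random.default_rng(seed)
    mu = rng.uniform(cfg.dv_mean_lo, cfg.dv_mean_hi, size=cfg.n_patients)
    alpha_i = rng.normal(0.0, cfg.intercept_sd, size=cfg.n_patients)
    frows = []
    prows = []
    for i in range(cfg.n_patients):
        dv = mu[i] + rng.normal(0.0, cfg.dv_frac_sd, size=cfg.n_fractions)
        frac_idx = np.arange(1, cfg.n_fractions + 1)
        delta = (alpha_i[i] + cfg.slope_per10 * dv / 10.0
                 + cfg.fraction_trend * frac_idx
                 + rng.normal(0.0, cfg.noise_sd, size=cfg.n_fractions))
        for t in range(cfg.n_fractions):
            frows.append({"patient": f"p{i:03d}", "fraction": int(frac_idx[t]),
                          "dv_bc_pct": dv[t], "delta_gy": delta[t]})
        med = float(np.median(dv))
        course_slope = (cfg.slope_per10 if cfg.course_slope_per10 is None
                        else cfg.course_slope_per10)
        prows.append({"patient": f"p{i:03d}", "median_dv_bc_pct": med,
                      "delta_gy": course_slope * med / 10.0
                      + rng.normal(0.0, cfg.noise_sd)})
    return pd.DataFrame(prows), pd.DataFrame(frows)
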