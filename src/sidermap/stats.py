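"""Nonparametric block-design tests and mixed-model comparison.

The analyses here operate on block designs whose rows are brains
(blocks) and whose columns are the compared conditions: cortical depth
layers, iron burden categories, cortical lobes, or ring counts.

* Friedman rank test (tie-corrected) with Kendall's W = chi2 / (n (k-1)).
* Skillings–Mack test for designs with missing cells (a brain with no
  pixels in an iron category has that cell missing, not zero).
* Conover's all-pairs post hoc for the Friedman design, with
  Benjamini–Hochberg adjustment.
* One-way repeated-measures ANOVA with Tukey HSD pairs (ring-model
  residuals and coefficients across ring counts).
* Linear mixed-effects comparison of a null model (age + sex + random
  intercepts for subject and region) against the model adding iron
  density, via likelihood ratio, AIC and BIC on ML fits, with
  leave-one-subject-out Cook's distance influence filtering (4/n rule).

All p-values are two-tailed; the working significance level is 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------- block tests


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    kendall_w: float
    n_blocks: int
    k_treatments: int


def _as_design(design) -> np.ndarray:
    arr = np.asarray(design, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("design must be a 2-D block x treatment matrix, k >= 2")
    return arr


def friedman_kendall(design) -> FriedmanResult:
    """Tie-corrected Friedman chi-square with Kendall's W normalization.

    ``design``: blocks (brains) in rows, treatments in columns, complete.
    Kendall's coefficient of concordance is chi2 / (n (k - 1)), i.e. 1
    when every block ranks the treatments identically and 0 when rank
    sums are perfectly balanced.
    """
    arr = _as_design(design)
    if np.isnan(arr).any():
        raise ValueError("design has missing cells; use skillings_mack")
    n, k = arr.shape
    if n < 2:
        raise ValueError("need at least two blocks")
    ranks = np.apply_along_axis(sps.rankdata, 1, arr)  # midranks within block
    rank_sums = ranks.sum(axis=0)
    chi2_unc = 12.0 / (n * k * (k + 1)) * np.sum(
        (rank_sums - n * (k + 1) / 2.0) ** 2
    )
    # tie correction: per-block sum of (t^3 - t) over tie groups
    tie_term = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n * k * (k**2 - 1))
    if denom <= 0:
        chi2 = 0.0  # all values tied in every block
    else:
        chi2 = chi2_unc / denom
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    w = chi2 / (n * (k - 1))
    return FriedmanResult(float(chi2), df, p, float(w), n, k)


@dataclass
class SkillingsMackResult:
    statistic: float
    df: int
    p: float
    n_blocks: int
    k_treatments: int
    dropped_treatments: tuple = ()


def skillings_mack(design) -> SkillingsMackResult:
    """Friedman-type rank test tolerating missing block-treatment cells.

    Within each block, observed treatments get midranks; the centered,
    block-size-scaled rank sums form a quadratic form with the null
    covariance built from block co-occurrence, inverted by Moore-Penrose
    pseudo-inverse.  Asymptotically chi-squared with k - 1 degrees of
    freedom.  Reduces exactly to the (uncorrected) Friedman statistic on
    complete tie-free designs.  Treatments observed in no block are
    dropped with a warning and the degrees of freedom reduced.
    """
    arr = _as_design(design)
    observed = np.isfinite(arr)
    seen = observed.any(axis=0)
    dropped: tuple = ()
    if not seen.all():
        dropped = tuple(np.nonzero(~seen)[0])
        warnings.warn(
            f"treatments {dropped} observed in no block; dropped", stacklevel=2
        )
        arr = arr[:, seen]
        observed = observed[:, seen]
    # blocks need >= 2 observed treatments to carry rank information
    usable = observed.sum(axis=1) >= 2
    arr, observed = arr[usable], observed[usable]
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError("not enough observed data for a block test")
    A = np.zeros(k)
    cov = np.zeros((k, k))
    for row, obs in zip(arr, observed):
        s = int(obs.sum())
        r = sps.rankdata(row[obs])
        scale = np.sqrt(12.0 / (s + 1))
        A[obs] += scale * (r - (s + 1) / 2.0)
        idx = np.nonzero(obs)[0]
        cov[np.ix_(idx, idx)] -= 1.0
        cov[idx, idx] += s  # diag gets (s - 1) net
    stat = float(A @ np.linalg.pinv(cov) @ A)
    df = k - 1
    p = float(sps.chi2.sf(stat, df))
    return SkillingsMackResult(stat, df, p, n, k, dropped)


def conover_posthoc(design, adjust: str = "BH", labels: Optional[Sequence] = None) -> pd.DataFrame:
    """All-pairs Conover post hoc for a complete Friedman-type design.

    t-type statistics from within-block rank sums (Conover 1999), with
    (n-1)(k-1) error degrees of freedom, adjusted across the pair family
    by Benjamini–Hochberg by default.
    """
    arr = _as_design(design)
    if np.isnan(arr).any():
        raise ValueError("Conover post hoc requires a complete design")
    n, k = arr.shape
    if labels is None:
        labels = list(range(k))
    ranks = np.apply_along_axis(sps.rankdata, 1, arr)
    R = ranks.sum(axis=0)
    A = float(np.sum(ranks**2))
    B = float(np.sum(R**2)) / n
    df = (n - 1) * (k - 1)
    denom_sq = 2.0 * n * (A - B) / df
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            diff = abs(R[a] - R[b])
            if denom_sq <= 0:
                t = np.inf if diff > 0 else 0.0
            else:
                t = diff / np.sqrt(denom_sq)
            p = float(2 * sps.t.sf(t, df)) if np.isfinite(t) else 0.0
            rows.append((labels[a], labels[b], float(t), min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["treatment_a", "treatment_b", "statistic", "p_raw"])
    method = {"BH": "fdr_bh", "none": None}.get(adjust, adjust)
    if method is None:
        table["p_adjusted"] = table["p_raw"]
    else:
        table["p_adjusted"] = multipletests(table["p_raw"], method=method)[1]
    return table


# ----------------------------------------------------- repeated-measures ANOVA


@dataclass
class RMAnovaResult:
    F: float
    df_condition: int
    df_error: int
    p: float
    tukey: pd.DataFrame
    ms_error: float


def rm_anova_tukey(values, labels: Optional[Sequence] = None) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Tukey HSD pairwise tests.

    ``values``: complete subjects x conditions matrix (e.g. per-brain
    mean residuals at ring counts 0..3).  Tukey pairs use the
    within-subject error mean square and the studentized range with
    (n-1)(k-1) degrees of freedom, as standard after a repeated-measures
    omnibus.
    """
    arr = _as_design(values)
    if np.isnan(arr).any():
        raise ValueError("repeated-measures ANOVA requires complete data")
    n, k = arr.shape
    if n < 3:
        raise ValueError("need at least three subjects")
    if labels is None:
        labels = list(range(k))
    grand = arr.mean()
    cond_means = arr.mean(axis=0)
    subj_means = arr.mean(axis=1)
    ss_cond = n * float(np.sum((cond_means - grand) ** 2))
    ss_subj = k * float(np.sum((subj_means - grand) ** 2))
    ss_total = float(np.sum((arr - grand) ** 2))
    ss_err = ss_total - ss_cond - ss_subj
    df_c, df_e = k - 1, (n - 1) * (k - 1)
    ms_c = ss_cond / df_c
    ms_e = max(ss_err / df_e, 0.0)
    F = ms_c / ms_e if ms_e > 0 else (np.inf if ms_c > 0 else 0.0)
    p = float(sps.f.sf(F, df_c, df_e)) if np.isfinite(F) else 0.0
    se = np.sqrt(ms_e / n)
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            diff = cond_means[a] - cond_means[b]
            if se > 0:
                q = abs(diff) / se
                pq = float(sps.studentized_range.sf(q, k, df_e))
            else:
                q, pq = (np.inf, 0.0) if diff != 0 else (0.0, 1.0)
            rows.append((labels[a], labels[b], float(diff), float(q), min(pq, 1.0)))
    tukey = pd.DataFrame(
        rows, columns=["condition_a", "condition_b", "mean_diff", "q", "p_adjusted"]
    )
    return RMAnovaResult(float(F), df_c, df_e, min(p, 1.0), tukey, ms_e)


# ------------------------------------------------------------- mixed models


@dataclass
class LMEComparison:
    response: str
    loglik_null: float
    loglik_full: float
    aic_null: float
    aic_full: float
    bic_null: float
    bic_full: float
    lrt_chi2: float
    lrt_df: int
    lrt_p: float
    iron_slope: float
    iron_slope_ci: tuple[float, float]
    iron_slope_p: float
    marginal_r2: float
    conditional_r2: float
    removed_subjects: tuple = ()
    singular: bool = False
    n_obs: int = 0


_REQUIRED_COLS = ("case_id", "region", "iron_density", "age", "sex")


def _fit_mixed(df: pd.DataFrame, response: str, include_iron: bool):
    import statsmodels.formula.api as smf

    fixed = f"{response} ~ age + C(sex)"
    if include_iron:
        fixed += " + iron_density"
    vc = {"case": "0 + C(case_id)", "region": "0 + C(region)"}
    model = smf.mixedlm(fixed, df, groups=np.ones(len(df)), vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False, method="lbfgs", maxiter=400)
    return fit


def _ml_ic(fit) -> tuple[float, float]:
    # parameters: fixed effects + variance components + residual variance
    k = fit.model.k_fe + fit.model.k_vc + 1
    nobs = fit.model.nobs
    llf = fit.llf
    return 2 * k - 2 * llf, k * np.log(nobs) - 2 * llf


def _nakagawa_r2(fit, df: pd.DataFrame) -> tuple[float, float]:
    X = fit.model.exog
    var_f = float(np.var(X @ fit.fe_params))
    var_re = float(np.sum(fit.vcomp))  # statsmodels reports vcomp on the data scale
    var_e = float(fit.scale)
    total = var_f + var_re + var_e
    if total <= 0:
        return 0.0, 0.0
    return var_f / total, (var_f + var_re) / total


def lme_compare(
    table: pd.DataFrame,
    response: str,
    filter_influence: bool = True,
    alpha: float = 0.05,
) -> LMEComparison:
    """Null vs iron-including mixed model for a marker density response.

    ``table`` is long format with one row per section: case_id, region,
    iron_density, age, sex and the response column (e.g. gfap_density).
    Both models carry random intercepts for subject and cortical region
    and fixed effects for age at death and sex; the full model adds iron
    density.  Models are fitted by maximum likelihood so the likelihood
    ratio between nested fixed-effect structures is valid; AIC and BIC
    come from the same ML fits.  Overly influential subjects (Cook's
    distance > 4/n over leave-one-subject-out refits of the full model)
    are removed first.
    """
    missing = [c for c in _REQUIRED_COLS + (response,) if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    df = table.dropna(subset=[response, "iron_density", "age", "sex"]).copy()
    removed: tuple = ()
    if filter_influence:
        dist = cooks_distances(df, response)
        n_subj = df["case_id"].nunique()
        thresh = 4.0 / n_subj
        removed = tuple(sorted(k for k, v in dist.items() if v > thresh))
        if removed:
            df = df[~df["case_id"].isin(removed)]
            if df.empty:
                raise ValueError("influence filtering removed every subject")
    fit0 = _fit_mixed(df, response, include_iron=False)
    fit1 = _fit_mixed(df, response, include_iron=True)
    ll0, ll1 = float(fit0.llf), float(fit1.llf)
    aic0, bic0 = _ml_ic(fit0)
    aic1, bic1 = _ml_ic(fit1)
    chi2 = max(2.0 * (ll1 - ll0), 0.0)
    p = float(sps.chi2.sf(chi2, 1))
    slope = float(fit1.fe_params["iron_density"])
    se = float(fit1.bse_fe["iron_density"])
    z = sps.norm.ppf(1 - alpha / 2)
    ci = (slope - z * se, slope + z * se)
    slope_p = float(fit1.pvalues["iron_density"])
    r2m, r2c = _nakagawa_r2(fit1, df)
    singular = bool(np.any(fit1.vcomp < 1e-10)) or not fit1.converged
    return LMEComparison(
        response,
        ll0,
        ll1,
        float(aic0),
        float(aic1),
        float(bic0),
        float(bic1),
        float(chi2),
        1,
        p,
        slope,
        ci,
        slope_p,
        r2m,
        r2c,
        removed,
        singular,
        len(df),
    )


def cooks_distances(table: pd.DataFrame, response: str) -> dict:
    """Per-subject Cook's distance from leave-one-subject-out refits.

    D_i = (beta - beta_(-i))' Cov(beta)^-1 (beta - beta_(-i)) / p on the
    fixed effects of the full (iron-including) model, the grouped-data
    analogue of the classical regression diagnostic.
    """
    full = _fit_mixed(table, response, include_iron=True)
    beta = np.asarray(full.fe_params)
    cov = np.asarray(full.cov_params())[: len(beta), : len(beta)]
    cov_inv = np.linalg.pinv(cov)
    p = len(beta)
    out = {}
    for subj in table["case_id"].unique():
        sub = table[table["case_id"] != subj]
        if sub["case_id"].nunique() < 2:
            continue
        try:
            fit_i = _fit_mixed(sub, response, include_iron=True)
        except Exception:
            continue
        delta = beta - np.asarray(fit_i.fe_params)
        out[subj] = float(delta @ cov_inv @ delta) / p
    return out


def influence_filter(
    table: pd.DataFrame, response: str
) -> tuple[pd.DataFrame, tuple, dict]:
    """Remove subjects with Cook's distance above 4/n (n = subjects)."""
    dist = cooks_distances(table, response)
    n_subj = table["case_id"].nunique()
    thresh = 4.0 / n_subj
    removed = tuple(sorted(k for k, v in dist.items() if v > thresh))
    filtered = table[~table["case_id"].isin(removed)]
    if filtered.empty:
        raise ValueError("influence filtering removed every subject")
    return filtered, removed, dist
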