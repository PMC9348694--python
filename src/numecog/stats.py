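"""Condition summaries, the dummy-coded GLM tuning test, electrode response
classification and the numerosity-versus-category comparison.

The tuning test is an ordinary-least-squares regression of per-trial HFB
scalars on an intercept plus an indicator for every condition other than the
reference, with the reference set to the empirically preferred condition
(the condition with the highest mean response).  The intercept then
estimates the preferred-condition mean — its t-statistic tests "response
above zero at the preferred numerosity" — and each indicator coefficient's
t tests that condition against the preferred one, with residual
df = N_kept - n_conditions.  Per-condition p-values are reported uncorrected
by default (a Bonferroni/Holm option exists for principled reuse).

Electrodes are classified into four operational response patterns:
``nonresponsive`` (an omnibus F-test cannot reject that every condition mean
is zero — note the intercept t is *not* used as the responsiveness gate:
because the reference level is the empirical argmax of eight noisy means,
the intercept test is selection-biased and rejects far more than its
nominal rate on silent channels, while the omnibus F is exact), ``tuned`` (preferred numerosity below the largest level, with at least
``min_significant_lower`` conditions significantly below it — a preference
for the smallest numerosity still counts as tuned, since contrast-energy
responses must grow with numerosity), ``energy_monotonic`` (preference for
the largest numerosity with means increasing monotonically, Spearman rank
correlation >= 0.8), and ``flat_responsive`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import f as scipy_f
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .stim import CATEGORY_LEVELS, NUMEROSITY_LEVELS


def _condition_sort_key(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))


def _ordered_levels(conditions: np.ndarray) -> list[str]:
    return sorted({str(c) for c in conditions}, key=_condition_sort_key)


@dataclass
class TuningFit:
    """Per-electrode condition summary, GLM table and response label."""

    summary: pd.DataFrame  # condition, n, mean, sem
    preferred: str
    glm: pd.DataFrame  # term, estimate, se, t, df, p
    residual_df: int
    omnibus_f: float = float("nan")  # all condition means zero
    omnibus_p: float = float("nan")
    response_window_s: tuple[float, float] | None = None
    label: str | None = None


def condition_summary(scalars: np.ndarray, conditions: np.ndarray,
                      kept: np.ndarray | None = None) -> tuple[pd.DataFrame, str]:
    """Mean and SEM of the per-trial scalars per condition, plus the
    preferred condition (argmax of means; ties break to the lower
    numerosity / lexicographically first label)."""
    scalars = np.asarray(scalars, dtype=float)
    conditions = np.asarray([str(c) for c in conditions])
    if kept is None:
        kept = np.ones(scalars.shape, dtype=bool)
    kept = np.asarray(kept, dtype=bool)
    rows = []
    for cond in _ordered_levels(conditions):
        vals = scalars[(conditions == cond) & kept]
        if vals.size == 0:
            raise ValueError(f"condition {cond!r} has no kept trials")
        if vals.size < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 kept trials")
        rows.append(
            {
                "condition": cond,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size)),
            }
        )
    summary = pd.DataFrame(rows)
    best = summary["mean"].to_numpy().argmax()  # first argmax = lower level on ties
    return summary, str(summary["condition"].iloc[best])


def _dummy_design(conditions: np.ndarray, reference: str) -> tuple[np.ndarray, list[str]]:
    levels = [c for c in _ordered_levels(conditions) if c != reference]
    X = np.ones((conditions.size, 1 + len(levels)))
    for j, lev in enumerate(levels, start=1):
        X[:, j] = conditions == lev
    return X, levels


def fit_condition_glm(scalars: np.ndarray, conditions: np.ndarray,
                      reference: str | None = None,
                      kept: np.ndarray | None = None,
                      multiple_comparison: str = "none",
                      response_window_s: tuple[float, float] | None = None) -> TuningFit:
    """OLS on intercept + one indicator per non-reference condition.

    ``reference`` defaults to the empirically preferred condition.
    Homoscedastic two-sided t-tests; the indicator t for a two-condition
    design equals the pooled-variance two-sample t exactly.
    """
    scalars = np.asarray(scalars, dtype=float)
    conditions = np.asarray([str(c) for c in conditions])
    if kept is None:
        kept = np.ones(scalars.shape, dtype=bool)
    kept = np.asarray(kept, dtype=bool)
    summary, preferred = condition_summary(scalars, conditions, kept)
    if reference is None:
        reference = preferred
    y = scalars[kept]
    conds = conditions[kept]
    if len(_ordered_levels(conds)) < 2:
        raise ValueError("the GLM needs at least two conditions")
    X, levels = _dummy_design(conds, reference)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design: some condition has no kept trials")
    res = sm.OLS(y, X).fit()
    # omnibus responsiveness: one-way cell-means F against all means zero
    cell_means = np.array([y[conds == c].mean() for c in _ordered_levels(conds)])
    rss1 = float(res.ssr)
    rss0 = float(y @ y)
    k = cell_means.size
    df_resid = y.size - k
    omnibus_f = ((rss0 - rss1) / k) / (rss1 / df_resid)
    omnibus_p = float(scipy_f.sf(omnibus_f, k, df_resid))
    terms = ["intercept"] + levels
    pvals = np.asarray(res.pvalues)
    if multiple_comparison != "none":
        # correct the condition contrasts only, never the intercept
        method = {"bonferroni": "bonferroni", "holm": "holm"}[multiple_comparison]
        pvals = pvals.copy()
        pvals[1:] = multipletests(pvals[1:], method=method)[1]
    glm = pd.DataFrame(
        {
            "term": terms,
            "estimate": np.asarray(res.params),
            "se": np.asarray(res.bse),
            "t": np.asarray(res.tvalues),
            "df": int(res.df_resid),
            "p": pvals,
        }
    )
    return TuningFit(
        summary=summary,
        preferred=reference,
        glm=glm,
        residual_df=int(res.df_resid),
        omnibus_f=float(omnibus_f),
        omnibus_p=omnibus_p,
        response_window_s=response_window_s,
    )


def classify_electrode(fit: TuningFit,
                       levels: tuple[int, ...] = NUMEROSITY_LEVELS,
                       alpha: float = 0.05,
                       min_significant_lower: int = 3,
                       spearman_min: float = 0.8) -> str:
    """Assign one of the four operational response-pattern labels."""
    glm = fit.glm.set_index("term")
    if not fit.omnibus_p < alpha:
        return "nonresponsive"
    max_level = str(max(levels))
    contrasts = glm.drop(index="intercept")
    sig_lower = int(((contrasts["p"] < alpha) & (contrasts["estimate"] < 0)).sum())
    if fit.preferred != max_level and sig_lower >= min_significant_lower:
        return "tuned"
    if fit.preferred == max_level:
        means = fit.summary.copy()
        order = np.array([int(c) for c in means["condition"]])
        rho = spearmanr(order, means["mean"].to_numpy()).statistic
        if rho >= spearman_min:
            return "energy_monotonic"
    return "flat_responsive"


@dataclass
class CategoryComparison:
    """Numerosity-versus-category GLM: preferred-numerosity trials as the
    reference level, one indicator per stimulus category."""

    glm: pd.DataFrame
    residual_df: int
    reference: str = ""
    n_reference_trials: int = 0
    n_category_trials: int = 0


def compare_with_categories(reference_scalars: np.ndarray,
                            category_scalars: np.ndarray,
                            category_conditions: np.ndarray,
                            reference_label: str = "preferred",
                            categories: tuple[str, ...] = CATEGORY_LEVELS) -> CategoryComparison:
    """OLS over pooled trials: preferred-numerosity trials are the reference
    level, each category gets an indicator; each coefficient's t tests that
    category against the preferred-numerosity response."""
    ref = np.asarray(reference_scalars, dtype=float)
    cat = np.asarray(category_scalars, dtype=float)
    conds = np.asarray([str(c) for c in category_conditions])
    missing = [c for c in categories if c not in set(conds)]
    if missing:
        raise ValueError(f"missing category trial(s) for: {missing}")
    unknown = sorted(set(conds) - set(categories))
    if unknown:
        raise ValueError(f"unknown category label(s): {unknown}")
    y = np.concatenate([ref, cat])
    pooled = np.concatenate([np.full(ref.size, reference_label), conds])
    X = np.ones((y.size, 1 + len(categories)))
    for j, lev in enumerate(categories, start=1):
        X[:, j] = pooled == lev
    res = sm.OLS(y, X).fit()
    glm = pd.DataFrame(
        {
            "term": ["intercept"] + list(categories),
            "estimate": np.asarray(res.params),
            "se": np.asarray(res.bse),
            "t": np.asarray(res.tvalues),
            "df": int(res.df_resid),
            "p": np.asarray(res.pvalues),
        }
    )
    return CategoryComparison(
        glm=glm,
        residual_df=int(res.df_resid),
        reference=reference_label,
        n_reference_trials=int(ref.size),
        n_category_trials=int(cat.size),
    )
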