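"""Statistical comparisons over the results table.

Three analyses mirror how simulation benchmarks of SDMs are usually
summarised:

* a one-sample Wilcoxon signed-rank test comparing the 25 per-run standard
  metrics of a configuration cell against the corresponding independent
  metric value;
* a two-sample Wilcoxon (Mann–Whitney) rank-sum test comparing standard
  metrics between the high and low grid resolutions;
* an ordinary least-squares factor analysis of exp(AUC) on the five design
  factors (resolution, algorithm, positional accuracy, sample size treated
  as categorical, and species specialisation), with and without all two-way
  interactions, ranked by AIC, plus a drop-one-factor table.

Wilcoxon p-values are exact for small tie-free samples (signed-rank: n ≤ 25;
rank-sum: n₁ + n₂ ≤ 25) and use the normal approximation with continuity
(and tie) correction otherwise.  Exact zero differences are dropped before
the signed-rank test (Wilcoxon's original policy; the Pratt variant would
give different p-values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .errors import DegenerateDataError, ParameterError, UndefinedMetricError

__all__ = [
    "WilcoxonResult",
    "LinearModelSummary",
    "wilcoxon_one_sample",
    "wilcoxon_two_sample",
    "fit_auc_model",
    "drop_term_table",
    "resolution_comparison",
    "standard_vs_independent",
]

FACTORS = ["resolution", "algorithm", "precision_level", "sample_size", "species"]


class WilcoxonResult(NamedTuple):
    statistic: float
    pvalue: float


def wilcoxon_one_sample(values, mu0: float = 0.0) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of location against ``mu0``.

    Exact null distribution for n ≤ 25 without tied absolute differences;
    normal approximation with continuity correction otherwise.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0.0]
    if len(d) == 0:
        raise UndefinedMetricError("all differences are zero; test undefined")
    tie_free = len(np.unique(np.abs(d))) == len(d)
    method = "exact" if (len(d) <= 25 and tie_free) else "approx"
    res = stats.wilcoxon(
        d, alternative="two-sided", method=method, correction=True,
        zero_method="wilcox",
    )
    return WilcoxonResult(float(res.statistic), float(res.pvalue))


def wilcoxon_two_sample(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact for tie-free samples with n₁ + n₂ ≤ 25; normal approximation with
    tie and continuity correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 25 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# exp(AUC) linear factor model
# ---------------------------------------------------------------------------

@dataclass
class LinearModelSummary:
    """One fitted OLS factor model of exp(AUC)."""

    terms: list[str]
    formula: str
    aic: float
    adjusted_r2: float
    df_model: int
    df_resid: int
    nobs: int
    delta_aic: float | None = None
    params: pd.Series = field(default_factory=pd.Series, repr=False)


def _formula(terms: list[str], include_interactions: bool) -> str:
    parts = [f"C({t})" for t in terms]
    rhs = " + ".join(parts)
    if include_interactions and len(parts) > 1:
        rhs = f"({rhs})**2"
    return f"exp_auc ~ {rhs}"


def _check_factors(results: pd.DataFrame, terms: list[str]) -> None:
    for t in terms:
        if t not in results.columns:
            raise ParameterError(f"results table lacks factor column {t!r}")
        if results[t].nunique() < 2:
            raise DegenerateDataError(f"factor {t!r} has fewer than 2 levels")


def _aliased_terms(design: np.ndarray, names: list[str]) -> list[str]:
    """Design columns that do not increase the rank (QR sweep)."""
    aliased = []
    rank = 0
    kept = np.empty((design.shape[0], 0))
    for j, name in enumerate(names):
        candidate = np.column_stack([kept, design[:, j]])
        new_rank = np.linalg.matrix_rank(candidate)
        if new_rank > rank:
            kept = candidate
            rank = new_rank
        else:
            aliased.append(name)
    return aliased


def fit_auc_model(
    results: pd.DataFrame,
    include_interactions: bool = False,
    auc_col: str = "auc_standard",
    terms: list[str] | None = None,
) -> LinearModelSummary:
    """OLS fit of exp(AUC) on categorical design factors.

    Sample size is treated as categorical (its levels are discrete design
    points, not a continuum).  AIC comes from the Gaussian log-likelihood
    (−2·llf + 2·k); differences between models on the same response are the
    meaningful quantity, and they are invariant to the additive constant.
    """
    terms = list(FACTORS) if terms is None else list(terms)
    _check_factors(results, terms)
    if auc_col not in results.columns:
        raise ParameterError(f"results table lacks AUC column {auc_col!r}")
    df = results[terms + [auc_col]].dropna().copy()
    df["exp_auc"] = np.exp(df[auc_col])
    formula = _formula(terms, include_interactions)
    model = smf.ols(formula, data=df)
    design = model.exog
    if np.linalg.matrix_rank(design) < design.shape[1]:
        aliased = _aliased_terms(design, list(model.exog_names))
        raise DegenerateDataError(
            f"rank-deficient design; aliased terms: {aliased}"
        )
    fit = model.fit()
    return LinearModelSummary(
        terms=terms,
        formula=formula,
        aic=float(fit.aic),
        adjusted_r2=float(fit.rsquared_adj),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        nobs=int(fit.nobs),
        params=fit.params,
    )


def drop_term_table(
    results: pd.DataFrame,
    auc_col: str = "auc_standard",
    terms: list[str] | None = None,
) -> pd.DataFrame:
    """Model-comparison table: full (±interactions) and drop-one-factor rows.

    Rows: the full model with all two-way interactions, the full model
    without interactions, then the no-interaction model minus each single
    factor.  Columns: the degrees of freedom attributable to the row (model
    df for the two full models, the dropped factor's parameter count for drop
    rows), AIC difference to the best model, and adjusted R².
    """
    terms = list(FACTORS) if terms is None else list(terms)
    full_int = fit_auc_model(results, True, auc_col, terms)
    full = fit_auc_model(results, False, auc_col, terms)
    rows = [
        {"model": "full with interactions", "df": full_int.df_model,
         "aic": full_int.aic, "adjusted_r2": full_int.adjusted_r2},
        {"model": "full without interactions", "df": full.df_model,
         "aic": full.aic, "adjusted_r2": full.adjusted_r2},
    ]
    for t in terms:
        reduced = fit_auc_model(
            results, False, auc_col, [u for u in terms if u != t]
        )
        rows.append(
            {
                "model": f"- {t}",
                "df": full.df_model - reduced.df_model,
                "aic": reduced.aic,
                "adjusted_r2": reduced.adjusted_r2,
            }
        )
    table = pd.DataFrame(rows)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return table[["model", "df", "delta_aic", "adjusted_r2", "aic"]]


# ---------------------------------------------------------------------------
# Canned comparisons over a results table
# ---------------------------------------------------------------------------

def standard_vs_independent(
    results: pd.DataFrame,
    metric: str = "auc",
    group_by: list[str] = ("species", "algorithm", "sample_size"),
) -> pd.DataFrame:
    """One-sample Wilcoxon of per-run standard metrics vs the independent one.

    Within each group, the 25 standard values of a cell are tested against
    the median independent value of the same runs (the independent metric
    plays the role of the known reference level mu0).
    """
    std_col, ind_col = f"{metric}_standard", f"{metric}_independent"
    rows = []
    for key, df in results.groupby(list(group_by), sort=True):
        mu0 = df[ind_col].median()
        try:
            res = wilcoxon_one_sample(df[std_col].to_numpy(), mu0)
            stat, p = res.statistic, res.pvalue
        except UndefinedMetricError:
            stat, p = np.nan, np.nan
        row = dict(zip(group_by, key if isinstance(key, tuple) else (key,)))
        row.update(
            {"mu0_independent": mu0, "median_standard": df[std_col].median(),
             "statistic": stat, "pvalue": p, "n": len(df)}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def resolution_comparison(
    results: pd.DataFrame, metric: str = "auc_standard"
) -> WilcoxonResult:
    """Two-sample Wilcoxon of a standard metric between grid resolutions."""
    res_levels = sorted(results["resolution"].unique())
    if len(res_levels) != 2:
        raise ParameterError("resolution comparison needs exactly two levels")
    a = results.loc[results["resolution"] == res_levels[0], metric].dropna()
    b = results.loc[results["resolution"] == res_levels[1], metric].dropna()
    return wilcoxon_two_sample(a.to_numpy(), b.to_numpy())
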