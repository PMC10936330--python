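"""Group-level statistics: quasi log-link GLM for band RMS,
Kolmogorov-Smirnov contrasts, chi-squared on stun-success counts, and the
cohort report tables.

The RMS model follows the printed quasi-GLM: identity-variance family
with log link (``EEGrms ~ treatment + period``), dispersion estimated
from Pearson residuals, and repeated measures within animal handled by
animal-clustered robust standard errors.  Post hoc contrasts use the
two-sample Kolmogorov-Smirnov comparison of distributions; good-stun
counts per treatment are compared with Pearson's chi-squared test
(no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

PERIODS = ("T0", "T1", "T2")


@dataclass
class GLMFit:
    """Quasi log-link GLM fit: coefficients on the log scale."""

    params: pd.Series
    bse: pd.Series                # cluster-robust standard errors
    dispersion: float             # Pearson-residual dispersion estimate
    fitted: np.ndarray
    converged: bool
    n_iter: int
    response: str
    result: object = field(repr=False, default=None)

    def summary(self) -> str:
        return str(self.result.summary())


@dataclass(frozen=True)
class KSResult:
    d: float
    pvalue: float
    n1: int
    n2: int


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    pvalue: float
    expected: np.ndarray
    small_expected: bool          # True when any expected count < 5


def fit_quasi_log_glm(data: pd.DataFrame, response: str = "value",
                      treatment_col: str = "treatment", period_col: str = "period",
                      animal_col: str = "animal") -> GLMFit:
    """Fit ``log E[y] = treatment + period`` with constant variance
    (quasi family), dispersion from Pearson residuals, and animal-clustered
    robust standard errors.

    Raises on non-convergence rather than returning a silently bad fit.
    """
    for col in (response, treatment_col, period_col, animal_col):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    if data[treatment_col].nunique() < 1 or data[period_col].nunique() < 1:
        raise ValueError("need at least one treatment and one period")
    y = data[response].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("log-link quasi GLM requires strictly positive responses")
    terms = []
    if data[treatment_col].nunique() > 1:
        terms.append(f"C({treatment_col})")
    if data[period_col].nunique() > 1:
        terms.append(f"C({period_col})")
    formula = f"{response} ~ " + (" + ".join(terms) if terms else "1")
    model = smf.glm(formula, data=data,
                    family=sm.families.Gaussian(link=sm.families.links.Log()))
    groups = data[animal_col]
    import warnings as _warnings

    with _warnings.catch_warnings():
        # a perfect (noiseless) fit triggers a spurious separation warning
        _warnings.filterwarnings("ignore", category=RuntimeWarning)
        _warnings.filterwarnings("ignore", message=".*Perfect separation.*")
        if groups.nunique() > 1:
            result = model.fit(cov_type="cluster", cov_kwds={"groups": groups})
        else:
            result = model.fit()
    converged = bool(getattr(result, "converged", True))
    if not converged and float(result.scale) < 1e-10 * max(1.0, float(np.mean(y)) ** 2):
        converged = True  # exact fit: IRLS stops on zero deviance, flag misreports
    if not converged:
        raise RuntimeError("quasi log-link GLM did not converge")
    return GLMFit(
        params=result.params,
        bse=result.bse,
        dispersion=float(result.scale),
        fitted=np.asarray(result.fittedvalues),
        converged=converged,
        n_iter=int(getattr(result, "fit_history", {}).get("iteration", 0) or 0),
        response=response,
        result=result,
    )


def ks_two_sample(a, b, method: str = "auto") -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the maximum absolute difference between the two empirical CDFs;
    the p-value uses scipy's default method (exact for small samples,
    asymptotic otherwise; ``method="asymp"`` forces the asymptotic form).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must contain at least two finite values")
    res = sp_stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return KSResult(d=float(res.statistic), pvalue=float(res.pvalue),
                    n1=int(a.size), n2=int(b.size))


def chi2_test(table) -> Chi2Result:
    """Pearson chi-squared test of homogeneity, no continuity correction.

    ``table`` is an (rows x cols) array of counts, e.g. per-treatment
    (sustained, not-sustained) counts.  A flag marks expected counts < 5.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold non-negative integer counts")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, dof, expected = sp_stats.chi2_contingency(table, correction=False)
    return Chi2Result(statistic=float(stat), df=int(dof), pvalue=float(p),
                      expected=expected, small_expected=bool((expected < 5).any()))


# ---------------------------------------------------------------------------
# cohort tables


def _mean_sd_table(df: pd.DataFrame, value: str, index: str, columns: list[str]
                   ) -> pd.DataFrame:
    g = df.groupby(columns + [index], observed=True)[value]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out


def percentage_power_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean (+- SD) percentage power per band by treatment and period (T0, T1)."""
    sub = rows[rows["period"].isin(["T0", "T1"])]
    return _mean_sd_table(sub, "pct", "band", ["treatment", "period"])


def rms_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean (+- SD) band RMS by treatment and period (T0, T1, T2)."""
    return _mean_sd_table(rows, "rms", "band", ["treatment", "period"])


def db_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean (+- SD) dB change from baseline by treatment and period (T1, T2)."""
    sub = rows[rows["period"].isin(["T1", "T2"])]
    return _mean_sd_table(sub, "db", "band", ["treatment", "period"])


def good_stun_counts(assessments: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment counts of sustained / not-sustained animals."""
    rows = []
    for tx, grp in assessments.groupby("treatment", observed=True):
        good = int(grp["sustained"].sum())
        rows.append({"treatment": tx, "sustained": good,
                     "not_sustained": int(len(grp) - good),
                     "n": int(len(grp)),
                     "proportion": good / len(grp)})
    return pd.DataFrame(rows)


def rank_treatments(counts: pd.DataFrame) -> list[str]:
    """Treatments ordered by decreasing good-stun proportion (ties broken by
    treatment label for determinism)."""
    ordered = counts.sort_values(["proportion", "treatment"],
                                 ascending=[False, True])
    return list(ordered["treatment"])


@dataclass
class CohortTables:
    """The three report tables plus the stun-count table and ranking."""

    percentage_power: pd.DataFrame
    rms: pd.DataFrame
    db_change: pd.DataFrame
    counts: pd.DataFrame
    ranking: list[str]
    chi2: Chi2Result | None
    threshold: float


def summarize_cohort(period_rows: pd.DataFrame, db_rows: pd.DataFrame,
                     assessments: pd.DataFrame, threshold: float = 30.0
                     ) -> CohortTables:
    """Build the cohort report: percentage power (T0, T1), RMS (T0-T2) and
    dB change (T1, T2) by treatment x period x band, plus the good-stun
    count table with its chi-squared test and the treatment ranking."""
    if len(assessments) == 0:
        raise ValueError("no assessed animals")
    counts = good_stun_counts(assessments)
    chi2 = None
    if len(counts) >= 2:
        tab = counts[["sustained", "not_sustained"]].to_numpy()
        if tab.sum(axis=0).min() > 0:
            chi2 = chi2_test(tab)
    return CohortTables(
        percentage_power=percentage_power_table(period_rows),
        rms=rms_table(period_rows),
        db_change=db_table(db_rows),
        counts=counts,
        ranking=rank_treatments(counts),
        chi2=chi2,
        threshold=threshold,
    )
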