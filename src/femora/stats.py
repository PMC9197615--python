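"""Cohort statistics for diaphyseal morphometry.

Covers the comparisons run on the three cohorts (modern, Initial/Early
Jomon, Late Jomon): a chi-square goodness-of-fit check of normality per
parameter, a split-plot (repeated-measures two-factor) ANOVA with cohort as
the between-subject factor and diaphyseal level as the within-subject
factor, Scheffé multiple comparisons on the cohort means, a principal
component analysis of per-specimen parameter means on the correlation
matrix, a chi-squared independence test for the lateral-curvature
contingency table, and period-group assignment from calibrated radiocarbon
ages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GofResult",
    "AnovaResult",
    "PCAResult",
    "ChiSqResult",
    "PeriodAssignment",
    "normality_gof",
    "rm_anova_scheffe",
    "pca_on_means",
    "chi_squared_independence",
    "assign_periods",
    "PERIOD_BOUNDARY_CAL_BP",
]

#: cut between the Late Jomon (ca. 4,500-4,000 cal BP) and Initial/Early
#: Jomon (ca. 10,200-6,500 cal BP) groups; any value inside the gap between
#: the two stated ranges separates them identically
PERIOD_BOUNDARY_CAL_BP = 6000.0


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    p: float
    n_bins: int


@dataclass
class AnovaResult:
    """Split-plot ANOVA table plus Scheffé cohort contrasts.

    ``table`` rows: cohort, subjects_within_cohort, level, cohort_x_level,
    error_within, total — with sum-of-squares, df, mean square, F and p.
    ``scheffe`` has one row per cohort pair with the contrast on subject
    means, its F-ratio, the Scheffé critical value and a significance flag.
    """

    table: pd.DataFrame
    scheffe: pd.DataFrame
    alpha: float
    dropped_specimens: tuple = ()


@dataclass
class PCAResult:
    """Correlation-matrix PCA: loadings (columns = components), eigenvalues
    and per-specimen scores."""

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    scores: pd.DataFrame
    column_means: np.ndarray = field(default=None)
    column_sds: np.ndarray = field(default=None)


@dataclass(frozen=True)
class ChiSqResult:
    statistic: float
    df: int
    p: float
    expected: np.ndarray


@dataclass(frozen=True)
class PeriodAssignment:
    specimen_id: str
    midpoint_cal_bp: float
    group: str  # initial_early_jomon | late_jomon


def normality_gof(sample, n_bins: Optional[int] = None) -> GofResult:
    """Chi-square goodness-of-fit of a sample against a fitted normal.

    Equal-probability bins are cut at normal quantiles of the sample mean
    and SD; the statistic is the usual sum of (O - E)^2 / E with
    ``df = bins - 3`` (two estimated parameters).  The default bin count
    follows the 2 * n^{2/5} rule.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError(f"need at least 8 observations, got {x.size}")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("sample has zero variance")
    if n_bins is None:
        n_bins = max(5, int(np.floor(2.0 * x.size**0.4)))
    if n_bins < 4:
        raise ValueError("need at least 4 bins for df >= 1")
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.concatenate([[-np.inf], sps.norm.ppf(qs, loc=mu, scale=sd), [np.inf]])
    observed, _ = np.histogram(x, bins=edges)
    expected = x.size / n_bins
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = n_bins - 3
    return GofResult(statistic=statistic, df=df, p=float(sps.chi2.sf(statistic, df)), n_bins=n_bins)


def _balanced_wide(table: pd.DataFrame, parameter: Optional[str]):
    df = table.copy()
    if parameter is not None and "parameter" in df.columns:
        df = df[df["parameter"] == parameter]
    required = {"specimen_id", "cohort", "level", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")
    wide = df.pivot_table(
        index=["cohort", "specimen_id"], columns="level", values="value"
    )
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"excluding {len(incomplete)} specimen(s) with missing levels: "
            f"{[s for _, s in incomplete]}",
            stacklevel=3,
        )
        wide = wide.drop(index=incomplete)
    return wide, tuple(s for _, s in incomplete)


def rm_anova_scheffe(
    table: pd.DataFrame,
    parameter: Optional[str] = None,
    alpha: float = 0.05,
    greenhouse_geisser: bool = False,
) -> AnovaResult:
    """Split-plot ANOVA (cohort between, level within) with Scheffé post hoc.

    ``table`` is tidy with columns ``specimen_id``, ``cohort``, ``level``,
    ``value`` (optionally filtered by a ``parameter`` column).  Specimens
    missing any level are excluded listwise with a warning.  The cohort
    effect is tested against the specimen-within-cohort stratum, the level
    and interaction effects against the within-subject residual.  Scheffé
    contrasts compare cohort means of the per-specimen level means using
    the between-subject error, so they can never be more liberal than an
    unadjusted pairwise F at the same alpha.  ``greenhouse_geisser``
    applies the epsilon correction to the within-subject tests.
    """
    wide, dropped = _balanced_wide(table, parameter)
    if wide.shape[0] < 2:
        raise ValueError("need at least two complete specimens")
    cohorts = wide.index.get_level_values("cohort")
    groups = list(dict.fromkeys(cohorts))
    if len(groups) < 2:
        raise ValueError("need at least two cohorts")
    L = wide.shape[1]
    if L < 2:
        raise ValueError("need at least two levels")
    data = wide.to_numpy(dtype=float)
    n_subj = data.shape[0]
    grand = data.mean()

    subj_means = data.mean(axis=1)
    group_sizes = np.array([(cohorts == g).sum() for g in groups])
    if (group_sizes < 2).any():
        raise ValueError("each cohort needs at least two specimens")
    group_means = np.array([data[cohorts == g].mean() for g in groups])
    level_means = data.mean(axis=0)
    cell_means = np.vstack([data[cohorts == g].mean(axis=0) for g in groups])

    ss_total = float(((data - grand) ** 2).sum())
    ss_between_subj = float(L * ((subj_means - grand) ** 2).sum())
    ss_cohort = float(L * (group_sizes * (group_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_cohort
    ss_level = float(n_subj * ((level_means - grand) ** 2).sum())
    ss_inter = float(
        (
            group_sizes[:, None]
            * (cell_means - group_means[:, None] - level_means[None, :] + grand) ** 2
        ).sum()
    )
    ss_error = ss_total - ss_cohort - ss_subj_within - ss_level - ss_inter

    g = len(groups)
    df_cohort = g - 1
    df_subj = n_subj - g
    df_level = L - 1
    df_inter = (g - 1) * (L - 1)
    df_error = (n_subj - g) * (L - 1)

    eps = 1.0
    if greenhouse_geisser:
        # pooled within-cohort covariance of the level measurements
        resid = np.vstack([data[cohorts == gr] - cell_means[i] for i, gr in enumerate(groups)])
        S = np.cov(resid, rowvar=False, ddof=g)
        # Greenhouse-Geisser epsilon on the double-centered covariance
        Sc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
        eps = float(np.trace(Sc) ** 2 / ((L - 1) * (Sc**2).sum()))
        eps = min(1.0, max(eps, 1.0 / (L - 1)))

    ms_cohort = ss_cohort / df_cohort
    ms_subj = ss_subj_within / df_subj
    ms_level = ss_level / df_level
    ms_inter = ss_inter / df_inter
    ms_error = ss_error / df_error

    def _ratio(num: float, den: float) -> float:
        # zero error strata occur for degenerate (noise-free synthetic) data
        if den > 0:
            return num / den
        return 0.0 if num == 0 else np.inf

    f_cohort = _ratio(ms_cohort, ms_subj)
    f_level = _ratio(ms_level, ms_error)
    f_inter = _ratio(ms_inter, ms_error)
    p_cohort = float(sps.f.sf(f_cohort, df_cohort, df_subj))
    p_level = float(sps.f.sf(f_level, eps * df_level, eps * df_error))
    p_inter = float(sps.f.sf(f_inter, eps * df_inter, eps * df_error))

    rows = [
        ("cohort", ss_cohort, df_cohort, ms_cohort, f_cohort, p_cohort),
        ("subjects_within_cohort", ss_subj_within, df_subj, ms_subj, np.nan, np.nan),
        ("level", ss_level, df_level, ms_level, f_level, p_level),
        ("cohort_x_level", ss_inter, df_inter, ms_inter, f_inter, p_inter),
        ("error_within", ss_error, df_error, ms_error, np.nan, np.nan),
        ("total", ss_total, n_subj * L - 1, np.nan, np.nan, np.nan),
    ]
    anova_table = pd.DataFrame(
        rows, columns=["source", "ss", "df", "ms", "F", "p"]
    ).set_index("source")

    # Scheffé on cohort means of the per-specimen level means; the error
    # term for subject means is MS_subjects_within / L
    ms_means = ms_subj / L
    f_crit = float(sps.f.isf(alpha, df_cohort, df_subj))
    scheffe_rows = []
    cohort_mean_of_means = {
        gr: float(subj_means[cohorts == gr].mean()) for gr in groups
    }
    for i in range(g):
        for j in range(i + 1, g):
            a, b = groups[i], groups[j]
            diff = cohort_mean_of_means[a] - cohort_mean_of_means[b]
            se2 = ms_means * (1.0 / group_sizes[i] + 1.0 / group_sizes[j])
            t2 = _ratio(diff**2, se2)
            crit = df_cohort * f_crit
            p = float(sps.f.sf(t2 / df_cohort, df_cohort, df_subj))
            scheffe_rows.append(
                {
                    "cohort_a": a,
                    "cohort_b": b,
                    "mean_difference": diff,
                    "F_ratio": t2,
                    "critical_value": crit,
                    "p": p,
                    "significant": bool(t2 > crit),
                }
            )
    scheffe = pd.DataFrame(scheffe_rows)
    return AnovaResult(table=anova_table, scheffe=scheffe, alpha=alpha, dropped_specimens=dropped)


def pca_on_means(matrix: pd.DataFrame) -> PCAResult:
    """PCA of per-specimen parameter means on the correlation matrix.

    Columns are centred and scaled (sample SD), so eigenvalues sum to the
    number of variables.  Loadings are signed so that the largest-magnitude
    loading of each component is positive, making runs reproducible.
    """
    df = pd.DataFrame(matrix)
    if df.shape[0] < 3:
        raise ValueError("need at least three specimens")
    X = df.to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [c for c, s in zip(df.columns, sds) if s == 0]
        raise ValueError(f"constant column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sds
    R = np.corrcoef(Z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for k in range(eigvecs.shape[1]):
        if eigvecs[np.argmax(np.abs(eigvecs[:, k])), k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    comp_names = [f"Z{k + 1}" for k in range(eigvecs.shape[1])]
    loadings = pd.DataFrame(eigvecs, index=df.columns, columns=comp_names)
    scores = pd.DataFrame(Z @ eigvecs, index=df.index, columns=comp_names)
    return PCAResult(
        loadings=loadings,
        eigenvalues=eigvals,
        scores=scores,
        column_means=X.mean(axis=0),
        column_sds=sds,
    )


def chi_squared_independence(table) -> ChiSqResult:
    """Pearson chi-squared independence test on a cohort x pattern table.

    All-zero rows and columns are dropped before computing the expected
    counts from the margins; a warning is emitted when any expected count
    falls below 5 (the usual small-sample caveat for archaeological group
    sizes).
    """
    counts = pd.DataFrame(table).to_numpy(dtype=float)
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("table must contain nonnegative integer counts")
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least two nonzero rows and columns")
    res = sps.chi2_contingency(counts, correction=False)
    if np.any(res.expected_freq < 5):
        warnings.warn(
            "some expected counts are below 5; the chi-squared approximation "
            "may be inaccurate",
            stacklevel=2,
        )
    return ChiSqResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p=float(res.pvalue),
        expected=res.expected_freq,
    )


def assign_periods(intervals: pd.DataFrame) -> pd.DataFrame:
    """Assign Jomon period groups from calibrated radiocarbon ages.

    ``intervals`` is tidy with one row per 68.3 % highest-probability
    interval: columns ``specimen_id``, ``cal_bp_from`` (older bound),
    ``cal_bp_to`` (younger bound) and ``probability_pct``.  Each specimen is
    summarized by the midpoint of its highest-probability interval and
    assigned ``late_jomon`` below the 6,000 cal BP boundary, otherwise
    ``initial_early_jomon``.  Midpoints outside both stated period ranges
    draw a warning but are still assigned by the boundary.
    """
    required = {"specimen_id", "cal_bp_from", "cal_bp_to", "probability_pct"}
    missing = required - set(intervals.columns)
    if missing:
        raise ValueError(f"intervals table lacks columns {sorted(missing)}")
    rows = []
    for sid, grp in intervals.groupby("specimen_id", sort=False):
        best = grp.loc[grp["probability_pct"].idxmax()]
        mid = 0.5 * (float(best["cal_bp_from"]) + float(best["cal_bp_to"]))
        group = (
            "late_jomon" if mid < PERIOD_BOUNDARY_CAL_BP else "initial_early_jomon"
        )
        if not (4000 <= mid <= 4500 or 6500 <= mid <= 10200):
            warnings.warn(
                f"{sid}: calibrated midpoint {mid:.0f} cal BP lies outside "
                "both stated period ranges; assigned by the 6,000 cal BP cut",
                stacklevel=2,
            )
        rows.append(
            {"specimen_id": sid, "midpoint_cal_bp": mid, "group": group}
        )
    return pd.DataFrame(rows)
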