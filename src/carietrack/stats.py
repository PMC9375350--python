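"""Statistical procedures: chi-square homogeneity, one-way
repeated-measures ANOVA with Bonferroni post hocs, and Cohen's
weighted kappa.

The repeated-measures ANOVA is the classical univariate
within-subject partition for one factor (time) with three levels:

    SS_total = SS_time + SS_subject + SS_error
    F = MS_time / MS_error,  df = (t-1, (t-1)(n-1))

Post hoc comparisons are paired t-tests of the later intervals
against the first (12-vs-6 and 18-vs-6 months), Bonferroni-corrected
for the 2 comparisons.  No sphericity correction is applied by
default; the Greenhouse-Geisser epsilon is available as an option and
recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "ChiSquareResult",
    "RmAnovaResult",
    "KappaResult",
    "DegenerateTableError",
    "InsufficientDataError",
    "chi_square",
    "rm_anova",
    "weighted_kappa",
]


class DegenerateTableError(ValueError):
    """A contingency-table marginal is zero; expected counts undefined."""


class InsufficientDataError(ValueError):
    """Too few complete cases for the requested analysis."""


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class PostHoc:
    """One paired comparison against the first interval."""

    label: str
    t: float
    df: int
    p_raw: float
    p_adjusted: float  # Bonferroni: min(1, raw * n_comparisons)


@dataclass(frozen=True)
class RmAnovaResult:
    F: float
    df_time: float
    df_error: float
    p: float
    posthoc: tuple[PostHoc, ...]
    n: int
    epsilon: float | None = None  # Greenhouse-Geisser, if applied


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    weighting: str


def chi_square(table) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity/independence.

    ``table`` is any 2-D array-like of non-negative counts, at least
    2x2.  Uses the standard statistic sum((O-E)^2/E) with
    df = (r-1)(c-1), no continuity correction.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError("zero marginal: expected counts undefined")
    res = sps.chi2_contingency(obs, correction=False)
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue))


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of times."""
    S = np.cov(data, rowvar=False, ddof=1)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    grand = S.mean()
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (S.mean(axis=1) ** 2).sum() + k**2 * grand**2)
    return float(num / den) if den > 0 else 1.0


def rm_anova(
    data,
    labels: tuple[int, ...] = (6, 12, 18),
    correction: str | None = None,
) -> RmAnovaResult:
    """One-way within-subject ANOVA over repeated interval measurements.

    Parameters
    ----------
    data:
        (n_subjects, n_times) array of complete cases — e.g. each
        child's caries increment at 6, 12 and 18 months — or one
        multiply-imputed completed set.
    labels:
        Interval labels; the first is the reference for post hocs.
    correction:
        ``None`` (default) or ``"gg"`` for Greenhouse-Geisser.

    Zero within-subject error variance (all subjects identical across
    times after centering) returns F = 0 with p = 1 rather than NaN.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(labels):
        raise ValueError(f"data must be (n, {len(labels)})")
    n, t = x.shape
    if n < 2:
        raise InsufficientDataError("repeated-measures ANOVA needs >= 2 complete cases")
    if np.isnan(x).any():
        raise ValueError("complete cases only; impute or drop missing rows first")

    grand = x.mean()
    ss_time = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = t * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_error = ss_total - ss_time - ss_subj

    df_time, df_error = float(t - 1), float((t - 1) * (n - 1))
    eps = None
    if correction == "gg":
        eps = _gg_epsilon(x)
        df_time, df_error = eps * df_time, eps * df_error
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")

    ms_error = ss_error / ((t - 1) * (n - 1))
    if ms_error <= 0 or np.isclose(ss_error, 0.0, atol=1e-12 * max(ss_total, 1.0)):
        F, p = 0.0, 1.0
    else:
        F = (ss_time / (t - 1)) / ms_error
        p = float(sps.f.sf(F, df_time, df_error))

    n_comp = t - 1
    posthoc = []
    for j in range(1, t):
        diff = x[:, j] - x[:, 0]
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                tstat, praw = 0.0, 1.0
            else:  # nonzero constant shift: evidence is unbounded
                tstat, praw = np.inf if diff.mean() > 0 else -np.inf, 0.0
        else:
            tt = sps.ttest_rel(x[:, j], x[:, 0])
            tstat, praw = float(tt.statistic), float(tt.pvalue)
        posthoc.append(
            PostHoc(
                label=f"{labels[j]}-vs-{labels[0]}",
                t=tstat,
                df=n - 1,
                p_raw=praw,
                p_adjusted=min(1.0, praw * n_comp),
            )
        )

    return RmAnovaResult(
        F=float(F),
        df_time=df_time,
        df_error=df_error,
        p=float(p),
        posthoc=tuple(posthoc),
        n=n,
        epsilon=eps,
    )


def weighted_kappa(ratings_a, ratings_b, weighting: str = "linear") -> KappaResult:
    """Cohen's weighted kappa for two ordinal rating vectors.

    kappa_w = 1 - sum(w*O) / sum(w*E) with linear or quadratic
    disagreement weights on the ordinal (e.g. ICDAS code) scale.
    Defaults to linear weights.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size == 0:
        raise ValueError("empty rating vectors")
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    if weighting not in ("linear", "quadratic"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if np.array_equal(a, b):  # perfect agreement even if a category is constant
        return KappaResult(1.0, weighting)
    k = cohen_kappa_score(a, b, weights=weighting)
    return KappaResult(float(k), weighting)
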