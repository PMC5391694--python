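"""Diversity and multivariate statistics on count matrices.

Shannon diversity H' (natural log) per plant genus, Welch two-sample t-tests
between native and alien groups, PCA ordination of functional composition, and
a homogeneity-of-dispersion test (Mahalanobis distance to group centroid, F
statistic, parametric and permutation p-values).

Group-level H' is reported as the arithmetic mean of per-genus values, which is
the only convention under which a single group value and a t-test across genera
are mutually consistent; a pooled-count variant is exposed separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .records import InteractionMatrix
from .traits import FunctionalMatrix, type_proportions

logger = logging.getLogger(__name__)


def shannon(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity H' in nats of a non-negative count vector."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValidationError("shannon expects a 1-D vector")
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValidationError("all-zero count vector has no diversity")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_rows(counts: np.ndarray) -> np.ndarray:
    """Vectorized per-row H' for a 2-D (or stacked 3-D) count array.

    Rows summing to zero yield H' = 0 with a warning-free fast path; callers
    that must reject zero rows do so beforehand.
    """
    c = np.asarray(counts, dtype=float)
    totals = c.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, c / np.where(totals > 0, totals, 1.0), 0.0)
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=-1)


def pooled_group_shannon(fm: FunctionalMatrix) -> dict[str, float]:
    """H' of per-status column totals (the pooled-count group convention)."""
    out = {}
    statuses = fm.status_array()
    for status in np.unique(statuses):
        out[str(status)] = shannon(fm.counts[statuses == status].sum(axis=0))
    return out


@dataclass(frozen=True)
class TTestResult:
    """Welch two-sample t-test with Welch-Satterthwaite degrees of freedom."""

    t: float
    df: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class DiversitySummary:
    per_genus_H: Mapping[str, float]
    group_mean: Mapping[str, float]
    group_se: Mapping[str, float]
    group_n: Mapping[str, int]


def welch_t(x, y) -> TTestResult:
    """Welch's unequal-variance t-test, two-sided.

    Degenerate inputs (zero variance in both samples) never raise: equal means
    give t=0, p=1; unequal means are flagged ``degenerate`` with p=0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("welch_t needs at least 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.isclose(x.mean(), y.mean()):
            return TTestResult(t=0.0, df=float(x.size + y.size - 2), p=1.0)
        warnings.warn("zero-variance samples with unequal means; p set to 0")
        sign = 1.0 if x.mean() > y.mean() else -1.0
        return TTestResult(
            t=sign * np.inf, df=float(x.size + y.size - 2), p=0.0, degenerate=True
        )
    sx, sy = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx**2 / (x.size - 1) + sy**2 / (y.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def _group_diversity(
    counts: np.ndarray, labels: Sequence[str], statuses: np.ndarray
) -> tuple[DiversitySummary, Optional[TTestResult]]:
    per_genus = {g: shannon(row) for g, row in zip(labels, counts)}
    values = np.array([per_genus[g] for g in labels])
    group_mean, group_se, group_n = {}, {}, {}
    for status in np.unique(statuses):
        v = values[statuses == status]
        group_mean[str(status)] = float(v.mean())
        group_se[str(status)] = float(
            v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
        )
        group_n[str(status)] = int(v.size)
    summary = DiversitySummary(
        per_genus_H=per_genus,
        group_mean=group_mean,
        group_se=group_se,
        group_n=group_n,
    )
    native = values[statuses == "native"]
    alien = values[statuses == "alien"]
    if native.size < 2 or alien.size < 2:
        logger.warning("t-test unavailable: need >= 2 genera per status")
        return summary, None
    return summary, welch_t(native, alien)


def group_functional_diversity(
    fm: FunctionalMatrix,
) -> tuple[DiversitySummary, Optional[TTestResult]]:
    """Per-genus exploration-type H', group means/SEs, native-vs-alien Welch t."""
    return _group_diversity(fm.counts, fm.row_labels, fm.status_array())


def group_fungal_diversity(
    m: InteractionMatrix,
) -> tuple[DiversitySummary, Optional[TTestResult]]:
    """Per-genus fungal-taxon H', group means/SEs, native-vs-alien Welch t."""
    return _group_diversity(m.counts, m.row_labels, m.status_array())


@dataclass(frozen=True)
class Ordination:
    scores: np.ndarray
    explained: np.ndarray
    row_labels: tuple[str, ...]


def pca_ordination(fm: FunctionalMatrix) -> Ordination:
    """PCA of row-proportion functional composition (covariance matrix).

    Rows are converted to proportions and column-centered; scores are the
    projections onto principal axes, ``explained`` the eigenvalue fractions.
    """
    if len(fm.row_labels) < 2:
        raise ValidationError("ordination needs at least 2 genera")
    from sklearn.decomposition import PCA

    props = type_proportions(fm)
    pca = PCA(n_components=min(props.shape))
    with warnings.catch_warnings():
        # a zero-variance matrix (all rows identical) divides 0/0 in the
        # explained-variance ratio; treated as all-zero below
        warnings.simplefilter("ignore", RuntimeWarning)
        scores = pca.fit_transform(props)
        explained = pca.explained_variance_ratio_
    if not np.isfinite(explained).all():  # zero total variance
        explained = np.zeros_like(explained)
    return Ordination(
        scores=scores, explained=explained, row_labels=fm.row_labels
    )


@dataclass(frozen=True)
class DispersionResult:
    distances: Mapping[str, float]
    F: float
    df1: int
    df2: int
    p_parametric: float
    p_permutation: float
    n_perm: int
    seed: Optional[int] = None


def _mahalanobis_to_centroids(
    X: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """Distance of each row to its group centroid, pooled-covariance metric.

    The pooled within-group covariance is inverted with the Moore-Penrose
    pseudo-inverse: with 6 trait columns and a handful of genera, singularity
    is the norm, not an edge case.
    """
    n, p = X.shape
    levels = np.unique(groups)
    centroids = {g: X[groups == g].mean(axis=0) for g in levels}
    resid = np.vstack([X[groups == g] - centroids[g] for g in levels])
    dof = max(n - len(levels), 1)
    cov = resid.T @ resid / dof
    cov_inv = np.linalg.pinv(cov, hermitian=True)
    d = np.empty(n)
    for i in range(n):
        v = X[i] - centroids[groups[i]]
        d[i] = np.sqrt(max(float(v @ cov_inv @ v), 0.0))
    return d


def _anova_f(values: np.ndarray, groups: np.ndarray) -> tuple[float, int, int]:
    levels = np.unique(groups)
    grand = values.mean()
    ss_between = sum(
        (values[groups == g].size) * (values[groups == g].mean() - grand) ** 2
        for g in levels
    )
    ss_within = sum(
        ((values[groups == g] - values[groups == g].mean()) ** 2).sum()
        for g in levels
    )
    df1 = len(levels) - 1
    df2 = values.size - len(levels)
    if df1 == 0 or df2 == 0:
        raise ValidationError("ANOVA needs >= 2 groups and residual df > 0")
    if ss_within == 0:
        return (0.0 if ss_between == 0 else np.inf), df1, df2
    return float((ss_between / df1) / (ss_within / df2)), df1, df2


def dispersion_test(
    fm: FunctionalMatrix,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> DispersionResult:
    """Homogeneity of multivariate dispersion between native and alien genera.

    Each genus's exploration-type proportion vector is measured against its
    group centroid in the Mahalanobis metric of the pooled within-group
    covariance; group difference in those distances is tested by one-way ANOVA
    (parametric F) and by ``n_perm`` full-recomputation label permutations
    (add-one p-value).
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    groups = fm.status_array()
    for g in np.unique(groups):
        if (groups == g).sum() < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 genera")
    X = type_proportions(fm)

    def statistic(labels: np.ndarray) -> float:
        d = _mahalanobis_to_centroids(X, labels)
        f, _, _ = _anova_f(d, labels)
        return f

    distances = _mahalanobis_to_centroids(X, groups)
    F, df1, df2 = _anova_f(distances, groups)
    p_par = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if statistic(rng.permutation(groups)) >= F:
            exceed += 1
    p_perm = (1 + exceed) / (1 + n_perm)
    return DispersionResult(
        distances=dict(zip(fm.row_labels, distances)),
        F=float(F),
        df1=df1,
        df2=df2,
        p_parametric=p_par,
        p_permutation=float(p_perm),
        n_perm=n_perm,
        seed=seed,
    )
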