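"""Statistical stage: agreement, group tests, ROC/Youden, DeLong, cluster bootstrap.

ROC machinery (empirical curve, trapezoidal AUC, DeLong variance/covariance,
Youden cutpoint) is implemented here from the placement-value formulation
rather than delegated, since the cutoff/tie-break conventions are part of the
package contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateTestError,
    DomainError,
    PreconditionError,
    UndefinedStatisticError,
)

LOWER_POSITIVE = "lower_positive"
HIGHER_POSITIVE = "higher_positive"


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary for one predictor against a binary outcome."""

    auc: float
    ci_low: float
    ci_high: float
    direction: str
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    youden: float
    curve: tuple[tuple[float, float], ...]  # (fpr, tpr) pairs

    @property
    def n_points(self) -> int:
        return len(self.curve)


@dataclass(frozen=True)
class AgreementResult:
    value: float
    kind: str  # "icc_2_1" | "cohen_kappa"


def _as_xy(x: Sequence[float], y: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise PreconditionError("x and y must be equal-length 1-D sequences")
    if not np.all(np.isfinite(x)):
        raise PreconditionError("x contains non-finite values")
    if not np.isin(y, (0, 1)).all():
        raise PreconditionError("y must contain only 0/1 labels")
    y = y.astype(int)
    if y.min() == y.max():
        raise DomainError("y must contain both classes")
    return x, y


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-sample placement values (midrank formulation).

    Scores follow the higher-positive convention.  Returns ``(auc, v10, v01)``
    with ``v10`` over positives and ``v01`` over negatives.
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    tz = sps.rankdata(np.concatenate([pos, neg]))
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float((tz[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return auc, v10, v01


def _curve(scores: np.ndarray, y: np.ndarray) -> tuple[tuple[float, float], ...]:
    """Empirical ROC polyline over all distinct thresholds, from (0,0) to (1,1)."""
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    distinct = np.r_[np.flatnonzero(np.diff(ss)), len(ss) - 1]
    tps = np.cumsum(ys)[distinct]
    fps = (distinct + 1) - tps
    p, q = ys.sum(), len(ys) - ys.sum()
    fpr = np.r_[0.0, fps / q]
    tpr = np.r_[0.0, tps / p]
    return tuple(zip(fpr.tolist(), tpr.tolist()))


def _scan_thresholds(x: np.ndarray, y: np.ndarray, direction: str
                     ) -> tuple[float, float, float, float]:
    """Best Youden cutpoint over midpoints of consecutive distinct values.

    Ties in J go to higher specificity, then to the lower cutoff.  Returns
    ``(cutoff, sensitivity_pct, specificity_pct, J)``.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    p = ys.sum()
    q = len(ys) - p
    bounds = np.flatnonzero(np.diff(xs) > 0)
    if len(bounds) == 0:
        raise UndefinedStatisticError("predictor is constant: no cutoff exists")
    cutoffs = (xs[bounds] + xs[bounds + 1]) / 2.0
    below_pos = np.cumsum(ys)[bounds]          # positives with x < cutoff
    below = bounds + 1.0                       # all with x < cutoff
    if direction == LOWER_POSITIVE:
        sens = below_pos / p
        spec = (q - (below - below_pos)) / q
    else:
        sens = (p - below_pos) / p
        spec = (below - below_pos) / q
    j = sens + spec - 1.0
    best = np.lexsort((cutoffs, -spec, -j))[0]
    return (float(cutoffs[best]), float(sens[best] * 100.0),
            float(spec[best] * 100.0), float(j[best]))


def empirical_roc(x: Sequence[float], y: Sequence[int],
                  direction: str = "auto") -> RocResult:
    """Empirical ROC with trapezoidal AUC, DeLong CI and Youden cutpoint.

    ``direction='auto'`` orients the predictor so the reported AUC is >= 0.5.
    The 95% CI uses the DeLong variance with a normal approximation, truncated
    to [0, 1].
    """
    x, y = _as_xy(x, y)
    if direction not in ("auto", LOWER_POSITIVE, HIGHER_POSITIVE):
        raise DomainError(f"unknown direction {direction!r}")
    if direction == "auto":
        auc_hp, _, _ = _placements(x, y)
        direction = HIGHER_POSITIVE if auc_hp >= 0.5 else LOWER_POSITIVE
    scores = x if direction == HIGHER_POSITIVE else -x
    auc, v10, v01 = _placements(scores, y)
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    half = 1.959963984540054 * np.sqrt(var)
    cutoff, sens, spec, j = _scan_thresholds(x, y, direction)
    return RocResult(
        auc=auc, ci_low=max(0.0, auc - half), ci_high=min(1.0, auc + half),
        direction=direction, cutoff=cutoff, sensitivity=sens,
        specificity=spec, youden=j, curve=_curve(scores, y))


def youden_cutoff(roc: RocResult, x: Sequence[float], y: Sequence[int]
                  ) -> tuple[float, float, float, float]:
    """Youden-optimal cutoff for the predictor underlying ``roc``.

    Returns ``(cutoff, sensitivity_pct, specificity_pct, J)``; candidates are
    midpoints between consecutive distinct predictor values, ties broken
    toward higher specificity then lower cutoff.
    """
    x, y = _as_xy(x, y)
    return _scan_thresholds(x, y, roc.direction)


def youden_index(sensitivity_pct: float, specificity_pct: float) -> float:
    """Youden's J from sensitivity and specificity given in percent."""
    if not (0 <= sensitivity_pct <= 100 and 0 <= specificity_pct <= 100):
        raise DomainError("sensitivity/specificity must be percentages in [0, 100]")
    return sensitivity_pct / 100.0 + specificity_pct / 100.0 - 1.0


def delong_test(x1: Sequence[float], x2: Sequence[float], y: Sequence[int]
                ) -> tuple[float, float, float, float]:
    """DeLong comparison of two correlated AUCs measured on the same samples.

    Predictors follow the higher-positive convention (orient beforehand).
    Returns ``(auc1, auc2, z, p)``; raises ``DegenerateTestError`` when the
    variance of the AUC difference vanishes (e.g. x2 a monotone transform
    of x1).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise PreconditionError("x1 and x2 must be paired (equal length)")
    _, y = _as_xy(x1, y)
    auc1, v10_1, v01_1 = _placements(x1, y)
    auc2, v10_2, v01_2 = _placements(x2, y)
    m, n = len(v10_1), len(v01_1)
    if m < 2 or n < 2:
        raise PreconditionError("need at least 2 samples in each class")
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    s = s10 / m + s01 / n
    var_diff = float(s[0, 0] + s[1, 1] - 2.0 * s[0, 1])
    if var_diff < 1e-12:
        raise DegenerateTestError("zero variance of the AUC difference")
    z = (auc1 - auc2) / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return auc1, auc2, float(z), float(p)


def univariate_r(x: Sequence[float], y: Sequence[int],
                 method: str = "spearman") -> tuple[float, float]:
    """Correlation between a predictor and a binary outcome with asymptotic p.

    Rank correlation by default; ``method='pearson'`` gives the point-biserial
    (product-moment) alternative.
    """
    x, y = _as_xy(x, y)
    if len(x) < 3:
        raise PreconditionError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("constant predictor: correlation undefined")
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise DomainError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small tie-free samples (n_a * n_b <= 400),
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[1] < 2:
        raise PreconditionError("ratings must be an (n_subjects, >=2 raters) matrix")
    if r.shape[0] < 5:
        raise PreconditionError("need at least 5 subjects")
    if not np.all(np.isfinite(r)):
        raise PreconditionError("ratings contain missing/non-finite cells")
    n, k = r.shape
    grand = r.mean()
    row_means = r.mean(axis=1)
    col_means = r.mean(axis=0)
    ssb = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((r - grand) ** 2)
    sse = sst - ssb - ssc
    msr = ssb / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom) < 1e-15 or (msr < 1e-15 and mse < 1e-15):
        raise UndefinedStatisticError("zero between-subject variance: ICC undefined")
    return float((msr - mse) / denom)


def cohen_kappa(l1: Sequence, l2: Sequence) -> float:
    """Unweighted Cohen's kappa between two categorical labelings."""
    l1 = np.asarray(l1)
    l2 = np.asarray(l2)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise PreconditionError("labelings must be equal-length 1-D sequences")
    labels = np.union1d(l1, l2)
    if len(labels) < 2:
        raise UndefinedStatisticError("single category in both raters: kappa undefined")
    n = len(l1)
    idx = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for u, v in zip(l1, l2):
        table[idx[u], idx[v]] += 1
    po = np.trace(table) / n
    pe = float(np.sum(table.sum(axis=0) * table.sum(axis=1)) / n**2)
    if pe >= 1.0 - 1e-15:
        raise UndefinedStatisticError("degenerate marginals: kappa undefined")
    return float((po - pe) / (1.0 - pe))


def cluster_bootstrap_auc(x: Sequence[float], y: Sequence[int],
                          cluster_ids: Sequence, B: int = 2000,
                          seed: Optional[int] = None,
                          direction: str = "auto") -> tuple[float, float, float]:
    """Percentile bootstrap CI of the AUC resampling whole clusters.

    Surrogate for a GEE sensitivity analysis: clusters (patients) are drawn
    with replacement ``B`` times; replicates ending up single-class are redrawn
    (at most 100 retries each).  The predictor orientation is fixed from the
    full sample.  Returns ``(auc, ci_low, ci_high)``.
    """
    x, y = _as_xy(x, y)
    cluster_ids = np.asarray(cluster_ids)
    if cluster_ids.shape != x.shape:
        raise PreconditionError("cluster_ids must align with x")
    clusters = np.unique(cluster_ids)
    if len(clusters) < 2:
        raise PreconditionError("need at least 2 clusters")
    if direction == "auto":
        auc_hp, _, _ = _placements(x, y)
        direction = HIGHER_POSITIVE if auc_hp >= 0.5 else LOWER_POSITIVE
    scores = x if direction == HIGHER_POSITIVE else -x
    auc, _, _ = _placements(scores, y)
    members = {c: np.flatnonzero(cluster_ids == c) for c in clusters}
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    for b in range(B):
        for attempt in range(101):
            chosen = rng.choice(clusters, size=len(clusters), replace=True)
            idx = np.concatenate([members[c] for c in chosen])
            yb = y[idx]
            if 0 < yb.sum() < len(yb):
                break
        else:
            raise DegenerateTestError(
                "could not draw a two-class bootstrap replicate in 100 retries")
        reps[b], _, _ = _placements(scores[idx], yb)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return auc, float(lo), float(hi)
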