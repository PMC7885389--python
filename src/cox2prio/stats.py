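"""Statistical primitives shared by every pipeline stage.

Welch's t, Pearson correlation, Benjamini-Hochberg FDR and average-linkage
clustering are delegated to scipy / statsmodels; the permutation p-value,
the Kaplan-Meier product-limit estimator and the two-group log-rank test
are implemented here because the pipeline needs behaviours those libraries
do not expose as a single call (seeded/exhaustive permutation modes, the
at-risk table, and the sign of O-E for the direction gate of the survival
criterion). lifelines is used in the test suite as an independent oracle
for the survival routines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "KMCurve",
    "Dendrogram",
    "welch_t",
    "welch_t_matrix",
    "permutation_p",
    "permutation_p_matrix",
    "bh_fdr",
    "pearson",
    "km_estimate",
    "logrank",
    "hclust_avg_pearson",
    "cut_k",
]

#: permutation tests enumerate all label arrangements when their count is
#: at most this, and fall back to seeded Monte-Carlo sampling otherwise
EXHAUSTIVE_LIMIT = 20000


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    df: float | None = None
    n_perm: int | None = None
    direction: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function; S(t) = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class Dendrogram:
    """Merge history in scipy linkage format plus the leaf ordering."""

    linkage: np.ndarray
    labels: tuple[str, ...]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in sch.leaves_list(self.linkage)]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


# ---------------------------------------------------------------------------
# two-sample location tests
# ---------------------------------------------------------------------------

def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise ValueError(f"group {name!r} needs at least 2 observations")
    return arr


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance t-test; the sign follows mean(a) - mean(b).

    Degenerate inputs with zero variance in both groups and equal means
    yield statistic 0 and p = 1 (every permutation ties).
    """
    a = _as_vector(a, "a")
    b = _as_vector(b, "b")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TestResult(statistic=0.0, p=1.0, df=float(a.size + b.size - 2))
        return TestResult(statistic=math.inf if a.mean() > b.mean() else -math.inf,
                          p=0.0, df=float(a.size + b.size - 2))
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      df=float(res.df))


def welch_t_matrix(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise Welch t for a genes x samples matrix.

    ``labels`` is boolean with True marking group A; the statistic's sign is
    mean(A) - mean(B) per row. Rows with zero variance in both groups give 0.
    """
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    A = X[:, labels]
    B = X[:, ~labels]
    m1 = A.mean(axis=1)
    m2 = B.mean(axis=1)
    v1 = A.var(axis=1, ddof=1)
    v2 = B.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
    t[se2 == 0.0] = 0.0
    return t


def _perm_counts_comb(n: int, k: int) -> int:
    return math.comb(n, k)


def permutation_p(values, labels, n_perm: int = 1000,
                  seed: int | None = None,
                  exhaustive_limit: int = EXHAUSTIVE_LIMIT) -> TestResult:
    """Two-sided label-permutation p-value for the Welch statistic.

    When the number of distinct label arrangements C(n, n_A) is at most
    ``exhaustive_limit`` the test enumerates them all and reports the exact
    p (the observed arrangement counts itself, so p >= 1/N). Otherwise it
    samples ``n_perm`` arrangements with the seeded generator and applies
    the +1/+1 correction, p = (1 + #{|t*| >= |t|}) / (n_perm + 1), so the
    estimate is never zero.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if values.shape != labels.shape:
        raise ValueError("values and labels must have equal length")
    n1 = int(labels.sum())
    if n1 == 0 or n1 == labels.size:
        raise ValueError("both label classes must be present")
    X = values[None, :]
    t_obs = float(welch_t_matrix(X, labels)[0])
    n = labels.size
    total = _perm_counts_comb(n, n1)
    # numerical tolerance so regenerated-but-identical arrangements tie
    tol = 1e-12 * max(1.0, abs(t_obs))
    if total <= exhaustive_limit:
        count = 0
        for idx in combinations(range(n), n1):
            lab = np.zeros(n, dtype=bool)
            lab[list(idx)] = True
            t_star = float(welch_t_matrix(X, lab)[0])
            if abs(t_star) >= abs(t_obs) - tol:
                count += 1
        return TestResult(statistic=t_obs, p=count / total, n_perm=total)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        lab = np.zeros(n, dtype=bool)
        lab[rng.choice(n, size=n1, replace=False)] = True
        t_star = float(welch_t_matrix(X, lab)[0])
        if abs(t_star) >= abs(t_obs) - tol:
            count += 1
    return TestResult(statistic=t_obs, p=(1 + count) / (n_perm + 1), n_perm=n_perm)


def permutation_p_matrix(X: np.ndarray, labels: np.ndarray, n_perm: int = 1000,
                         seed: int | None = None,
                         chunk: int = 250) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise permutation p-values sharing one set of label permutations.

    This mirrors how marker-selection tools permute class labels once per
    round and score every gene against the same shuffled labels. Returns
    ``(t_obs, p)``; p uses the +1/+1 correction. Permutations are processed
    in chunks to bound memory on genome-sized matrices.
    """
    labels = np.asarray(labels, dtype=bool)
    t_obs = welch_t_matrix(X, labels)
    abs_obs = np.abs(t_obs) - 1e-12 * np.maximum(1.0, np.abs(t_obs))
    n = labels.size
    n1 = int(labels.sum())
    rng = np.random.default_rng(seed)
    exceed = np.zeros(X.shape[0], dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        for _ in range(m):
            lab = np.zeros(n, dtype=bool)
            lab[rng.choice(n, size=n1, replace=False)] = True
            t_star = welch_t_matrix(X, lab)
            exceed += np.abs(t_star) >= abs_obs
        done += m
    p = (1 + exceed) / (n_perm + 1)
    return t_obs, p


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def pearson(x, y) -> TestResult:
    """Pearson correlation with the two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs at least 3 observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return TestResult(statistic=float(r), p=float(p), df=float(x.size - 2))


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float).ravel()
    e = np.asarray(events, dtype=int).ravel()
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    if (~np.isin(e, (0, 1))).any():
        raise ValueError("event flags must be 0 or 1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate of the survival function.

    Subjects censored exactly at an event time are counted in the at-risk
    set for that time (the standard convention: censoring happens just
    after the event). With no events the curve is identically 1.
    """
    t, e = _check_surv(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=np.int64)
    n_events = np.empty(event_times.size, dtype=np.int64)
    s = 1.0
    for i, et in enumerate(event_times):
        n_i = int((t >= et).sum())
        d_i = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv[i] = s
        at_risk[i] = n_i
        n_events[i] = d_i
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk,
                   n_events=n_events)


def logrank(times_a, events_a, times_b, events_b) -> TestResult:
    """Two-group log-rank test with the hypergeometric variance for ties.

    Returns the 1-df chi-square statistic, its two-sided p, and
    ``direction`` = sign(O_A - E_A): positive means group A experienced
    more events than expected, i.e. group A fares worse. With no events in
    either arm the statistic is 0 and p = 1.
    """
    ta, ea = _check_surv(times_a, events_a)
    tb, eb = _check_surv(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return TestResult(statistic=0.0, p=1.0, df=1.0, direction=0)
    o_minus_e = 0.0
    var = 0.0
    o_a = 0.0
    for et in event_times:
        at_risk = t >= et
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((t == et) & (e == 1)).sum())
        d_a = int(((t == et) & (e == 1) & in_a).sum())
        exp_a = d * n_a / n
        o_a += d_a
        o_minus_e += d_a - exp_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0.0:
        return TestResult(statistic=0.0, p=1.0, df=1.0, direction=0)
    chi2 = o_minus_e**2 / var
    p = float(scipy.stats.chi2.sf(chi2, df=1))
    return TestResult(statistic=float(chi2), p=p, df=1.0,
                      direction=int(np.sign(o_minus_e)))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def hclust_avg_pearson(X: np.ndarray, labels=None) -> Dendrogram:
    """Average-linkage (UPGMA) clustering on 1 - Pearson correlation.

    ``X`` holds one row per sample and one column per feature; similarity
    between samples is the Pearson correlation of their feature profiles.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if labels is None:
        labels = tuple(str(i) for i in range(X.shape[0]))
    labels = tuple(labels)
    sd = X.std(axis=1)
    if (sd == 0).any():
        flat = [labels[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"zero-variance sample profile(s): {flat}")
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize rounding noise
    Z = sch.linkage(squareform(dist, checks=False), method="average")
    return Dendrogram(linkage=Z, labels=labels)


def cut_k(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Cut the tree into ``k`` flat clusters; returns label -> cluster id."""
    if k < 1 or k > len(dendrogram.labels):
        raise ValueError(f"k must be in [1, {len(dendrogram.labels)}]")
    assignment = sch.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    return {lab: int(c) for lab, c in zip(dendrogram.labels, assignment)}
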