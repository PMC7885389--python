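"""Stage 1: marker-based stratification and differential expression.

The cohort is split into marker-high and marker-low patient groups by the
marker gene's z-score (a z gate followed by a quantile cap, reproducing the
asymmetric "top 15% / bottom 15%" selection), genome-wide Welch statistics
with label-permutation p-values are computed between the groups, a compound
filter (fold change, p, |t|, FDR) selects the differentially expressed
genes, and unsupervised clustering on the resulting signature is used to
check that it separates the two groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cohortio import ExpressionMatrix, GeneList, ZScoreMatrix, log2_fpkm, zscore
from .stats import cut_k, hclust_avg_pearson, bh_fdr, permutation_p_matrix

__all__ = [
    "StratificationResult",
    "SignatureReport",
    "stratify",
    "select_extreme",
    "run_deg",
    "filter_deg",
    "validate_signature",
]


@dataclass(frozen=True)
class StratificationResult:
    """Disjoint marker-high / marker-low sample id lists plus thresholds."""

    high_ids: tuple[str, ...]
    low_ids: tuple[str, ...]
    z_high: float
    z_low: float
    fraction: float

    def __post_init__(self) -> None:
        if set(self.high_ids) & set(self.low_ids):
            raise ValueError("high and low groups overlap")

    @property
    def labels(self) -> dict[str, str]:
        out = {s: "high" for s in self.high_ids}
        out.update({s: "low" for s in self.low_ids})
        return out


@dataclass(frozen=True)
class SignatureReport:
    """Agreement between a 2-cut clustering and the stratification labels."""

    confusion: pd.DataFrame
    exact_match: bool
    ari: float
    cluster_of: dict[str, int] = field(repr=False, default_factory=dict)


def select_extreme(zrow: pd.Series, side: str, gate: float,
                   fraction: float) -> list[str]:
    """Samples passing the z gate, capped at the top ceil(fraction*n) by |z|.

    ``side='high'`` keeps z > gate and ranks descending; ``side='low'``
    keeps z < gate and ranks ascending. Ties in z break by sample id so the
    selection is deterministic.
    """
    n = len(zrow)
    cap = math.ceil(fraction * n)
    if side == "high":
        pool = zrow[zrow > gate]
        ranked = pool.sort_index().sort_values(ascending=False, kind="stable")
    elif side == "low":
        pool = zrow[zrow < gate]
        ranked = pool.sort_index().sort_values(ascending=True, kind="stable")
    else:
        raise ValueError(f"side must be 'high' or 'low', got {side!r}")
    return list(ranked.index[:cap])


def stratify(z: ZScoreMatrix, marker: str, z_high: float = 1.0,
             z_low: float = -0.25, fraction: float = 0.15) -> StratificationResult:
    """Split samples into marker-high and marker-low groups.

    The gate is applied first (z > ``z_high`` / z < ``z_low``), then each
    side is capped at the top ceil(``fraction`` * n) samples by z. Raises
    if the marker is absent or either side comes out empty.
    """
    zrow = z.gene_row(marker)
    high = select_extreme(zrow, "high", z_high, fraction)
    low = select_extreme(zrow, "low", z_low, fraction)
    if not high:
        raise ValueError(
            f"no samples with {marker} z > {z_high}; lower z_high or check the cohort"
        )
    if not low:
        raise ValueError(
            f"no samples with {marker} z < {z_low}; raise z_low or check the cohort"
        )
    return StratificationResult(high_ids=tuple(high), low_ids=tuple(low),
                                z_high=z_high, z_low=z_low, fraction=fraction)


def run_deg(expr: ExpressionMatrix, strat: StratificationResult,
            n_perm: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Genome-wide high-vs-low differential expression.

    Per gene: Welch t on log2(FPKM+1) (high minus low), a two-sided
    label-permutation p-value (one shared set of permutations across genes),
    Benjamini-Hochberg FDR over all tested genes, and the linear-scale fold
    change (mean_high + 1) / (mean_low + 1). The table is ranked by t
    descending with ties broken by gene symbol.
    """
    ids = list(strat.high_ids) + list(strat.low_ids)
    sub = expr.subset_samples(ids)
    if len(strat.high_ids) < 2 or len(strat.low_ids) < 2:
        raise ValueError("each stratified group needs at least 2 samples")
    X = np.log2(sub.values.to_numpy(dtype=float) + 1.0)
    labels = np.array([s in set(strat.high_ids) for s in ids])
    t, p = permutation_p_matrix(X, labels, n_perm=n_perm, seed=seed)
    fdr = bh_fdr(p)
    linear = sub.values.to_numpy(dtype=float)
    mean_high = linear[:, labels].mean(axis=1)
    mean_low = linear[:, ~labels].mean(axis=1)
    fc = (mean_high + 1.0) / (mean_low + 1.0)
    table = pd.DataFrame(
        {
            "gene": sub.genes,
            "t": t,
            "fold_change": fc,
            "p": p,
            "fdr": fdr,
            "direction": np.where(t >= 0, "up_in_high", "up_in_low"),
        }
    )
    table = table.sort_values(["t", "gene"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    return table


def filter_deg(table: pd.DataFrame, fc: float = 1.5, p: float = 0.05,
               t_abs: float = 2.0, fdr: float = 0.35) -> tuple[GeneList, GeneList]:
    """Apply the compound DEG filter with strict inequalities.

    up:   fold_change > fc  and p < p  and t > t_abs  and fdr < fdr
    down: fold_change < 1/fc and p < p and t < -t_abs and fdr < fdr

    The up list keeps the table's t-descending order; the down list is
    ordered by t ascending (strongest down-regulation first).
    """
    keep_common = (table["p"] < p) & (table["fdr"] < fdr)
    up_mask = keep_common & (table["fold_change"] > fc) & (table["t"] > t_abs)
    down_mask = keep_common & (table["fold_change"] < 1.0 / fc) & (table["t"] < -t_abs)
    up = table.loc[up_mask, "gene"]
    down = table.loc[down_mask].sort_values(["t", "gene"], kind="stable")["gene"]
    return (
        GeneList(name="deg_up", symbols=tuple(up),
                 criterion=f"FC>{fc}, p<{p}, t>{t_abs}, FDR<{fdr} (up in marker-high)"),
        GeneList(name="deg_down", symbols=tuple(down),
                 criterion=f"FC<1/{fc}, p<{p}, t<-{t_abs}, FDR<{fdr} (up in marker-low)"),
    )


def validate_signature(expr: ExpressionMatrix, strat: StratificationResult,
                       signature: GeneList) -> SignatureReport:
    """Cluster the stratified samples on the signature and score agreement.

    Signature rows are z-scored over the stratified samples, samples are
    clustered by average linkage on 1 - Pearson correlation and the tree is
    cut at k=2; the report carries the confusion matrix against the
    stratification labels, an exact-match flag, and the Adjusted Rand Index.
    """
    if len(signature) == 0:
        raise ValueError("signature is empty")
    missing = [g for g in signature if g not in expr.values.index]
    if missing:
        raise KeyError(f"signature genes missing from expression matrix: {missing}")
    ids = list(strat.high_ids) + list(strat.low_ids)
    sub = expr.subset_samples(ids)
    z = zscore(sub).values.loc[list(signature)]
    dendro = hclust_avg_pearson(z.to_numpy().T, labels=ids)
    cluster_of = cut_k(dendro, 2)
    truth = strat.labels
    confusion = pd.crosstab(
        pd.Series({s: truth[s] for s in ids}, name="stratum"),
        pd.Series(cluster_of, name="cluster"),
    )
    ari = float(adjusted_rand_score(
        [truth[s] for s in ids], [cluster_of[s] for s in ids]
    ))
    exact = ari == 1.0
    return SignatureReport(confusion=confusion, exact_match=exact, ari=ari,
                           cluster_of=cluster_of)
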