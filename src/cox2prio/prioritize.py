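"""Stage 2: the six criterion gene lists and their intersection.

Starting from the genes up-regulated in marker-high patients, six
independent lines of evidence are encoded as gene lists:

GL1  genetic alteration (copy-number amplification or mRNA z > +1) in more
     than 10% of the primary TNBC cohort;
GL2  copy-number amplification in more than 1% of a metastatic cohort;
GL3  strictly highest mean expression in the Basal PAM50 subtype;
GL4  significantly higher expression in TNBC than non-TNBC samples;
GL5  high expression associated with worse overall survival AND worse
     distant metastasis-free survival (median split, log-rank p < 0.05,
     high arm worse, both endpoints);
GL6  significantly higher expression in the less-sensitive (high-EC50)
     half of a drug-response cell-line panel.

The intersection of all six lists is the candidate set; a final Pearson
co-expression check against the marker confirms which candidates track
marker expression in the TNBC cohort.

The gene lists printed in the source study ship as packaged fixtures and
can be loaded with :func:`load_table1_lists`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import scipy.stats

from .cohortio import (
    CellLinePanel,
    ClinicalTable,
    CopyNumberTable,
    ExpressionMatrix,
    GeneList,
    ZScoreMatrix,
    log2_fpkm,
)
from .stats import logrank, pearson

__all__ = [
    "AlterationProfile",
    "PrioritizationResult",
    "alteration_profiles",
    "build_gl1",
    "build_gl2",
    "build_gl3",
    "build_gl4",
    "build_gl5",
    "build_gl6",
    "classify_panel",
    "classify_panel_series",
    "intersect_all",
    "coexpression_confirm",
    "load_table1_lists",
]

logger = logging.getLogger(__name__)

PAM50_FOR_GL3 = ("LumA", "LumB", "HER2E", "Basal", "Normal-like")


@dataclass(frozen=True)
class AlterationProfile:
    """Per-gene alteration percentages in a cohort.

    ``alteration_rate`` is the literal sum of the amplification and
    mRNA-upregulation percentages, so a patient altered both ways is
    double-counted and the rate may exceed 100.
    """

    gene: str
    pct_amplified: float
    pct_mrna_up: float

    @property
    def alteration_rate(self) -> float:
        return self.pct_amplified + self.pct_mrna_up


@dataclass(frozen=True)
class PrioritizationResult:
    """The six lists, their intersection, and the co-expression subset."""

    gene_lists: dict[str, GeneList]
    intersection: GeneList
    coexpressed: GeneList
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gl in self.gene_lists.items():
            stray = [g for g in self.intersection if g not in gl]
            if stray:
                raise ValueError(f"intersection not contained in {name}: {stray}")
        stray = [g for g in self.coexpressed if g not in self.intersection]
        if stray:
            raise ValueError(f"coexpressed genes outside the intersection: {stray}")

    def to_dict(self) -> dict:
        return {
            "gene_lists": {k: v.to_dict() for k, v in self.gene_lists.items()},
            "intersection": self.intersection.to_dict(),
            "coexpressed": self.coexpressed.to_dict(),
            "parameters": self.parameters,
        }


def _require_genes(candidates: GeneList, index: pd.Index, what: str) -> None:
    missing = [g for g in candidates if g not in index]
    if missing:
        raise KeyError(f"candidate genes missing from {what}: {missing}")


def alteration_profiles(candidates: GeneList, cna: CopyNumberTable,
                        z: ZScoreMatrix, z_thresh: float = 1.0
                        ) -> list[AlterationProfile]:
    """Amplification (+2 call) and mRNA-up (z > threshold) percentages."""
    _require_genes(candidates, cna.values.index, "copy-number table")
    _require_genes(candidates, z.values.index, "z-score matrix")
    profiles = []
    n_cna = cna.values.shape[1]
    n_z = z.values.shape[1]
    for g in candidates:
        pct_amp = 100.0 * float((cna.values.loc[g] == 2).sum()) / n_cna
        pct_up = 100.0 * float((z.values.loc[g] > z_thresh).sum()) / n_z
        profiles.append(AlterationProfile(gene=g, pct_amplified=pct_amp,
                                          pct_mrna_up=pct_up))
    return profiles


def build_gl1(candidates: GeneList, cna: CopyNumberTable, z: ZScoreMatrix,
              threshold: float = 10.0) -> GeneList:
    """Genes altered (amplified or mRNA-up, summed) in > threshold % of samples.

    Ranked by alteration rate descending, ties broken by gene symbol.
    """
    profiles = alteration_profiles(candidates, cna, z)
    kept = [p for p in profiles if p.alteration_rate > threshold]
    kept.sort(key=lambda p: (-p.alteration_rate, p.gene))
    return GeneList(
        name="GL1",
        symbols=tuple(p.gene for p in kept),
        criterion=f"alteration rate (amp% + z>1%) > {threshold}% in primary cohort",
    )


def build_gl2(candidates: GeneList, cna_metastatic: CopyNumberTable,
              threshold: float = 1.0) -> GeneList:
    """Genes with a +2 copy-number call in > threshold % of metastatic samples."""
    _require_genes(candidates, cna_metastatic.values.index,
                   "metastatic copy-number table")
    n = cna_metastatic.values.shape[1]
    rates = {
        g: 100.0 * float((cna_metastatic.values.loc[g] == 2).sum()) / n
        for g in candidates
    }
    kept = sorted(
        (g for g in candidates if rates[g] > threshold),
        key=lambda g: (-rates[g], g),
    )
    return GeneList(
        name="GL2",
        symbols=tuple(kept),
        criterion=f"amplified in > {threshold}% of metastatic cohort",
    )


def build_gl3(candidates: GeneList, expr: ExpressionMatrix,
              clinical: ClinicalTable) -> GeneList:
    """Genes whose mean log2(FPKM+1) is strictly highest in the Basal subtype.

    Ties with any other subtype exclude the gene. Requires at least one
    sample per canonical PAM50 subtype.
    """
    _require_genes(candidates, expr.values.index, "expression matrix")
    pam50 = clinical.values["PAM50"]
    common = [s for s in expr.samples if s in pam50.index]
    pam50 = pam50.loc[common]
    for subtype in PAM50_FOR_GL3:
        if (pam50 == subtype).sum() == 0:
            raise ValueError(f"no samples with PAM50 subtype {subtype!r}")
    log2 = log2_fpkm(expr)[common]
    means = {
        subtype: log2.loc[list(candidates), pam50.index[pam50 == subtype]].mean(axis=1)
        for subtype in PAM50_FOR_GL3
    }
    kept = []
    others = [s for s in PAM50_FOR_GL3 if s != "Basal"]
    for g in candidates:
        if all(means["Basal"][g] > means[s][g] for s in others):
            kept.append(g)
    return GeneList(name="GL3", symbols=tuple(kept),
                    criterion="strictly highest mean expression in Basal subtype")


def build_gl4(candidates: GeneList, expr: ExpressionMatrix,
              tnbc_flags: pd.Series, alpha: float = 0.05) -> GeneList:
    """Genes significantly higher in TNBC than non-TNBC (one-sided Welch).

    ``tnbc_flags`` is a boolean series indexed by sample id.
    """
    _require_genes(candidates, expr.values.index, "expression matrix")
    common = [s for s in expr.samples if s in tnbc_flags.index]
    flags = tnbc_flags.loc[common].astype(bool)
    if flags.all() or (~flags).all():
        raise ValueError("both TNBC and non-TNBC samples are required")
    log2 = log2_fpkm(expr)[common]
    tnbc_cols = flags.index[flags]
    rest_cols = flags.index[~flags]
    kept = []
    for g in candidates:
        res = scipy.stats.ttest_ind(
            log2.loc[g, tnbc_cols], log2.loc[g, rest_cols],
            equal_var=False, alternative="greater",
        )
        if res.pvalue < alpha:
            kept.append(g)
    return GeneList(name="GL4", symbols=tuple(kept),
                    criterion=f"higher in TNBC, one-sided Welch p < {alpha}")


def build_gl5(candidates: GeneList, expr: ExpressionMatrix,
              clinical: ClinicalTable, alpha: float = 0.05) -> GeneList:
    """Genes whose high expression predicts worse OS *and* worse DMFS.

    Samples are median-split on log2(FPKM+1) per gene (high arm strictly
    above the median); inclusion requires log-rank p < alpha with the high
    arm disadvantaged, for both endpoints.
    """
    _require_genes(candidates, expr.values.index, "expression matrix")
    common = [s for s in expr.samples if s in clinical.values.index]
    clin = clinical.values.loc[common]
    log2 = log2_fpkm(expr)[common]
    for endpoint in ("OS", "DMFS"):
        if clin[f"{endpoint}_event"].sum() == 0:
            raise ValueError(f"no {endpoint} events: the cohort is fully censored")
    kept = []
    for g in candidates:
        row = log2.loc[g]
        high = row > row.median()
        if high.all() or (~high).all():
            continue  # constant gene: no split
        ok = True
        for endpoint in ("OS", "DMFS"):
            t_col, e_col = f"{endpoint}_time", f"{endpoint}_event"
            res = logrank(
                clin.loc[high.values, t_col], clin.loc[high.values, e_col],
                clin.loc[~high.values, t_col], clin.loc[~high.values, e_col],
            )
            if not (res.p < alpha and res.direction == 1):
                ok = False
                break
        if ok:
            kept.append(g)
    return GeneList(
        name="GL5", symbols=tuple(kept),
        criterion=f"median split, log-rank p < {alpha}, high arm worse, OS and DMFS",
    )


def classify_panel_series(ec50: pd.Series) -> tuple[list[str], list[str]]:
    """Rank lines by EC50 ascending (ties by id); lower floor(n/2) are MS."""
    if ec50.size < 2:
        raise ValueError("panel needs at least 2 cell lines")
    ranked = sorted(ec50.index, key=lambda line: (ec50[line], line))
    n_ms = ec50.size // 2
    return ranked[:n_ms], ranked[n_ms:]


def classify_panel(panel: CellLinePanel) -> tuple[list[str], list[str]]:
    """Split a panel into more-sensitive / less-sensitive halves by EC50."""
    return classify_panel_series(panel.ec50)


def build_gl6(candidates: GeneList, panel: CellLinePanel,
              alpha: float = 0.05) -> GeneList:
    """Genes significantly higher in less-sensitive lines (one-sided Welch)."""
    _require_genes(candidates, panel.expression.index, "panel expression")
    ms, ls = classify_panel(panel)
    if len(ms) < 2 or len(ls) < 2:
        raise ValueError("each sensitivity class needs at least 2 cell lines")
    kept = []
    for g in candidates:
        res = scipy.stats.ttest_ind(
            panel.expression.loc[g, ls], panel.expression.loc[g, ms],
            equal_var=False, alternative="greater",
        )
        if res.pvalue < alpha:
            kept.append(g)
    return GeneList(name="GL6", symbols=tuple(kept),
                    criterion=f"higher in less-sensitive lines, one-sided Welch p < {alpha}")


def intersect_all(*lists: GeneList, name: str = "intersection") -> GeneList:
    """Symbols present in every list, ordered by the first list's order."""
    if not lists:
        raise ValueError("need at least one gene list")
    first, rest = lists[0], lists[1:]
    symbols = tuple(
        g for g in first if all(g in other for other in rest)
    )
    return GeneList(name=name, symbols=symbols,
                    criterion="present in " + ", ".join(gl.name for gl in lists))


def coexpression_confirm(genes: GeneList, expr: ExpressionMatrix, marker: str,
                         r_min: float = 0.2, p_max: float = 0.05) -> GeneList:
    """Candidates whose expression correlates with the marker.

    Pearson r > ``r_min`` and p < ``p_max`` on log2(FPKM+1) across the
    supplied samples. The marker itself trivially passes; a zero-variance
    gene is recorded as failing with a warning.
    """
    if marker not in expr.values.index:
        raise KeyError(f"marker gene not in expression matrix: {marker!r}")
    log2 = log2_fpkm(expr)
    marker_vals = log2.loc[marker]
    kept = []
    for g in genes:
        if g == marker:
            kept.append(g)
            continue
        if g not in log2.index:
            raise KeyError(f"gene not in expression matrix: {g!r}")
        try:
            res = pearson(log2.loc[g], marker_vals)
        except ValueError:
            logger.warning("gene %s has zero variance; fails co-expression", g)
            continue
        if res.statistic > r_min and res.p < p_max:
            kept.append(g)
    return GeneList(name="coexpressed", symbols=tuple(kept),
                    criterion=f"Pearson r > {r_min} and p < {p_max} vs {marker}")


def load_table1_lists() -> dict[str, GeneList]:
    """The six printed selection-criterion gene lists, as packaged fixtures."""
    criteria = {
        "GL1": "high genetic alteration rate in primary TNBC cohort",
        "GL2": "copy-number amplification in metastatic cohort",
        "GL3": "highest mean expression in Basal subtype",
        "GL4": "higher expression in TNBC vs non-TNBC",
        "GL5": "high expression associated with poor OS and DMFS",
        "GL6": "higher expression in less-sensitive cell lines",
    }
    out = {}
    for i in range(1, 7):
        name = f"GL{i}"
        text = (
            resources.files("cox2prio.fixtures")
            .joinpath(f"table1_gl{i}.txt")
            .read_text()
        )
        symbols = tuple(line.strip() for line in text.splitlines() if line.strip())
        out[name] = GeneList(name=name, symbols=symbols, criterion=criteria[name])
    return out
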