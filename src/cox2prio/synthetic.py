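"""Synthetic cohorts and cell-line panels with planted structure.

The generator emulates the statistical shape the downstream analysis
assumes, so every stage is testable without any external download:

* log-normal bulk FPKM — log2(FPKM+1) is Gaussian per gene with a mean
  drawn once per gene from a stated range;
* a planted block of genes co-regulated with the marker: planted genes are
  shifted by ``delta`` (log2 units) in Basal-subtype samples and by a
  further ``delta`` in the marker-high patients, so co-expression with the
  marker is causal (the marker-high label is assigned from the marker's
  own draw before planted genes are sampled);
* discrete copy-number calls, i.i.d. per gene and sample, with an elevated
  amplification frequency for planted genes;
* exponential survival with a hazard multiplier for patients whose mean
  planted-gene expression exceeds the cohort median, and uniform censoring
  calibrated to a target censoring fraction;
* a cell-line panel in which resistance genes are overexpressed by
  ``delta_panel`` in the less-sensitive (upper-EC50) half.

With ``delta = surv_beta = 0`` every planted effect vanishes and the
cohort is an exact null for the downstream tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohortio import (
    CellLinePanel,
    ClinicalTable,
    CopyNumberTable,
    ExpressionMatrix,
    write_clinical,
    write_cna,
    write_expression,
    write_panel,
)
from .deg import select_extreme

__all__ = [
    "CohortSpec",
    "PanelSpec",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_panel",
    "write_cohort",
]

DEFAULT_SUBTYPE_PROBS = {
    "LumA": 0.45,
    "LumB": 0.25,
    "HER2E": 0.20,
    "Normal-like": 0.10,
}


class SpecValidationError(ValueError):
    """A simulation spec field is invalid; the message names the field."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated patient cohort.

    Effect sizes are in log2(FPKM+1) units. ``delta`` is applied to planted
    genes twice over: once in every Basal sample (subtype enrichment) and
    once more in marker-high patients (marker co-expression), so a single
    knob controls all planted expression signal and ``delta = 0`` is a
    clean null.
    """

    n_patients: int = 120
    n_genes: int = 2000
    marker_gene: str = "PTGS2"
    planted_genes: tuple[str, ...] | None = None
    planted_down_genes: tuple[str, ...] | None = None
    delta: float = 2.0
    sigma: float = 0.5
    baseline_mu_range: tuple[float, float] = (3.0, 7.0)
    amp_freq: float = 0.15
    background_amp_freq: float = 0.02
    surv_beta: float = 1.0
    baseline_hazard: float = math.log(2.0) / 60.0
    censor_frac: float = 0.3
    subtype_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROBS)
    )
    tnbc_frac: float = 0.5
    z_high: float = 1.0
    fraction: float = 0.15
    seed: int = 0

    @property
    def genes(self) -> list[str]:
        background = [f"G{i:04d}" for i in range(1, self.n_genes)]
        return [self.marker_gene] + background

    @property
    def planted(self) -> tuple[str, ...]:
        if self.planted_genes is not None:
            return tuple(self.planted_genes)
        n_planted = min(8, self.n_genes - 1)
        return tuple(f"G{i:04d}" for i in range(1, n_planted + 1))

    @property
    def planted_down(self) -> tuple[str, ...]:
        """Genes suppressed in marker-high patients (the down-signature).

        Default: the 8 background genes following the planted block, so the
        DEG signature contains both directions — correlation-distance
        clustering of samples needs an expression *pattern*, not just a
        common shift.
        """
        if self.planted_down_genes is not None:
            return tuple(self.planted_down_genes)
        start = len(self.planted) + 1
        n_down = max(0, min(8, self.n_genes - 1 - len(self.planted)))
        return tuple(f"G{i:04d}" for i in range(start, start + n_down))

    def validate(self) -> None:
        if self.n_patients < 4:
            raise SpecValidationError("n_patients must be >= 4")
        if self.n_genes < 2:
            raise SpecValidationError("n_genes must be >= 2")
        if self.delta < 0:
            raise SpecValidationError("delta must be >= 0")
        if self.sigma <= 0:
            raise SpecValidationError("sigma must be > 0")
        for name, value in (
            ("amp_freq", self.amp_freq),
            ("background_amp_freq", self.background_amp_freq),
            ("censor_frac", self.censor_frac),
            ("tnbc_frac", self.tnbc_frac),
            ("fraction", self.fraction),
        ):
            if not (0.0 <= value <= 1.0):
                raise SpecValidationError(f"{name} must be in [0, 1]")
        if self.baseline_hazard <= 0:
            raise SpecValidationError("baseline_hazard must be > 0")
        if abs(sum(self.subtype_probs.values()) - 1.0) > 1e-9:
            raise SpecValidationError("subtype_probs must sum to 1")
        if any(p < 0 for p in self.subtype_probs.values()):
            raise SpecValidationError("subtype_probs must be non-negative")
        universe = set(self.genes)
        stray = [g for g in self.planted if g not in universe]
        if stray:
            raise SpecValidationError(
                f"planted_genes not in the gene universe: {stray}"
            )
        stray = [g for g in self.planted_down if g not in universe]
        if stray:
            raise SpecValidationError(
                f"planted_down_genes not in the gene universe: {stray}"
            )
        if self.marker_gene in self.planted or self.marker_gene in self.planted_down:
            raise SpecValidationError("planted gene lists must not include marker_gene")
        overlap = set(self.planted) & set(self.planted_down)
        if overlap:
            raise SpecValidationError(
                f"planted_genes and planted_down_genes overlap: {sorted(overlap)}"
            )


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of one simulated cell-line sensitivity panel."""

    n_lines: int = 37
    genes: tuple[str, ...] | None = None
    n_genes: int = 200
    resistance_genes: tuple[str, ...] = ()
    ec50_range: tuple[float, float] = (0.5, 50.0)
    delta_panel: float = 3.0
    sigma: float = 0.5
    baseline_mu_range: tuple[float, float] = (3.0, 7.0)
    seed: int = 0

    @property
    def gene_universe(self) -> list[str]:
        if self.genes is not None:
            return list(self.genes)
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def validate(self) -> None:
        if self.n_lines < 2:
            raise SpecValidationError("n_lines must be >= 2")
        low, high = self.ec50_range
        if not (0 < low < high):
            raise SpecValidationError("ec50_range must satisfy 0 < low < high")
        if self.delta_panel < 0:
            raise SpecValidationError("delta_panel must be >= 0")
        if self.sigma <= 0:
            raise SpecValidationError("sigma must be > 0")
        universe = set(self.gene_universe)
        stray = [g for g in self.resistance_genes if g not in universe]
        if stray:
            raise SpecValidationError(
                f"resistance_genes not in the gene universe: {stray}"
            )


@dataclass(frozen=True)
class SimulatedCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    cna: CopyNumberTable
    truth: dict


def _draw_survival(rng: np.random.Generator, hazards: np.ndarray,
                   censor_frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Exponential event times with uniform censoring on [0, T].

    T is solved so the expected censoring fraction matches ``censor_frac``:
    P(censored) = mean_i (1 - exp(-h_i T)) / (h_i T).
    """
    event = rng.exponential(1.0 / hazards)
    if censor_frac <= 0.0:
        return event, np.ones(event.size, dtype=int)

    def expected_censoring(T: float) -> float:
        x = hazards * T
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1e9 / hazards.mean()
    T = brentq(lambda T: expected_censoring(T) - censor_frac, lo, hi)
    censor = rng.uniform(0.0, T, size=event.size)
    time = np.minimum(event, censor)
    observed = (event <= censor).astype(int)
    # guard against a zero time from floating underflow
    time = np.maximum(time, 1e-12)
    return time, observed


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate one cohort; identical spec and seed give identical output."""
    spec.validate()
    streams = np.random.SeedSequence(spec.seed).spawn(6)
    rng_clin, rng_mu, rng_expr, rng_cna, rng_os, rng_dmfs = (
        np.random.default_rng(s) for s in streams
    )
    n = spec.n_patients
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    genes = spec.genes
    planted = list(spec.planted)

    # --- clinical skeleton: receptor status and PAM50 subtype -------------
    n_tnbc = int(round(spec.tnbc_frac * n))
    tnbc_mask = np.zeros(n, dtype=bool)
    tnbc_mask[rng_clin.choice(n, size=n_tnbc, replace=False)] = True
    er = np.where(tnbc_mask, "negative", "positive")
    pr = np.empty(n, dtype=object)
    her2 = np.empty(n, dtype=object)
    pam50 = np.empty(n, dtype=object)
    subtype_names = list(spec.subtype_probs)
    subtype_p = np.array([spec.subtype_probs[s] for s in subtype_names])
    # fixed cohort composition (largest-remainder apportionment) so every
    # subtype is represented whenever the non-TNBC arm is big enough
    n_non = n - n_tnbc
    counts = np.floor(subtype_p * n_non).astype(int)
    remainder = subtype_p * n_non - counts
    for j in np.argsort(-remainder)[: n_non - counts.sum()]:
        counts[j] += 1
    non_tnbc_subtypes = np.repeat(subtype_names, counts)
    rng_clin.shuffle(non_tnbc_subtypes)
    k = 0
    for i in range(n):
        if tnbc_mask[i]:
            pr[i], her2[i], pam50[i] = "negative", "negative", "Basal"
        else:
            # ER already positive, so the sample cannot be triple negative
            pr[i] = "positive" if rng_clin.random() < 0.6 else "negative"
            her2[i] = "positive" if rng_clin.random() < 0.25 else "negative"
            pam50[i] = non_tnbc_subtypes[k]
            k += 1
    basal_mask = pam50 == "Basal"

    # --- expression -------------------------------------------------------
    lo, hi = spec.baseline_mu_range
    mu = rng_mu.uniform(lo, hi, size=len(genes))
    log2x = mu[:, None] + rng_expr.normal(0.0, spec.sigma, size=(len(genes), n))
    gene_idx = {g: i for i, g in enumerate(genes)}
    marker_row = gene_idx[spec.marker_gene]
    log2x[marker_row] += spec.delta * basal_mask

    # marker-high label: the same z gate + quantile cap the DEG stage uses,
    # computed TNBC-wide from the marker's own draw
    tnbc_ids = [s for s, m in zip(samples, tnbc_mask) if m]
    marker_high_ids: list[str] = []
    if len(tnbc_ids) >= 2:
        marker_tnbc = pd.Series(log2x[marker_row, tnbc_mask], index=tnbc_ids)
        sd = marker_tnbc.std(ddof=0)
        if sd > 0:
            zrow = (marker_tnbc - marker_tnbc.mean()) / sd
            marker_high_ids = select_extreme(zrow, "high", spec.z_high,
                                             spec.fraction)
    marker_high_mask = np.array([s in set(marker_high_ids) for s in samples])

    planted_rows = np.array([gene_idx[g] for g in planted], dtype=int)
    if planted_rows.size:
        boost = spec.delta * (basal_mask.astype(float)
                              + marker_high_mask.astype(float))
        log2x[planted_rows] += boost[None, :]
    planted_down = list(spec.planted_down)
    down_rows = np.array([gene_idx[g] for g in planted_down], dtype=int)
    if down_rows.size:
        log2x[down_rows] -= spec.delta * marker_high_mask.astype(float)[None, :]

    fpkm = np.clip(np.exp2(log2x) - 1.0, 0.0, None)
    expression = ExpressionMatrix(pd.DataFrame(fpkm, index=genes, columns=samples))

    # --- copy-number calls -------------------------------------------------
    calls = np.zeros((len(genes), n), dtype=int)
    base_probs = {-2: 0.01, -1: 0.05, 1: 0.05}
    for i, g in enumerate(genes):
        p_amp = spec.amp_freq if g in set(planted) else spec.background_amp_freq
        p = np.array([base_probs[-2], base_probs[-1],
                      1.0 - sum(base_probs.values()) - p_amp,
                      base_probs[1], p_amp])
        calls[i] = rng_cna.choice([-2, -1, 0, 1, 2], size=n, p=p)
    cna = CopyNumberTable(pd.DataFrame(calls, index=genes, columns=samples))

    # --- survival -----------------------------------------------------------
    if planted_rows.size:
        planted_mean = log2x[planted_rows].mean(axis=0)
        risk = (planted_mean > np.median(planted_mean)).astype(float)
    else:
        risk = np.zeros(n)
    hazards = spec.baseline_hazard * np.exp(spec.surv_beta * risk)
    os_time, os_event = _draw_survival(rng_os, hazards, spec.censor_frac)
    dmfs_time, dmfs_event = _draw_survival(rng_dmfs, hazards, spec.censor_frac)

    clinical = ClinicalTable(pd.DataFrame(
        {
            "ER": er, "PR": pr, "HER2": her2, "PAM50": pam50,
            "OS_time": os_time, "OS_event": os_event,
            "DMFS_time": dmfs_time, "DMFS_event": dmfs_event,
        },
        index=pd.Index(samples, name="sample"),
    ))

    truth = {
        "marker_gene": spec.marker_gene,
        "planted_genes": planted,
        "planted_down_genes": planted_down,
        "marker_high_ids": marker_high_ids,
        "tnbc_ids": tnbc_ids,
        "risk_ids": [s for s, r in zip(samples, risk) if r > 0],
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(spec).items()
        },
    }
    return SimulatedCohort(expression=expression, clinical=clinical, cna=cna,
                           truth=truth)


def simulate_panel(spec: PanelSpec) -> CellLinePanel:
    """Generate a cell-line panel with resistance genes planted in the
    less-sensitive (upper-EC50) half."""
    spec.validate()
    streams = np.random.SeedSequence(spec.seed).spawn(3)
    rng_ec, rng_mu, rng_expr = (np.random.default_rng(s) for s in streams)
    lines = [f"L{i:03d}" for i in range(1, spec.n_lines + 1)]
    lo, hi = spec.ec50_range
    ec50 = pd.Series(
        np.exp(rng_ec.uniform(np.log(lo), np.log(hi), size=spec.n_lines)),
        index=lines,
    )
    # the split rule of the prioritization stage: lower half more sensitive
    from .prioritize import classify_panel_series
    _, ls_lines = classify_panel_series(ec50)
    ls_mask = np.array([l in set(ls_lines) for l in lines])

    genes = spec.gene_universe
    mu = rng_mu.uniform(*spec.baseline_mu_range, size=len(genes))
    X = mu[:, None] + rng_expr.normal(0.0, spec.sigma,
                                      size=(len(genes), spec.n_lines))
    resistant = set(spec.resistance_genes)
    for i, g in enumerate(genes):
        if g in resistant:
            X[i] += spec.delta_panel * ls_mask
    expression = pd.DataFrame(X, index=genes, columns=lines)
    return CellLinePanel(ec50=ec50, expression=expression)


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write expression.tsv, clinical.tsv, cna.tsv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "cna": outdir / "cna.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression(cohort.expression, paths["expression"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_cna(cohort.cna, paths["cna"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2) + "\n")
    return paths
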