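"""Configuration-driven orchestration: simulate -> DEG -> prioritize -> report.

A run is described by a flat YAML mapping (unknown keys are errors, not
warnings). All analysis thresholds default to the study values: z gates
+1 / -0.25 with a 15% quantile cap, fold change 1.5, p 0.05, |t| 2,
FDR 0.35, 10% and 1% alteration thresholds for GL1/GL2, Pearson r 0.2.
One root seed drives every stage through derived substreams; the manifest
records SHA-256 content hashes of all written outputs so a re-run can be
verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohortio, deg, prioritize
from .cohortio import GeneList
from .synthetic import CohortSpec, PanelSpec, simulate_cohort, simulate_panel, write_cohort

__all__ = ["PipelineConfig", "PipelineError", "PipelineRun", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Flat configuration for one end-to-end run."""

    seed: int = 0
    marker: str = "PTGS2"
    n_perm: int = 1000
    # stratification
    z_high: float = 1.0
    z_low: float = -0.25
    fraction: float = 0.15
    # DEG filter
    fc: float = 1.5
    p: float = 0.05
    t_abs: float = 2.0
    fdr: float = 0.35
    # gene-list thresholds
    gl1_threshold: float = 10.0
    gl2_threshold: float = 1.0
    gl_alpha: float = 0.05
    r_min: float = 0.2
    coexpr_p: float = 0.05
    # cohort simulation (used when no input paths are given)
    n_patients: int = 120
    n_genes: int = 2000
    delta: float = 2.0
    sigma: float = 0.5
    tnbc_frac: float = 0.5
    amp_freq: float = 0.15
    surv_beta: float = 1.0
    censor_frac: float = 0.3
    metastatic_n: int = 180
    n_lines: int = 37
    delta_panel: float = 3.0
    # alternative input modes
    table1_only: bool = False
    expression_path: str | None = None
    clinical_path: str | None = None
    cna_path: str | None = None
    metastatic_cna_path: str | None = None
    panel_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class PipelineError(RuntimeError):
    """An analysis stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineRun:
    """Everything a finished run produced, plus where it was written."""

    config: PipelineConfig
    result: prioritize.PrioritizationResult
    deg_table: pd.DataFrame | None
    stratification: deg.StratificationResult | None
    signature_report: deg.SignatureReport | None
    outdir: Path
    manifest: dict
    truth: dict | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineError(name, exc) from exc
    return wrap


def _write_report(outdir: Path, lines: list[str]) -> Path:
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineRun:
    """Execute all stages, writing every intermediate table and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report_lines = [f"cox2prio pipeline run (seed {config.seed})", ""]

    if config.table1_only:
        lists = prioritize.load_table1_lists()
        intersection = prioritize.intersect_all(*lists.values())
        result = prioritize.PrioritizationResult(
            gene_lists=lists,
            intersection=intersection,
            coexpressed=GeneList(name="coexpressed", symbols=(),
                                 criterion="not computed in lists-only mode"),
            parameters={"mode": "table1_only"},
        )
        for name, gl in lists.items():
            p = outdir / f"{name}.txt"
            cohortio.write_gene_list(gl, p)
            written.append(p)
            report_lines.append(f"{name}: {len(gl)} genes")
        p = outdir / "intersection.txt"
        cohortio.write_gene_list(intersection, p)
        written.append(p)
        report_lines += ["", f"intersection ({len(intersection)} genes): "
                         + ", ".join(intersection)]
        manifest = _finalize(config, outdir, written, report_lines)
        return PipelineRun(config=config, result=result, deg_table=None,
                           stratification=None, signature_report=None,
                           outdir=outdir, manifest=manifest)

    seed_stream = np.random.SeedSequence(config.seed)
    cohort_seed, met_seed, panel_seed, deg_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in seed_stream.spawn(4)
    )

    # --- inputs: read from paths or simulate -----------------------------
    if config.expression_path:
        for key in ("clinical_path", "cna_path", "metastatic_cna_path",
                    "panel_path"):
            if getattr(config, key) is None:
                raise PipelineError("inputs", FileNotFoundError(
                    f"{key} must be set when expression_path is given"))
        expr = _stage("inputs")(cohortio.read_expression, config.expression_path)
        clinical = _stage("inputs")(cohortio.read_clinical, config.clinical_path)
        cna = _stage("inputs")(cohortio.read_cna, config.cna_path)
        cna_met = _stage("inputs")(cohortio.read_cna, config.metastatic_cna_path)
        panel = _stage("inputs")(cohortio.read_panel, config.panel_path)
        truth = None
    else:
        cspec = CohortSpec(
            n_patients=config.n_patients, n_genes=config.n_genes,
            marker_gene=config.marker, delta=config.delta, sigma=config.sigma,
            tnbc_frac=config.tnbc_frac, amp_freq=config.amp_freq,
            surv_beta=config.surv_beta, censor_frac=config.censor_frac,
            z_high=config.z_high, fraction=config.fraction, seed=cohort_seed,
        )
        cohort = _stage("simulate")(simulate_cohort, cspec)
        expr, clinical, cna = cohort.expression, cohort.clinical, cohort.cna
        truth = cohort.truth
        met_spec = dataclasses.replace(cspec, n_patients=config.metastatic_n,
                                       seed=met_seed)
        cna_met = _stage("simulate")(simulate_cohort, met_spec).cna
        pspec = PanelSpec(
            n_lines=config.n_lines, genes=tuple(expr.genes),
            resistance_genes=tuple(truth["planted_genes"]),
            delta_panel=config.delta_panel, sigma=config.sigma,
            seed=panel_seed,
        )
        panel = _stage("simulate")(simulate_panel, pspec)
        paths = write_cohort(cohort, outdir / "cohort")
        written.extend(paths.values())
        p = outdir / "panel.tsv"
        cohortio.write_panel(panel, p)
        written.append(p)
        p = outdir / "metastatic_cna.tsv"
        cohortio.write_cna(cna_met, p)
        written.append(p)

    # --- stage 1: TNBC selection, stratification, DEG ---------------------
    tnbc_ids = _stage("select_tnbc")(cohortio.select_tnbc, clinical)
    if len(tnbc_ids) < 4:
        raise PipelineError("select_tnbc",
                            ValueError(f"only {len(tnbc_ids)} TNBC samples"))
    expr_tnbc = expr.subset_samples(tnbc_ids)
    z_tnbc = _stage("zscore")(cohortio.zscore, expr_tnbc)
    strat = _stage("stratify")(deg.stratify, z_tnbc, config.marker,
                               config.z_high, config.z_low, config.fraction)
    deg_table = _stage("deg")(deg.run_deg, expr_tnbc, strat,
                              config.n_perm, deg_seed)
    up, down = _stage("deg_filter")(deg.filter_deg, deg_table, config.fc,
                                    config.p, config.t_abs, config.fdr)
    p = outdir / "deg_table.tsv"
    deg_table.to_csv(p, sep="\t", index=False)
    written.append(p)
    volcano = pd.DataFrame({
        "gene": deg_table["gene"],
        "log2_fc": np.log2(deg_table["fold_change"]),
        "neg_log10_p": -np.log10(deg_table["p"]),
    })
    p = outdir / "volcano.tsv"
    volcano.to_csv(p, sep="\t", index=False)
    written.append(p)
    for gl in (up, down):
        p = outdir / f"{gl.name}.txt"
        cohortio.write_gene_list(gl, p)
        written.append(p)
    report_lines += [
        f"TNBC samples: {len(tnbc_ids)}",
        f"marker-high: {len(strat.high_ids)}  marker-low: {len(strat.low_ids)}",
        f"DEG up (marker-high): {len(up)}  DEG down: {len(down)}",
    ]

    signature_report = None
    signature = GeneList(name="signature", symbols=up.symbols + down.symbols,
                         criterion="DEG up + down")
    if len(signature) >= 2:
        signature_report = _stage("signature")(deg.validate_signature,
                                               expr_tnbc, strat, signature)
        report_lines.append(
            f"signature clustering ARI: {signature_report.ari:.3f} "
            f"(exact match: {signature_report.exact_match})"
        )

    # --- stage 2: the six gene lists --------------------------------------
    candidates = up
    cna_tnbc = cohortio.CopyNumberTable(cna.values[tnbc_ids])
    tnbc_flags = pd.Series(
        {s: s in set(tnbc_ids) for s in clinical.samples}, name="tnbc"
    )
    gl1 = _stage("gl1")(prioritize.build_gl1, candidates, cna_tnbc, z_tnbc,
                        config.gl1_threshold)
    gl2 = _stage("gl2")(prioritize.build_gl2, candidates, cna_met,
                        config.gl2_threshold)
    gl3 = _stage("gl3")(prioritize.build_gl3, candidates, expr, clinical)
    gl4 = _stage("gl4")(prioritize.build_gl4, candidates, expr, tnbc_flags,
                        config.gl_alpha)
    gl5 = _stage("gl5")(prioritize.build_gl5, candidates, expr, clinical,
                        config.gl_alpha)
    gl6 = _stage("gl6")(prioritize.build_gl6, candidates, panel,
                        config.gl_alpha)
    lists = {gl.name: gl for gl in (gl1, gl2, gl3, gl4, gl5, gl6)}
    intersection = prioritize.intersect_all(*lists.values())
    coexpressed = _stage("coexpression")(
        prioritize.coexpression_confirm, intersection, expr_tnbc,
        config.marker, config.r_min, config.coexpr_p,
    )
    result = prioritize.PrioritizationResult(
        gene_lists=lists, intersection=intersection, coexpressed=coexpressed,
        parameters=config.to_dict(),
    )
    for gl in lists.values():
        p = outdir / f"{gl.name}.txt"
        cohortio.write_gene_list(gl, p)
        written.append(p)
    p = outdir / "prioritization.json"
    p.write_text(json.dumps(result.to_dict(), indent=2) + "\n")
    written.append(p)
    report_lines += [""] + [f"{name}: {len(gl)} genes" for name, gl in lists.items()]
    report_lines += [
        "",
        f"intersection ({len(intersection)} genes): " + ", ".join(intersection),
        f"marker co-expressed ({len(coexpressed)} genes): " + ", ".join(coexpressed),
    ]
    if truth is not None:
        planted = truth["planted_genes"]
        recovered = [g for g in planted if g in intersection]
        report_lines.append(
            f"planted genes recovered: {len(recovered)}/{len(planted)}"
        )

    manifest = _finalize(config, outdir, written, report_lines)
    return PipelineRun(config=config, result=result, deg_table=deg_table,
                       stratification=strat, signature_report=signature_report,
                       outdir=outdir, manifest=manifest, truth=truth)


def _finalize(config: PipelineConfig, outdir: Path, written: list[Path],
              report_lines: list[str]) -> dict:
    report_path = _write_report(outdir, report_lines)
    written.append(report_path)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
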