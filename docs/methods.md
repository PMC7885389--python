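# Methods

This note documents the models, parameter choices and numerical decisions
behind `cox2prio`, and what the synthetic studies do and do not establish.

## Pipeline model

The analysis takes a gene-by-sample FPKM matrix, a clinical table
(ER/PR/HER2 status, PAM50 subtype, OS and DMFS time/event), discrete
copy-number calls in {−2, …, +2}, and a cell-line panel (EC50 per line,
log2 expression per gene per line).

**TNBC selection.** A sample is TNBC iff ER, PR and HER2 are all
`negative`. An `unknown` status excludes the sample: triple negativity
must be established, not merely unrefuted.

**z-scores.** Per gene, on log2(FPKM+1) (pseudocount +1 handles zeros),
referenced to *all* samples of the supplied matrix, with population
(ddof = 0) SD. Diploid-referenced z-scores would need matched CNA calls
per sample and are not reproducible from expression alone; the all-sample
reference is the deterministic choice and is what the z-gate thresholds
(+1 / −0.25) are interpreted against. Zero-variance genes map to all-zero
rows. Population vs sample SD is immaterial at cohort size; population SD
is fixed for determinism.

**Stratification.** The marker gene's z-row is gated (z > z_high for the
high side, z < z_low for the low side) and each side is then capped at the
top ⌈fraction·n⌉ samples by z (defaults +1, −0.25, 0.15). Gate-then-cap
reproduces the asymmetric group sizes that arise when one gate is stricter
than the other. Ties in z break by sample id.

**Differential expression.** Per gene, a Welch t statistic on
log2(FPKM+1), high minus low. Significance comes from label permutations:
one shared set of shuffled labels scores every gene (the behavior of
marker-selection tools that permute class labels globally), with
p = (1 + #{|t*| ≥ |t|}) / (n_perm + 1), so p is never zero; when the
number of distinct arrangements C(n, n_high) ≤ 20 000 the scalar kernel
enumerates them exhaustively instead. Default n_perm = 1000. FDR is
Benjamini–Hochberg over all tested genes. Fold change is computed on the
*linear* FPKM scale, (mean_high + 1)/(mean_low + 1): the conventional
"fold change > 1.5" filter refers to linear ratios, while t is computed in
log space where variance is stabilized. A consequence worth knowing: for
near-null genes the linear mean is tail-dominated, so the fold-change
direction and the t sign can disagree below |t| ≈ 2; they always agree
for genes the filter can actually select. All filter inequalities are
strict. The DEG table is ranked by t descending, ties broken by symbol.

**Signature validation.** The up+down signature rows are z-scored over
the stratified samples and the samples clustered by average linkage
(UPGMA) on 1 − Pearson correlation of their signature profiles, cut at
k = 2. Correlation distance removes per-sample offsets, so a signature
must contain an expression *pattern* (both directions) to separate
groups — a one-sided signature is structurally invisible to it. Agreement
is reported as a confusion matrix, an exact-match flag and the ARI.

**Gene lists.** GL1's alteration rate is the *literal sum* of the
amplification percentage (+2 calls) and the mRNA-up percentage (z > +1),
so dual-altered patients are double-counted and the rate can exceed 100 —
this is the definition used by the alteration-frequency displays the
criterion mimics. GL3 demands a strict maximum of the Basal subtype mean
over each other subtype; ties exclude (determinism requires a rule, and
"highest" is read strictly). GL4 and GL6 use one-sided Welch tests at
p < 0.05 — the minimal standard reading of "significantly highly
expressed"; this is an assumption, recorded here deliberately. GL5 splits
each gene at its cohort median (high arm strictly above) and requires
log-rank p < 0.05 *and* the high arm disadvantaged (O − E > 0), for both
OS and DMFS; "auto best cutoff" scanning is out of scope. The panel split
generalizes 18/19 to ⌊n/2⌋ more-sensitive / ⌈n/2⌉ less-sensitive, ties in
EC50 broken by line id. The intersection preserves the first list's
order.

## Synthetic cohorts

The generator's defaults are the study conditions used by the acceptance
studies; all effect sizes are in log2(FPKM+1) units.

| parameter | default | meaning |
|---|---|---|
| n_patients | 120 | cohort size |
| n_genes | 2000 | gene universe (marker + background) |
| tnbc_frac | 0.5 | fraction ER−/PR−/HER2− (all labelled Basal) |
| delta | 2.0 | planted-gene shift; applied once in Basal samples and once more in marker-high patients |
| sigma | 0.5 | within-group SD of log2 expression |
| baseline_mu_range | (3, 7) | per-gene mean, drawn once per gene |
| amp_freq | 0.15 | P(+2 call) for planted genes (background 0.02) |
| surv_beta | 1.0 | log hazard ratio for the high-risk half |
| baseline_hazard | ln2/60 | median survival ≈ 60 months at baseline |
| censor_frac | 0.3 | target uniform-censoring fraction |
| n_lines / delta_panel | 37 / 3.0 | panel size; resistance-gene shift in the less-sensitive half |

Design notes:

* **Causal co-expression.** The marker is drawn first; marker-high
  patients are labelled with exactly the z-gate + cap rule the DEG stage
  uses (TNBC-wide); planted genes are then shifted in those patients.
  Co-expression with the marker is therefore causal in the simulation,
  mirroring the stratify-then-compare design being tested.
* **One effect knob.** Planted genes carry the Basal-subtype enrichment
  and the marker-high increment with the same magnitude `delta`, and a
  companion down-regulated block (−delta in marker-high patients) mirrors
  a two-sided signature. `delta = 0` with `surv_beta = 0` is an exact
  null for every downstream test.
* **Cohort composition is fixed, not sampled.** TNBC count and non-TNBC
  subtype counts use largest-remainder apportionment of the stated
  probabilities (assignment to samples is randomized). This reflects how
  cohorts report fixed composition and guarantees every PAM50 subtype is
  present whenever the arithmetic allows, which GL3 requires.
* **Survival.** Exponential, hazard h₀·exp(β·I(mean planted expression >
  median)); OS and DMFS are independent draws with the same hazards.
  Censoring is uniform on [0, T] with T solved (Brent) so the expected
  censoring fraction equals `censor_frac`; the realized fraction lands
  within ±10 percentage points.
* **CNA calls** are i.i.d. across genes and samples (−2: 1%, ±1: 5% each,
  +2: `amp_freq` or background); the alteration-rate criterion only uses
  marginal frequencies.
* Because any varying Gaussian gene has ≈16% of samples above z = +1,
  GL1's 10% threshold is weakly selective *on synthetic data*; the planted
  amplification keeps planted genes comfortably above it, which is all the
  recovery study needs.

**What the generator does not emulate:** tumor micro-environment, batch
effects, read-level noise, correlated CNA segments, non-exponential
hazards, informative censoring, or realistic FPKM heavy tails. Passing
tests therefore demonstrate that the *procedure* is implemented correctly
and is calibrated under its own assumptions — not that it would reproduce
any particular real-cohort gene list, which depends on retired data
freezes of the source databases.

## Statistical kernels

Welch t, Pearson r (t-transform p, n−2 df), BH-FDR and UPGMA linkage are
delegated to scipy/statsmodels. Kaplan–Meier and the log-rank test are
implemented in-package: the estimator returns the at-risk table, subjects
censored at an event time count as at risk at that time, and the log-rank
test uses the hypergeometric variance for ties and reports
sign(O_A − E_A) so callers can gate on direction. lifelines serves as an
independent oracle in the test suite, never as the implementation.

## Dose-response fitting

response = bottom + (top − bottom)/(1 + (dose/IC50)^hill), fitted by
least squares on log-dose with the Hill slope bounded to (0.1, 10) and
initialization from the data extremes and the dose nearest half-response.
The IC50 is the fitted curve midpoint. Curves whose observed response
span is below 0.3 are rejected as degenerate rather than fitted. The
recovery test uses a 10-point, 4-decade dose design (0.5–5000 µM): with
four free parameters, sparser 8-point designs leave the plateau/midpoint
trade-off poorly constrained and the IC50 spread roughly doubles.

The cleavage-efficiency formula 1 − √(1 − fraction cleaved) inverts the
re-annealing model: a heteroduplex is cleavable when exactly one strand
carries an indel, so the uncleaved fraction is the square of the unedited
allele fraction. Caliper measurements are auto-ordered so the larger
reading is Length.

## Problem sizes of the repeated-simulation studies

Null calibration pools 20 cohorts of 2000 genes × 120 patients
(n_perm = 1000) and applies one Kolmogorov–Smirnov test to the pooled
p-values; the marker gene is excluded from the pool because the groups
are stratified on it, making it differential by construction. The
planted-recovery study runs the complete pipeline (cohort + metastatic
cohort + panel simulation included) on 20 seeds at the default
conditions. These sizes keep each study to well under a minute while
leaving the binomial/KS error far from the acceptance margins.

## Known limitations

* The permutation scheme shares one permutation set across genes; this
  matches the emulated tool and is fast, but p-values are mildly
  dependent across genes within a run (the pooled KS test absorbs this).
* GL5's median split discards within-arm dose-response information; a
  Cox model would be more efficient but is deliberately out of scope.
* The packaged gene-list fixtures are transcriptions of a printed table;
  list 5 carries 21 symbols (its final entry is required for the
  ten-gene intersection to hold).
* No multiple-testing correction is applied across the six list-builder
  tests themselves; the intersection is the error-control mechanism, as
  in the original design.
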