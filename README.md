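# cox2prio

Marker-anchored candidate-gene prioritization for triple-negative breast
cancer (TNBC), packaged as a tested, reusable pipeline.

## The scientific problem

COX-2 (*PTGS2*) is over-expressed in aggressive breast tumors, yet selective
COX-2 inhibitors have shown inconsistent clinical benefit, suggesting that
co-expressed genes modulate both tumor aggressiveness and drug response. A
practical way to nominate such genes from public data is a *multi-criterion
intersection*: stratify a TNBC cohort by marker expression, find the genes
differentially enriched in marker-high patients, and keep only those that
independently show

1. **GL1** – genetic alteration (copy-number amplification, CNA call +2, or
   mRNA z-score > +1) in more than 10% of primary TNBC patients,
2. **GL2** – copy-number amplification in more than 1% of a metastatic
   cohort,
3. **GL3** – strictly highest mean expression in the Basal PAM50 subtype,
4. **GL4** – significantly higher expression in TNBC vs non-TNBC samples,
5. **GL5** – high expression associated with worse overall survival (OS)
   *and* worse distant metastasis-free survival (DMFS), and
6. **GL6** – significantly higher expression in the less-sensitive half of
   a cell-line panel ranked by COX-2-inhibitor EC50.

The intersection GL1 ∩ … ∩ GL6 is the candidate set; a final Pearson
co-expression check (r > 0.2, p < 0.05 against the marker) confirms which
candidates track marker expression. Applied to the published gene lists
(packaged here as fixtures), the intersection yields the ten candidates
*TPM4, RGS2, LAMC2, SERPINB5, KLK7, MFGE8, KLK5, ID4, RBP1, SLC2A1*.

## The statistics underneath

* **Stratification** — per-gene z-scores of log2(FPKM+1) over the cohort
  (population SD); marker-high = z > +1, marker-low = z < −0.25, each side
  capped at the top ⌈0.15·n⌉ samples.
* **Differential expression** — per-gene Welch t on log2(FPKM+1) with a
  two-sided label-permutation p-value, p = (1 + #{|t*| ≥ |t|})/(n_perm + 1)
  (exhaustive enumeration when the number of label arrangements ≤ 20 000),
  Benjamini–Hochberg FDR, and the compound filter FC > 1.5, p < 0.05,
  |t| > 2, FDR < 0.35.
* **Survival** — Kaplan–Meier product-limit curves and the two-group
  log-rank test (hypergeometric variance for ties), with a direction gate:
  the high-expression arm must have O − E > 0 for both endpoints.
* **Clustering** — average-linkage (UPGMA) on 1 − Pearson correlation,
  cut at k = 2, scored with the Adjusted Rand Index against the
  stratification labels.
* **Wet-lab arithmetic** — Surveyor cleavage efficiency
  1 − √(1 − fraction cleaved), caliper tumor volume (4/3)π(L/2)(W/2)²,
  percent viability inhibition (1 − treated/control)·100, and 4-parameter
  log-logistic IC50 fitting.

Because the original cohorts are not redistributable, a synthetic-cohort
generator (`cox2prio.synthetic`) emulates their statistical structure —
log-normal FPKM with a planted marker-co-regulated gene block, discrete CNA
calls, exponential survival with expression-dependent hazard, uniform
censoring, and an EC50-ranked cell-line panel — so every stage of the
pipeline is testable end-to-end, including its null behavior.

## Worked example

```sh
cox2prio run --outdir demo --seed 7
```

simulates a 120-patient cohort (60 TNBC), a 180-patient metastatic cohort
and a 37-line drug panel, then runs the full analysis. Output:

```
cox2prio pipeline run (seed 7)

TNBC samples: 60
marker-high: 9  marker-low: 9
DEG up (marker-high): 14  DEG down: 10
signature clustering ARI: 1.000 (exact match: True)

GL1: 14 genes
GL2: 13 genes
GL3: 9 genes
GL4: 9 genes
GL5: 9 genes
GL6: 9 genes

intersection (8 genes): G0006, G0008, G0004, G0007, G0002, G0005, G0003, G0001
marker co-expressed (8 genes): G0006, G0008, G0004, G0007, G0002, G0005, G0003, G0001
planted genes recovered: 8/8
```

Reading this: of the 60 simulated TNBC patients, 9 were marker-high and 9
marker-low; 14 genes passed the compound DEG filter upward (the 8 planted
genes, the marker itself, plus a few borderline nulls) and 10 downward; the
DEG signature separates the two patient groups perfectly (ARI = 1); the
six evidence lists intersect to exactly the 8 genes that were planted to
satisfy every criterion, and all of them pass the marker co-expression
check. Every intermediate table (DEG table, volcano data, gene lists,
manifest with content hashes) is written under `demo/`.

The published gene lists can be intersected directly without simulation:

```sh
echo "table1_only: true" > table1.yaml
cox2prio run --config table1.yaml --outdir table1
```

prints the ten-candidate intersection named above.

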