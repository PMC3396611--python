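# prognoseq

Genome-wide RNA-seq biomarker screening for time-to-event outcomes, built
for the setting where whole-transcriptome counts from archival (FFPE)
tumor tissue are screened for association with disease recurrence — the
workflow behind RNA-seq prognostic-marker discovery in breast-cancer
cohorts with on the order of 136 patients and 26 events.

It is a library plus CLI for statisticians and computational biologists
who need the full chain, reproducibly:

1. **Normalization** — log2 counts (log2(0) := 0), max-count < 5
   exclusion, third-quartile normalization against a reference feature
   class (RefSeq or intronic), RLE diagnostics.
2. **Survival screen** — for each feature, univariate Cox regression on
   standardized expression: per-SD log hazard β and standardized hazard
   ratio SHR = e^β; Lin–Wei robust sandwich SE; Wald p (t reference with
   df = events − 1); Storey q-values (λ = 0.5); TDRDA sets — the maximum
   lower bound B for which |SHR| > B holds at FDR 10% — and
   regression-to-the-mean–corrected SHRs via empirical-Bayes shrinkage
   β_rtm = β̄ + (β − β̄)·τ²/(τ² + se²).
3. **Intergenic discovery** — pooled reads → read islands → merge-cutoff
   estimation against gene annotation → ROIs → retention filters
   (avg count ≥ 5, length ≥ 100 bp, depth ≥ 0.075) → intergenic
   classification against refFlat spans → per-patient ROI counts →
   post-FDR <1000 bp condensation with co-expression evidence.
4. **Networks & subgroups** — co-expression graph at Pearson R > 0.6 over
   identified features; ER status calls from bimodal ESR1/PGR expression.
5. **Concordance** — Lin's CCC and Pearson r on log2 hazard ratios across
   platforms, RT-PCR C_T normalization, prognostic-agreement 2×2 tables
   with Fisher's exact test.
6. **Synthetic cohorts** — a first-class generator reproducing the
   emulated cohort's abundance spectrum, co-expressed blocks,
   negative-binomial counts, library-size variation, exponential survival
   with calibrated censoring, and a small genome with hidden intergenic
   loci — so the entire pipeline is testable offline.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run the full pipeline on a synthetic cohort emulating the target study
(136 patients, 26 events, 2,000 features, four co-expressed blocks):

```yaml
# demo.yaml
outdir: demo_run
seed: 4
cohort:
  n_patients: 136
  n_features: 2000
  n_events_target: 26
  prognostic_fraction: 0.10
  block_sizes: [10, 15, 25, 50]
  block_rho: 0.85
n_read_patients: 8
depth_scale: 8.0
```

```bash
prognoseq run --config demo.yaml
```

prints (abridged):

```json
{
  "n_patients": 136,
  "n_events": 30,
  "n_features_retained": 2000,
  "pi0": 0.94,
  "n_identified": 2,
  "intergenic": {
    "n_reads": 190413, "n_islands": 98, "merge_cutoff": 50,
    "n_rois": 95, "n_retained": 92, "n_intergenic": 16
  },
  "network": {"n_nodes": 2, "n_edges": 1, "component_sizes": [2]}
}
```

Read it as: after the max-count filter, 2,000 features were screened
against the 30 observed events; Storey's estimate says ~94% of features
are null, and 2 features pass FDR < 10% (with only ~26 events, genome-wide
power against moderate effects is low — many seeds identify nothing, which
is the statistically honest outcome). The read pool over the synthetic
genome collapses into 98 islands, merged at the estimated 50-bp cutoff
into 95 ROIs, of which 16 — exactly the planted hidden loci — survive the
filters and fall outside annotated genes. The two identified features
co-express at R > 0.6 and form one 2-node network component.

The screen table itself (`demo_run/screen.tsv`, best rows):

```
feature_id   beta     robust_se  shr     p       q       tdrda_lower_bound  shr_rtm
F00552      -0.5202   0.1067     0.5944  0.0000  0.0678  1.0                0.8090
F00788      -0.7995   0.1751     0.4496  0.0001  0.0797  1.0                0.8521
```

F00788's hazard drops ≈55% per SD of expression (SHR 0.45), it survives
FDR 10% (q = 0.08) with a TDRDA lower bound of 1.0 on |SHR|, and its
RTM-corrected SHR of 0.85 shows how much of the observed extremity the
shrinkage attributes to selection.

Stage-by-stage CLI commands (`prognoseq normalize|screen|
discover-intergenic|network|call-er|concord|synth`) expose the same
functionality on your own TSV/CSV/BED/refFlat files; every function is
also importable (`from prognoseq import screen, lin_ccc, ...`).

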