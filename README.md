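# immunoflow

Synthetic flow-cytometry cohort simulation, hierarchical boolean gating,
T-cell exhaustion scoring, macrophage polarization profiling, and
Bonferroni-corrected two-group comparison tables for splenocyte / tumor
immunophenotyping studies.

The package covers an end-to-end analysis pipeline:

1. **`immunoflow.synthetic`** — generate per-animal event-level marker
   intensity tables (two-mode log-normal intensity models, ≥50,000 events
   per animal by default) whose gated population fractions follow
   cohort-level (mean, SD) percentage statistics. Builtin cohort presets
   transcribe published group summary tables for wild-type (WT) and
   transfected (TF) tumor-bearing, sham (SH), and checkpoint-blockade
   (TF_aPDL1) groups.
2. **`immunoflow.gating`** — boolean threshold gates with AND semantics
   arranged in gate trees; percent-of-parent and percent-of-root
   statistics; builtin antibody panels (1, 1t, 2, 3, 3mod, 4); automatic
   density-valley threshold estimation for external event tables; JSON
   serialization of gate trees.
3. **`immunoflow.stats`** — the T-cell exhaustion score
   `(PD-1% + Tim-3% on CTLs and Ths) / (CTL% + Th%)`, the M1:M2
   macrophage marker ratio, caliper tumor volume (`length x width^2 / 2`),
   antibody dosing, and the two-tailed **pooled-variance** Student's
   t-test (from raw values or summary statistics) with Bonferroni
   family-wise correction.
4. **`immunoflow.pipeline`** — orchestration (`summary` mode compares the
   transcribed published summaries deterministically; `simulation` mode
   runs generate → gate → score → compare at event level), report
   rendering (CSV / JSON / markdown with significance asterisks), and a
   reproducibility manifest.

All report percentages are percent-of-parent within the panel hierarchy
(e.g. Tregs as percent of the CD4+ Th gate, granulocytes as percent of
the CD11b+ myeloid gate); top-level populations are percent of the CD45+
leukocyte gate.

## CLI

```bash
# simulate a cohort of event tables (CSV, one row per event)
immunoflow simulate --cohort TF --panel 3 --events 50000 --seed 17 --out cohort_dir

# gate one event table into the panel's populations
immunoflow gate --panel 3 --in cohort_dir/TF_3_00.csv --out populations.csv

# exhaustion score from a gated table
immunoflow score --in populations.csv

# compare two summary tables (population,mean,sd,n)
immunoflow compare --a tf.csv --b sh.csv --family-size 6

# full comparison tables
immunoflow report --panel 3 --panel 4 --cohort-a TF --cohort-b SH --mode summary --out results/
immunoflow run-all --mode simulation --seed 1 --out results/
```

## Reproducibility notes

- Cohort sampling is deterministic in `(seed, animal_index)` and, by
  default, *quantile-stratified*: each animal receives a distinct normal
  quantile so finite-cohort sample moments track the configured
  (mean, SD). Plain iid draws are available via `sampling="iid"`.
- Event/marker assignment defaults to exact apportionment of the sampled
  per-animal fractions (`assignment="exact"` in `generate_cohort`);
  multinomial/Bernoulli draws are available via `assignment="stochastic"`
  (and are the defaults of the lower-level `generate_events`).
- Events exactly at a gate threshold are negative; positive/negative
  gates at one threshold therefore partition their parent.
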