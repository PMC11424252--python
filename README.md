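# tcatrace

Analysis toolkit for intraoperative ¹³C isotope-tracing studies of
TCA-cycle metabolism in kidney tissue and kidney cancer. Patients infused
with [U-¹³C]glucose, [1,2-¹³C]acetate or [U-¹³C]glutamine yield tissue
fragments whose metabolite mass isotopologue distributions (MIDs) report
how each tumour feeds and turns its TCA cycle. `tcatrace` implements the
computational chain from raw isotopologue envelopes to cohort-level
statistics, for metabolism researchers who want the whole pipeline
reproducible and testable without patient data.

## What's inside

* **`tcatrace.tca`** — an exact positional-isotopomer simulator. Each
  metabolite pool is a probability vector over its 2^C carbon-labelling
  patterns; reactions are the standard atom maps (citrate synthase, IDH,
  alpha-KG dehydrogenase with its CO₂ losses, succinate/fumarate
  scrambling, PDH and pyruvate-carboxylase entry, reductive carboxylation
  of alpha-KG). Tracer signatures emerge exactly: acetate gives
  first-turn citrate m+2 and [4,5-¹³C]glutamate, a second turn gives
  citrate m+4, glutamine gives oxidative m+4 intermediates or reductive
  citrate m+5 / malate m+3.
* **`tcatrace.natabund`** — natural-abundance correction of measured
  MIDs for derivatized GC-MS fragments (lower-triangular correction
  matrix, nonnegative least-squares inversion).
* **`tcatrace.metrics`** — the labelling statistics: total labelling
  1 − m+0, citrate m+2/pyruvate m+3, citrate m+4/citrate m+2, plasma
  normalizations, the [4,5-¹³C]glutamate fraction of labelled glutamate,
  and the respiratory control ratio (state III/state IV).
* **`tcatrace.qc`** — LC/GC-MS feature-table QC: S/N against blanks,
  QC run-order trend tests with Benjamini–Hochberg adjustment,
  conditional LOESS drift correction, stable-subset TIC normalization,
  log₁₀ + ionization-mode deduplication, Cohen's-d cross-study
  concordance.
* **`tcatrace.survival`** — OxPhos gene-set scoring (PC1 of z-scaled
  log₂ expression of KEGG OxPhos + PDH-complex genes), median or 30/70
  stratification with grade/stage filters, Kaplan–Meier curves, log-rank
  tests, and the nested fragment-within-patient comparison.
* **`tcatrace.cohort`** — seeded synthetic generators for tracing
  cohorts, QC feature tables, and expression/survival cohorts.
* **`tcatrace.cli` / `tcatrace.io`** — a `tcatrace` command with
  `simulate`, `correct`, `metrics`, `qc`, `score`, `synth` and `run`
  subcommands over tidy CSV/TSV/GMT/JSON files.

## Worked example

Simulate an acetate infusion at 25 % acetyl-CoA enrichment in a
kidney-like tissue and read off the two-cycle retention marker:

```python
from tcatrace import TCAParams, TracerSpec, simulate

params = TCAParams(pdh_fraction=0.0, pc_fraction=0.05,
                   anaplerosis_unlabelled=0.2, turnover=0.8,
                   reductive_fraction=0.05)
result = simulate(TracerSpec("acetate_12_13C2", 0.25), params)
citrate = result["citrate"][1]
print([round(f, 4) for f in citrate.fractions])
# [0.5714, 0.0631, 0.2845, 0.0408, 0.033, 0.0066, 0.0006]
print(round(citrate[4] / citrate[2], 4))   # 0.1162
```

Citrate m+2 (0.285) dominates the labelled species — single-turn acetate
entry — while the m+4/m+2 ratio of 0.116 measures how much label survived
a second turn of the cycle at turnover 0.8.

Generate the default synthetic kidney-vs-tumour glucose cohort (10+10
patients, 3 fragments each) and run the nested patient-level comparison
of the PDH-contribution ratio:

```python
from tcatrace import default_cohort_spec, generate_tracing_cohort, nested_comparison
from tcatrace.io import metrics_table

records = generate_tracing_cohort(default_cohort_spec(), seed=17)
table = metrics_table(records)
sub = table[table.metric == "citrate_m2_over_pyruvate_m3"]
res = nested_comparison(sub, "adjacent_kidney", "ccRCC")
print(res.statistic, res.p_value)   # 10.40  4.9e-09
```

The kidney-like class averages a citrate m+2/pyruvate m+3 ratio of 0.95
against 0.44 in the tumour-like class — the suppressed-glucose-oxidation
contrast the metric was designed to detect — and the nested test, which
collapses fragments to patient means before testing, rejects decisively.

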