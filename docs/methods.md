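# Methods

## The label-fate model

`tcatrace.tca` propagates exact distributions over the 2^C binary
carbon-labelling patterns of each TCA-cycle metabolite pool through the
cycle's atom mappings, one discrete turn at a time. This is a
Markov-chain view of isotope propagation, not a kinetic flux model: the
state space is small (at most 64 patterns for citrate), every reaction is
a linear map on a probability vector, and all results are exact to
floating-point precision. The discrete-turn framing matches how tracer
data from the three clinical tracers are usually interpreted — "first
turn" and "second turn" labelling signatures — and makes the simulator
usable both as a data generator and as an enumeration oracle for the
metrics built on top of it.

Atom maps follow standard citrate-synthase/aconitase/IDH stereochemistry.
The convention used internally is: acetyl-CoA C1 (carboxyl) and C2
(methyl) become glutamate C5 and C4; both CO2 molecules released in a
turn (IDH, then alpha-KG dehydrogenase) derive from OAA carbons. Any
numbering convention giving the same observables is equivalent; the
observable anchors are

* [1,2-13C]acetate, first turn: citrate m+2 only, glutamate labelled at
  positions 4 and 5 only;
* second turn with label retention: citrate m+4;
* [U-13C]glutamine, oxidative first turn: m+4 four-carbon intermediates
  and m+4 citrate;
* reductive carboxylation of alpha-KG m+5: citrate m+5, and malate m+3
  after citrate cleavage;
* [U-13C]glucose with pyruvate-carboxylase entry: first-turn citrate
  beyond m+2 (m+3, m+5).

Succinate and fumarate are symmetric molecules; their pattern
distributions are averaged with the carbon-reversed distribution after
every update (exact 50/50 scrambling).

### Turn ordering

A "turn" applies the reaction steps sequentially in cyclic order starting
just downstream of the tracer's entry point: condensation first for the
acetyl-entry tracers (glucose, acetate), alpha-KG dehydrogenase first for
glutamine. Starting every tracer at condensation would make first-turn
citrate m+4 from glutamine impossible (the label must travel
alpha-KG → succinate → … → OAA → citrate within its first pass), whereas
the rotated ordering carries freshly entered label exactly once around
the cycle per turn for every entry point.

### OAA inflow and the turnover knob

The OAA pool refresh combines the anaplerotic split and cycle turnover
without redundancy:

    OAA = pc·PC(pyruvate) + ana·unlabelled
          + (1 − pc − ana)·(turnover·malate + (1 − turnover)·unlabelled)

`pc` (pyruvate-carboxylase share) and `ana` (unlabelled anaplerosis)
partition the inflow, and `turnover` is the per-turn probability that a
cycle-derived OAA molecule re-enters condensation rather than exiting.
Consequences used as tests: turnover = 0 means no citrate m+4 from
acetate after the first turn; citrate m+4/m+2 is non-decreasing in
turnover.

### Glutamine entry and the reductive branch

Glutamine entry is modelled as full per-turn replacement of the alpha-KG
pool at the stated enrichment (the pool is treated as dominated by the
anaplerotic source). The reductive branch is applied once, after the
oxidative turns, as a terminal mix of weight `reductive_fraction` into
the citrate and malate pools — it is a route signature, not an iterated
kinetic pathway. Under the glutamine tracer the branch runs on the
glutamine-derived alpha-KG source; under the other tracers on the cycle
alpha-KG pool.

### Defaults

| parameter | default | rationale |
|---|---|---|
| acetate acetyl-CoA enrichment | 0.25 | infusions reach ~20–25 % acetyl-CoA m+2 |
| glutamine m+5 enrichment | 0.32 | plasma glutamine m+5 plateaus near 30–35 % |
| glucose-derived pyruvate m+3 | 0.20 | mid-range tissue pyruvate enrichment under a glucose infusion |
| `n_turns` | 8 | labelling has converged for turnover < 1 |
| `glu_exchange` | 1.0 | glutamate–alpha-KG exchange is fast relative to a turn; a modelling choice, configurable |
| `dilution` | 0.0 | single knob for per-pool unlabelled exchange; per-pool overrides possible by diluting states directly |

A note on monotonicity: citrate m+2/pyruvate m+3 rises with the PDH share
at moderate turnover, but at very high turnover additional cycling moves
citrate mass from exactly-m+2 into m+4/m+5 species and the exact-m+2
fraction can dip. The monotonicity checks therefore fix turnover at 0.6;
the non-monotone high-turnover regime is real model behaviour, not an
artefact.

## Natural-abundance correction

The measured envelope of a derivatized fragment convolves the
tracer-derived MID with the natural isotope pattern of every non-tracer
atom (TBDMS derivatization adds C, H, Si) plus the residual 1.07 % 13C of
unlabelled backbone carbons. The correction matrix is lower-triangular
with positive diagonal; the inverse problem is solved by nonnegative
least squares rather than direct inversion, because inversion can return
negative fractions on noisy data. Clamped values are logged. Isotope
abundances default to IUPAC 2021 representative values and are
overridable. The forward model truncates the envelope to the m+0..m+C
window and renormalizes, mirroring how instruments report a bounded
isotopologue window; the round-trip correct(convolve(x)) = x holds to
better than 1e-8 on TBDMS-scale formulas.

## Labelling metrics

Ratios (citrate m+2/pyruvate m+3, citrate m+4/citrate m+2, plasma
normalizations, the [4,5-13C]glutamate fraction) return missing values
with reason codes instead of raising, so cohort tables stay rectangular.
The [4,5] glutamate fraction uses 1 − P(unlabelled) as its denominator;
for exhaustive positional distributions this equals the sum over labelled
positional species. The respiratory control ratio is state III / state IV
oxygen consumption.

## Metabolomics QC pipeline

Stage order is fixed: S/N filter statistics → run-order trend test →
LOESS drift correction → stable-subset TIC normalization → log10 +
mode deduplication. Choices where common practice had to fill gaps:

* Run-order trend: Spearman correlation (robust to monotone
  nonlinearity), restricted to QC points inside the metabolite's QC
  interquartile range, BH-adjusted at alpha 0.05.
* LOESS (span 0.75) is fit on QC samples only and interpolated to all
  run orders (QC-based robust LOESS signal correction); correction is
  conditional on BH significance, and metabolites with a nonpositive
  fitted trend are skipped with a logged reason.
* Stable subset for normalization: QC CV ≤ 0.2 and S/N ≥ 10. Blank
  columns are never normalized — they define the noise floor, not sample
  loading — which also makes normalization idempotent.
* Zeros are imputed as half the metabolite's minimum positive value
  before the log; ties in mode deduplication keep positive mode. All
  such events are logged.
* Multi-batch tables are processed independently per batch.

Cross-study comparison: intensities are min-normalized and
log10-transformed, group differences summarized as Cohen's d with pooled
SD, and concordance with an external effect-size table computed as
Pearson's r over the intersection of HMDB identifiers.

## Scoring and survival

The OxPhos score is PC1 of log2-transformed, per-gene mean-centred,
z-scaled expression of the OxPhos gene set (KEGG oxidative
phosphorylation plus PDHA1, PDHB, DLAT, DLD, PDHX), computed by SVD and
sign-oriented to correlate positively with mean set expression (without
the orientation, "high OxPhos" would be ambiguous). Stratification
supports a median split (ties to "low", logged) and a 30/70 quantile rule
that leaves the middle 40 % unlabelled, with optional grade/stage
subcohort filters. Kaplan–Meier estimation and the log-rank (Mantel–Cox)
test are delegated to lifelines; hand-worked product-limit tables and an
exhaustive 252-permutation oracle on a 5+5 toy set serve as independent
checks in the test suite.

The nested comparison treats patients as the independent units: fragment
values are collapsed to equally weighted patient means and compared with
a pooled-variance two-sided t-test. In the balanced case this is exactly
the two-level nested ANOVA with patient as the random factor (the
equivalence is asserted in the tests); for unbalanced cohorts it keeps
equal patient weights rather than reverting to fragment pooling, avoiding
pseudoreplication.

## Synthetic cohorts

The generators are pure functions of (spec, seed).

* Tracing cohorts: per-patient TCA parameters are log-normal
  perturbations (SD 0.2) of the tissue-class prior; fragment-level MID
  noise is Dirichlet with concentration 500 (≈2 % SD on major fractions),
  which respects the simplex by construction. The default contrast is 10
  kidney-like patients (turnover 0.9, PDH share 0.7, reductive 0.05)
  versus 10 tumour-like patients (turnover 0.45, PDH share 0.35,
  reductive 0.3), 3 fragments each — the scale of a per-tracer infusion
  subcohort.
* Feature tables: 40 metabolites × 80 study samples with a QC every 4
  injections (21 QCs, ~100 injections — a typical QC-RLSC design), blanks
  at 1 % of signal, QC noise CV 5 %, and an optional multiplicative 1→2
  run-order ramp on a quarter of the metabolites.
* Survival cohorts: a latent standard-normal program shifts the set
  genes; survival is exponential with hazard multiplied by exp(beta·z)
  and independent exponential censoring at a configurable rate.

What the generators do **not** emulate: correlated measurement error
across metabolites, retention-time or adduct artefacts, batch effects
beyond a batch label, non-proportional hazards, and real gene–gene
covariance. Passing tests therefore demonstrate correctness of the
computations under the stated statistical structure, not robustness to
every failure mode of real data.

## Problem sizes and determinism

Simulation is exact and seedless; all stochastic studies are seeded and
sized to run on a laptop: 100 seeded cohorts for the nested-comparison
power study, 200 replicates for QC drift power, 2000 replicates of 50+50
subjects for log-rank type-I calibration. `scripts/acceptance.py` derives
all randomness from its single `--seed` argument.

## Known limitations

* No absolute flux estimation, isotopic non-stationarity, or
  compartmentation; the reductive branch is a signature, not a flux.
* CO2 is assumed unlabelled everywhere except as the explicit
  reductive-carboxylation carbon (no refixation).
* The nested test assumes approximately normal patient means;
  heavy-tailed fragment noise would call for a rank-based variant.
* lifelines' chi-square log-rank p is asymptotic; at very small n the
  exact permutation distribution (used as the test oracle) is preferable.
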