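# Methods

This note documents the models, conventions and design choices behind
`cnssig`, in the order the workflow runs. Everything quantitative stated
here is computed by the test suite or the example scripts; nothing is
asserted that the code does not reproduce.

## Scope and shape

The package is a library (`src/cnssig`) whose public face is its
importable API plus `examples/` scripts; a thin `click` CLI mirrors the
stages (`simulate`, `discover`, `normalize`, `classify`, `evaluate`,
`run`) for shell use. Both in-silico stages of the diagnostic workflow
are covered: marker discovery from probe-level expression matrices, and
signature detection from probe counts. Orthogonal wet-lab validation
(PCR/Sanger detection of BCOR internal tandem duplications, targeted RNA
sequencing for MN1 fusions, immunohistochemistry) and DNA methylation
profiling are out of scope, as is probe-level summarization from raw
array files — discovery starts at probe-set matrices.

## Synthetic data: what it emulates, and what it does not

Real patient cohorts for these rare entities are not redistributable, so
every stage runs on synthetic cohorts with planted ground truth. The
generators are first-class, tested code; their defaults are the study
conditions used throughout the tests and the acceptance script.

### Discovery stage (microarray-like)

Log2 intensity of probe *i* in sample *j* of class *c*:

    x_ij = m_i + e_ic + ε_ij,   m_i ~ N(6, 2²),  ε_ij ~ N(0, 0.6²)

with `e_ic ≥ 0` the planted log2 effect (0 for non-markers). The
probe-level mean spread (sd 2 log2 units) matters: real arrays span many
log2 units across probes, and it is this spread that lets quantile
normalization preserve a planted effect. With a degenerate, narrow
probe-mean distribution an up-regulated probe is forced into extreme
ranks whose reference quantiles are dominated by non-elevated samples,
and the effect is compressed severely — an artifact of an unrealistic
generator, not of the method. Within-class noise of 0.6 log2 units is
typical for expressed probes on clinical-grade material.

The default discovery fixtures plant effects of 4–6 log2 units (16–64
fold). The marker panels of these entities are strongly up-regulated
(tens-fold in the discovery tables), so strong planted effects are the
realistic regime; quantile normalization still shaves 0.3–0.7 log2 units
off a planted effect when the target class is a quarter of the cohort
(visible in `examples/02_marker_discovery.py`).

### Detection stage (nCounter-like)

Counts are negative binomial, `Var = μ + φ μ²`, with a single dispersion
`φ = 0.005` shared across probes. Molecular-barcode counting is
near-Poisson; φ adds mild residual overdispersion so that a lane's count
for a ~400-count probe has CV ≈ 9%. This precision is what makes the
single-lane reference-fold QC reproducible: a marker planted at an
expected 8× reference fold is re-measured within roughly [5.3, 12]
across seeds (tested). Per-lane structure:

* efficiency factor `L_j = exp(N(0, 0.15²))` multiplying **all** probes
  (hybridization/scanning/FFPE-degradation yield; this is the only
  degradation model — no fragment-length effects);
* RNA-content factor `C_j = exp(N(0, 0.25²))` multiplying endogenous and
  housekeeping probes only;
* positive controls: a six-step geometric spike-in ladder
  (8192 … 8 expected counts, factor 4), scaled by `L_j` only;
* negative controls: mean 2 counts;
* housekeeping genes: entity-independent mean 1200 · `L_j` · `C_j`;
* endogenous markers: baseline 40 counts, multiplied for planted entity
  samples by a per-probe elevation factor.

The elevation is calibrated to the hybridization QC statistic rather
than set directly: for a target reference fold `F` drawn uniformly in
the configured window (default 3.9–92.7×) with `n_e` planted samples in
a cohort of `N`, the shared multiplier is `m = F(N−n_e)/((N−1) −
F(n_e−1))`, which makes the *expected* reference fold equal `F`. The
fold saturates at `(N−1)/(n_e−1)` when several samples share a
signature, so the drawn window is clipped to 95% of that ceiling and a
configuration whose window is entirely unattainable is rejected.

Reference samples are ordinary planted tumors, merely tagged (the real
references are tumors with prior methylation diagnoses, not a separate
population). Diagnoses configured as glioma-like express the glioma
panel at 4–16×; a configurable number of planted entity samples may
additionally express it (the dual-signature case), and single probes can
be elevated in chosen background diagnoses (e.g. EMX1/PRDM6 in posterior
fossa ependymomas/medulloblastomas — the reason those probes are
excluded from the infratentorial HGNET-BCOR panel).

Default cohort compositions mirror the published series: 92
supratentorial samples (80 background: 25 HGG, 17 PNET, 18 EPN, 9 CPC,
7 ATRT, 2 ETMR, 2 NOS; planted: 1 EFT-CIC, 3 NB-FOXR2, 4 HGNET-MN1,
4 HGNET-BCOR) and 95 infratentorial (93 background: 50 EPN, 36 MB,
4 CPC, 3 ATRT; planted: 2 HGNET-BCOR), 187 in total with 14 entity
samples. The patient-vs-sample ambiguity in the source cohort (a relapse
lane, references re-run across compartments) is deliberately not
resolved in code: compositions are configuration, not constants.

What the generators do **not** model: tumor purity dilution (the >70%
tumor-cell slide QC is metadata only), batch/cartridge effects beyond
the per-lane factors, probe-sequence-specific hybridization biases, and
correlated marker co-expression within an entity (probe elevations are
drawn independently). Passing tests therefore demonstrate that the
pipeline recovers planted signal under realistic noise — not that the
panels would perform identically on real FFPE material.

## Marker discovery conventions

* **Test variant**: two-sided pooled-variance Student t-test (Welch
  available via `DiscoveryParams(welch=True)`).
* **Resampling**: per repetition, a subset of the non-target pool of
  size `min(n_target, pool)` is drawn without replacement; if the pool
  is smaller than the target class the whole pool is reused with a
  warning. 100 repetitions by default; classes with few clean
  up-regulated candidates can use 200.
* **Fold change** is the difference of log2 means, reported also as
  `2^diff`. Averaging is done on the log scale across repetitions; the
  linear alternative can be recovered from the per-repetition interface
  but log-scale averaging matches the log2-transformed data.
* **Zero-variance probes** inside a repetition: p = 0 if the group means
  differ, 1 if equal (no NaN propagation).
* **Ranking**: ascending `mean_p`, ties by descending `mean_log2fc`,
  then probe id — fully deterministic. Ranks are assigned to every
  tested probe; the returned panel is fold-filtered (≥ 10×) and capped
  at `top_n` (100).
* **Quantile normalization** averages tied ranks (equal inputs map to
  equal outputs). On tie-free data — the generic case for continuous
  intensities — the operation is exactly idempotent; with ties a second
  pass can move tied values slightly, as in the standard tie-averaging
  implementations.
* **Compartments**: supra- and infratentorial samples are normalized and
  analyzed separately; this is a labeled data split, not two code paths.

## Count normalization conventions

Both normalization steps scale each lane by `target / geomean(anchor
probes)`. By default the target is the cohort's arithmetic mean of the
per-lane geometric means (the vendor software's default scheme); fixed
targets can be supplied instead, which is how stored reference lanes
from earlier runs stay comparable and makes the cancellation of a
per-lane scale factor mathematically exact (a lane rescaled by any k > 0
normalizes back to the same values; with cohort-derived targets the
cohort mean itself shifts slightly, so exact per-lane invariance holds
only for fixed targets). Lanes with zero anchor counts are QC-flagged;
the geometric mean then uses the remaining positive anchors, falling
back to factor 1. Log scale is `log2(count + 1)`. Background subtraction
(negative-control mean + 2 SD, floored at 0) exists behind a flag and is
off by default. The reference-fold QC runs on post-normalization linear
counts, and a zero mean of the non-reference samples renders the QC
indeterminate rather than passed.

## Classification conventions

* **Clustering**: average linkage (UPGMA) on Euclidean distances of the
  compartment's marker-panel + glioma-panel log2 vectors, via
  `scipy.cluster.hierarchy`; merge heights are validated against an
  exhaustive O(n³) oracle in the tests. Newick export uses
  height-difference branch lengths.
* **Signature score**: cohort-standardized mean of the entity's panel
  (z-score); an all-constant cohort scores 0 everywhere.
* **Calling rule** (the published analysis assigns groups by visual
  co-clustering with reference samples; this package fixes an explicit,
  testable rule): called entity = unique arg-max with `z ≥ τ` (τ = 2),
  panel elevation ≥ `min_call_fold` (2× over the cohort median panel
  level), and membership in the reference's cluster when the tree is cut
  into (number of referenced entities) + 1 clusters. The elevation guard
  exists because a z-score alone flags ~2% of null samples per entity in
  a ~90-lane cohort; requiring a two-fold absolute elevation (against
  marker folds of ≥ 3.9×) removes those flukes without costing
  sensitivity. Exact score ties yield no call and an `ambiguous` flag.
  Entities without a reference are callable but flagged
  `low-confidence-no-reference`; entities absent from a compartment's
  panel are not callable there, and configuring a reference for one is
  an error. A reference failing to recover its own entity aborts the run
  (`ClassificationIntegrityError`).
* **Tree-cut depth**: the (referenced entities + 1)-cluster cut is a
  declared convention; because planted samples share their reference's
  signature, calls are insensitive to the exact depth.
* **Glioma contrast**: per-panel "high" status uses a largest-gap
  bimodal split of panel scores (minimum gap 1 log2 unit) instead of the
  cohort z-score, because the glioma-expressing group is typically the
  *majority* of an HGG re-analysis cohort and cohort standardization
  cannot flag a majority (the z of a 22-of-28 majority saturates near
  0.5). Labels: `dual` (both panels), `signature`/`glioma` (one), and
  `outlier` for a sample expressing neither whose first merge height
  exceeds the cohort's 95th percentile of first-merge heights; neither-
  high samples that are not isolated are labeled `none`.

## Evaluation conventions

ROC curves sweep all observed scores (`sklearn.metrics.roc_curve`
without intermediate dropping, so the curve includes (0,0) and (1,1));
ties use the midrank convention, making the trapezoidal AUC equal the
pairwise Mann–Whitney statistic (tested against an exhaustive pair-count
oracle). Per-probe ROC is the primary report; a per-panel mean-score ROC
is exposed as an option. Entities with zero positives are skipped with a
warning — with tumors this rare, a class can easily have one sample or
none, and a single-positive AUC, while defined, is fragile.

## Problem sizes and determinism

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configuration and seed give
byte-identical outputs, and the pipeline manifest records SHA-256
digests per output for end-to-end reproducibility checks. The shipped
problem sizes — 187-lane cohorts, 1000-probe discovery matrices, 100
resampling repetitions, 10–50-seed replicate loops — were chosen so the
entire suite and the acceptance script each run in seconds on a single
CPU while keeping every statistic in its intended operating regime.

## Known limitations

* The calling rule, τ, the elevation guard and the tree-cut depth are
  this package's operationalization of a visual clustering judgment;
  other reasonable rules exist.
* The negative-binomial/log-normal generators have no correlated
  co-expression structure, so multi-probe panels are "easier" than on
  real tumors where marker probes co-vary.
* AUCs near 1 on synthetic cohorts (and in the source analysis) partly
  reflect tiny positive-class sizes; they are not an estimate of
  real-world single-probe performance.
* The RCC dialect is fixed to one common tag-delimited flavor (version
  1.7 header, `CodeClass,Name,Accession,Count` body); instrument
  metadata such as binding density is carried but not interpreted.
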