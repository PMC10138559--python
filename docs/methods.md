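# Methods

## Model and procedure

The pipeline takes gene × sample log2 expression matrices with a sample
sheet assigning samples to (platform, dose, time) conditions and a
control/treated cohort, plus gene-set collections (injury modules,
pathways) in GMT format. Per condition it computes per-gene log2 fold
changes as the difference of cohort means of log2 values, per-gene
significance, and then set-level activation scores.

**Fold change and DEG calling.** Per-gene significance uses a Welch
unequal-variance two-sample t-test on the log2 values. The choice is
deliberate: the only downstream consumer of p-values is the FDR cut, the
test is exactly calibrated under the generator's Gaussian model, and it
is swappable behind `de_test` if a count-model test (e.g. a
bootstrap-variance or negative-binomial method) is preferred for real
data. Genes with zero variance in both cohorts get p = 1 when the means
are equal and p = 0 otherwise. Multiple testing uses Benjamini–Hochberg
(via statsmodels), and DEGs are genes with q ≤ 0.1 — the threshold is
inclusive; the boundary matters only at exact ties. Genes with missing
values in either cohort are dropped per condition (no imputation) and
counted in the profile.

**Module scoring.** AAFC is the *mean* of |log2 FC| over the module's
measured genes; AFC is the mean of signed log2 FC. Mean rather than sum
makes scores comparable across module sizes; because every null draw has
exactly the module's size, mean and sum give identical z-scores (they
differ by the constant factor *m*). Gene-identifier matching is
case-insensitive; a module sharing no genes with the profile is refused
by single-module scoring and becomes a flagged NaN cell in table runs.

**Permutation null.** The null draws gene subsets of exactly the matched
size, without replacement, from the profile's measured genes —
independently per (module, condition) cell, each from a child RNG stream
derived deterministically from the top-level seed and the module and
condition labels, so table cells do not depend on evaluation order. The
default is 10,000 draws. When C(universe, size) ≤ 200,000 the
implementation switches to exhaustive enumeration of all subsets: the
null is then exact, its spread uses the population standard deviation
(ddof 0, since the entire null population is in hand) and the empirical
p is the exact tail fraction r/n. Monte-Carlo nulls use the sample
standard deviation (ddof 1) and the (r+1)/(N+1) correction so p is never
0. Ties count toward the tail (conservative). AAFC significance is
upper-tailed; AFC is two-sided around the null mean, since up- and
downregulation are both meaningful, and the direction label (up/down at
|z| > threshold) carries the sign. A degenerate null (sd = 0, e.g. the
module equals the universe or the profile is constant) yields NaN z and
p and an unactivated call — never a division by zero.

Note a structural property of profile-wide nulls: when a sizeable
minority of the universe is genuinely perturbed, unperturbed modules
score *below* the null mean (negative z), because the null mean absorbs
the perturbed genes. This is expected behaviour, visible in the first
example script.

**Pathway analyses.** Directional pathway scoring is AFC scoring with
category labels (Metabolism; Cell and Immune Signaling; Cell
Cycle/Translation/Transcription; other) — a pure relabelling that never
alters z. Over-representation uses the standard one-sided hypergeometric
upper tail against the measured-gene universe with BH adjustment across
the batch. This is the plain Fisher-type test; EASE-style variants that
subtract one from the hit count will give systematically larger
p-values.

**Comparative analyses.** DEG overlap matrices are pairwise intersection
counts; the common-gene set is the strict intersection across *all*
provided DEG sets; gene ranking uses the arithmetic mean of log2 FC
across conditions. Cross-platform/cross-species agreement is the squared
Pearson correlation of module-score vectors over a shared module
vocabulary (reported to 2 decimals). PCA embeds items (conditions) in
fold-change or module-score space: features are centred, not scaled, and
each component's sign is fixed by making its largest-magnitude loading
positive. Visual cluster-separation claims are quantified as the mean
silhouette coefficient in the first two PCs; all-singleton groupings are
0 by convention with a flag.

## Synthetic data generator

The generator emulates a two-platform (in vivo / in vitro), two-dose,
two-time toxicant study with small cohorts: gene g's log2 expression is
baseline(g) + shift(g, condition) (treated samples only) + N(0,
noise_sd), with baseline(g) ~ N(5, 2) drawn once and shared across
conditions and one control cohort per (platform, time) shared across
doses. Planted effects are organised into module-linked gene sets;
shift = sign(g) · effect_log2 · dose-multiplier · time-multiplier, fixed
per gene (not resampled per sample) so the ground truth is exact and the
mean-difference fold change is unbiased for it. Defaults: 10,000 genes,
cohorts of 3, noise 0.5 log2 units, dose multipliers 1.0/1.5, time
multipliers 1.0/1.5, planted effect 2.0 log2 units with an 80%-positive
direction mix (perturbed modules are predominantly upregulated, as is
typical of injury-response modules). Per-condition sample counts are not
published for the emulated design; n = 3 follows its in vivo arm and is
configurable.

What the generator does *not* emulate: count noise (a negative-binomial
mode is a possible extension; the additive-Gaussian model is the
simplest under which the fold-change estimator is unbiased), library-size
or batch effects, gene–gene correlation beyond the planted modules, and
dose–response saturation. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under a clean model —
not that any particular biological dataset will reproduce published
values.

## Validation experiments and problem sizes

`toxmod.validation` (exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs:

* **Published-table correlation** — the bundled 8-module × 8-condition
  published z-score table; in vivo 33h-HD vs in vitro 24h-HD gives
  R² = 0.31 after 2-decimal rounding. This is the repository's one exact
  numerical link to published results; every other published number
  (DEG counts, individual z-scores, enrichment p-values) depends on the
  deposited sequencing data, proprietary module memberships or versioned
  annotation databases and is out of reach by design.
* **Null calibration** — 100 random 50-gene modules on a no-effect
  5000-gene profile (3v3, noise 0.5), N = 10,000: empirical p < 0.05 and
  z > 2 rates near the nominal 5%.
* **Planted recovery** — 100 replicates, one planted module
  (effect 2.0, multiplier 1) and one null module each: activation power
  and false-call count.
* **Monte-Carlo vs exhaustive** — 20 random universes of 8–15 genes:
  max |Δz| between N = 10,000 sampling and full enumeration.
* **DE calibration** — KS distance of null p-values from uniform at
  5000 genes; BH vs an independently coded step-up on 1000 random
  vectors.
* **Dose monotonicity** — 50 replicates of a 4000-gene two-dose design
  (multipliers 1.0/1.5, five planted modules): fractions of replicates
  with more DEGs and higher planted-module z at the high dose.
* **Determinism** — the full pipeline run twice on a 1000-gene synthetic
  experiment (N = 2000 resamples; determinism is independent of N):
  byte-compared outputs.

Problem sizes were chosen so the whole battery completes in about a
minute while keeping every statistical band comfortably estimable.

## Design choices and limitations

* The AAFC aggregation form (mean) and the subset-resampling reading of
  the null ("randomly selected fold-change values") are the two places
  where published descriptions admit alternatives (sum-aggregation;
  value-resampling with replacement). Both alternatives change scores
  but not z materially; the implemented choices are recorded here and in
  the permutation section above.
* Gene identifiers are opaque case-folded strings; no ortholog mapping.
  Cross-species comparison operates on module-score vectors over a shared
  module vocabulary, dropping non-shared modules with a warning.
* The common-gene operation implements the strict all-sets intersection;
  per-platform unions first are an easy caller-side variant.
* Fold-change PCA centres but does not scale features; both the
  embedding and the silhouette depend on this convention.
* The bundled score table is the only data file; all other fixtures are
  generated programmatically at test time.
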