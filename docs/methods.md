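# Methods

## Model and procedure

### Signed-rank reference profiles

Raw inputs are per-instance expression vectors (probes × instances) plus
instance metadata with plate assignments and a control flag. For every
non-control instance the differential expression is computed against the
per-probe **mean** of the same-plate controls, then converted to signed ranks:
absolute rank *i* for the *i*-th smallest |differential| (largest gets *N*),
carrying the differential's sign. Controls are consumed during construction
and never stored.

Conventions, fixed for reproducibility:

* **Control aggregation** is the mean by default (`control_aggregate="median"`
  is available). The mean is the minimal-assumption default; the choice is
  isolated inside `differential_profile`.
* **Ties in |d|** (including multiple zeros) are broken by ascending probe
  index via a stable sort, so every profile is an exact signed permutation of
  1..*N* — required for the closed-form score denominator. Average-rank
  fractions would be marginally less biased under heavy ties but break the
  permutation invariant and exact integer arithmetic.
* **sign(0) = +**. A zero differential lands in the lowest ranks where its
  contribution is negligible either way.
* Compound-list filtering matches perturbagen names exactly; case folding is
  opt-in to avoid silently merging distinct labels.

### Connection scores and set aggregation

For signature probes *g₁..gₘ* with directions *s*(*gᵢ*) = ±1:

c(**R**, **s**) = Σᵢ R(gᵢ)s(gᵢ) / Σᵢ₌₁..ₘ (N − i + 1).

The numerator is an exact integer (int64); the single float division makes
every instance score exactly a ratio of integers, so scores are bit-exact
reproducible and the brute-force oracle comparison in the tests can assert
`==` rather than approximate equality.

The treatment-set score is the **median** of member instance scores; for even
set sizes, the mean of the two middle values (preserving the exact
antisymmetry c(flip(s)) = −c(s) at set level). Grouping modes: by drug, or by
drug × cell line; an empty cell-line string is its own category.

### Null model and p-values

Per treatment set, `n_random` (default **2000**) random signatures matching
the query's (m_up, m_down) split are drawn uniformly without replacement from
the database's full probe universe, each is set-scored, and the sample mean μ̂
and sd σ̂ (n−1 denominator) summarize the null. The two-sided p-value is the
normal tail mass

p = Φ̄((|c| − μ̂)/σ̂) + Φ((−|c| − μ̂)/σ̂),

computed with the error function via `scipy.stats.norm`. 2000 draws give
p-values whose dominant uncertainty is σ̂ estimation (δσ/σ ≈ 1/√(2n) ≈ 1.6%);
at the decision-relevant range p ≤ 0.05 this translates to ≤ 0.004 absolute
error on p, which the validation confirms against 10⁵ brute-force resamples.
The up/down split is preserved in the null because the score is
sign-sensitive; μ̂ is estimated rather than assumed zero (it is cheap and
guards against sign-imbalanced signatures on structured databases).

Degenerate nulls (σ̂ = 0, e.g. single-probe signatures on one-instance sets
with pathological data) return p = 1 if |c| ≤ |μ̂| else 0, with a warning;
the Z-score is ±∞ by sign. Significance uses the Bonferroni-style threshold
p ≤ α/n_sets (α = 0.05 default) — the expected count of false positive sets
is below α — with an optional positive/negative direction filter.

**Normality caveat.** The null set score is a median of normalized sums of m
bounded rank draws; for the m ≈ 30 signatures typical of this analysis it is
close to normal (the validation requires ≥ 90% of sets to pass a KS check at
p > 0.01, and observes ~100% on Gaussian synthetic data). Very small m (≤ 3)
makes the instance-score lattice coarse and the approximation degrades;
p-values for such signatures should be treated as indicative.

### Contribution fractions

The diminished score c\*ₖ removes probe *k*'s term from the numerator but
keeps the full denominator, so c − c\*ₖ = R(k)s(k)/denominator identically.
CFₖ = 1 − median(c\*ₖ)/median(c), with both medians over the set's instances;
CF\*ₖ divides by the (positive) per-set maximum, pinning the top contributor
at exactly 1.0. Negative CFs (probes opposing the connection) keep their sign
after normalization — the normalization fixes the top of the scale, and
suppressing signs would discard the information that a probe fights the
connection. CF is computed only for sets passing the significance filter:
near-zero medians make the ratio unstable, and an exactly zero median set
score is an error. For single-instance sets the algebra gives
CFₖ = R(k)s(k)/(c·denominator) and Σₖ CFₖ = 1 exactly; medians break the sum
rule for larger sets.

### Determinism contract

Every stochastic step takes an explicit seed. Per-set substreams are spawned
from the master `SeedSequence` in sorted-set-key order, so results are
independent of evaluation order and the per-set work is freely parallelizable
without changing a single output byte; the CLI requires a seed in the run
config (no wall-clock default). Random signatures are drawn in vectorized
batches (argpartition of uniform keys — a uniform ordered sample without
replacement), equivalent in distribution to drawing one signature at a time.

## The synthetic-data generator

`synthetic` emulates the structure that matters to the pipeline, at desk
scale:

* **Probe universe**: N = 978 by default (the landmark-gene count of the
  L1000 assay, the directly measured part of such collections).
* **Plates**: treated instances fill plates sequentially (small treatment
  sets stay co-plated, as in real layouts); every plate carries its own
  vehicle controls, whose finite count couples co-plated profiles through the
  shared control baseline.
* **Noise**: per-instance Gaussian, or multivariate Student-t for a finite
  `noise_df` — one scale factor √(df/χ²_df) per instance shared across
  probes. This is deliberate: for *any* iid symmetric probe-wise noise the
  signed-rank transform yields a uniform signed permutation, so marginal tail
  weight is invisible downstream. Instance-level scale mixing is the minimal
  mechanism by which heavy tails survive ranking, and it is also what bad
  replicates look like: whole-instance outliers.
* **Characteristic response profiles** (`profile_sd`): each perturbagen can
  carry a reproducible transcriptome-wide response shared by its replicate
  instances (seeded separately via `profile_seed` so reruns can redraw noise
  while keeping perturbagen identities fixed). This makes set members
  correlated the way real treatment sets are; direction-random, so such sets
  remain null with respect to any query.
* **Planted effects**: mimics add `effect_size` to the companion query's
  up-probes and subtract it from the down-probes; reversers do the opposite;
  a truth table records the roles. Effect 5 (in noise-sd units) makes the
  signature probes dominate the top ranks, giving set scores near ±1.

What the generator does **not** emulate: probe–probe correlation induced by
upstream expression inference (real collections infer most probes from the
landmark genes, creating large correlated blocks), dose–response and
time-course structure, cell-line-specific baselines, and real biological
covariance. Passing tests therefore demonstrate the correctness and
calibration of the *algorithms* under controlled conditions, not performance
claims on any real reference collection.

## The skewness diagnostic and the case for the median

`skew_landscape` supports two readings of "per-set score skewness":

* `within_set` (default): Pearson's moment skewness (m₃/m₂^1.5, population
  moments) of the member *instance* scores within each set of size ≥ 3, under
  random signatures. This is the distribution whose asymmetry justifies
  aggregating instances by median rather than mean.
* `across_signatures`: skewness of the *set score* over random signatures —
  the distribution the normal null approximates. A normalized sum of m
  bounded rank draws (then a median), it is structurally near-symmetric:
  its skewness is O(1/√N) for any noise model, and the tests assert |γ| stays
  small. Exceedances of γ = 1 under this reading are not attainable, which is
  why the within-set reading is the default diagnostic.

On heavy-tailed synthetic data (profile_sd = 4, noise_df = 3) the fraction of
(set, signature) pairs at sizes 3–50 with within-set γ > 1 runs ≈ 3× the
Gaussian-noise fraction at matched sizes (≈ 0.09 vs ≈ 0.03 in the validation
runs) — correlated replicates plus straggler instances create exactly the
asymmetric within-set score distributions the median resists.

The rerun-stability comparison is conditioned on **signal-bearing** sets
(planted mimics under t₃ noise): there a straggler replicate displaces the
mean by O(set score) but leaves the median nearly untouched, and the observed
across-rerun variance of the median runs at ~0.4–0.6× that of the mean. On
pure-null sets the ordering reverses — scores are rank-bounded, so there are
no heavy tails for the median to resist and it pays the usual ~π/2 efficiency
cost. The aggregation choice is about the sets one acts on, which are the
significant ones.

## Problem sizes used in the validation suite

Chosen to give the statistical checks real resolution while keeping the whole
suite desk-scale: 20 sets × 10⁵ brute-force signatures for the erf-vs-resampling
comparison (evaluated at true p ∈ {0.002, 0.01, 0.05}, the regime where
p-values drive Bonferroni decisions; at p ≳ 0.2 the σ̂-estimation noise of a
2000-draw null alone exceeds the comparison's resolution); 200 null sets at
n_random = 2000 for type-I calibration (±3 binomial SE band); 64 sets × 4000
draws for the KS normality check; 36 sets × 50 random signatures per noise
model for the skew landscape; 8 planted sets × 15 reruns for the aggregation
stability comparison. `scripts/acceptance.py` re-runs the same studies at
slightly reduced Monte-Carlo depth.

## Known limitations

* The normal null is an approximation; it is validated here for m ≈ 30
  signatures and set sizes 1–50 on synthetic data, not guaranteed for extreme
  signature sizes or strongly structured real databases.
* CF is undefined at zero median set score and unstable near it; the
  significance gate is the guard, not a fix.
* The Bonferroni criterion is conservative when connections are correlated
  across cell lines of the same drug; no FDR procedure is provided.
* Probe identifiers are matched as exact strings end to end; any platform
  mapping (gene symbol ↔ probe) is upstream of this package.
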