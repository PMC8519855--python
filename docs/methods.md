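# Methods

## The statistic and its null

For subjects `i = 1..n` with aligned maps `X_i, Y_i ∈ R^V`, the test asks
whether within-subject intermodal similarity exceeds between-subject
similarity. The statistic is the mean within-subject similarity
`A0 = (1/n) Σ_i ψ(X_i, Y_i)` with `ψ` the sample Pearson correlation
across masked-in locations (Spearman with average-rank ties as the
rank-based alternative). Under the null — `ψ(X_i, Y_i)` equal in
distribution to `ψ(X_i, Y_j)` for `i ≠ j` — subjects are exchangeable with
respect to the pairing of modalities, so shuffling the Y maps across
subjects generates valid null draws `A_k`. The p-value

    p = (1 + #{k : |A0| ≤ |A_k|}) / (K + 1)

includes the identity permutation as the always-counted term, which keeps
the estimator valid (never anti-conservative in expectation) and bounds p
below by `1/(K+1)`. Ties count toward the numerator; tie detection is
exact floating-point equality, appropriate because ties arise structurally
(the identity ordering being re-drawn by chance), not numerically —
permutation statistics are computed by one shared code path so identical
orderings produce identical floats.

The default is two-sided (`|·|` on both sides); a one-sided `greater`
option serves the directional question "is within-subject similarity
*higher*?". Permutations are sampled uniformly with replacement from all
`n!` row orders; no derangement restriction is imposed. The exactness
argument needs only exchangeability across subjects — independent
subjects, no distributional assumption on the maps, and in particular no
assumption about spatial autocorrelation within a map.

### Computation

Every permutation statistic is an average of entries of the n × n
cross-similarity matrix `C[i, j] = ψ(X_i, Y_j)`. The implementation
row-standardizes both matrices once (rank-transforming first for
Spearman), forms `C` with a single matrix product, and scores each
permutation as a gather — mathematically identical to re-scoring each
permuted dataset, and what makes thousand-replicate simulation cells run
in seconds. Degenerate inputs (a zero-variance row, non-finite values
inside the mask, fewer than 3 masked-in locations) are rejected up front
with the offending subject named; they are never silently dropped, since
dropping locations per subject would compare modalities over different
location sets.

## Simulation model

Subject-level maps are generated from population mean maps `M1, M2` as

    X_i = a_i · M1 + E_i1,    Y_i = a_i · M2 + E_i2,

with `a_i ~ N(1, σ_a²)` drawn once per subject and shared across
modalities, and `E_i1, E_i2` i.i.d. `N(0, σ_e²)` per location. The mean of
`a_i` is 1, not 0: subject maps scatter around the population mean map,
and `σ_a² = 0` collapses every `a_i` to 1, making within- and
between-subject similarity identically distributed — the exact null. With
`σ_a² > 0` the shared coefficient couples a subject's two maps through the
(correlated) mean maps, and power increases with `σ_a²`, `n`, `|ρ|`, and
decreasing `σ_e²`.

One subtlety: because *both* maps scale by the same `a_i`, the
within-subject correlation in the noise-free limit is `ρ` for every
`a_i ≠ 0` — Pearson correlation is invariant to a common rescaling even
when negative. What distinguishes within from between pairs is that a
between-pair `(a_i M1, a_j M2)` has correlation attenuated and spread by
the independent magnitudes of `a_i, a_j`, so the permutation distribution
of the mean statistic widens around a different center. At small n a
single near-zero or negative `a_i` visibly fattens the null; this is real
behavior of the model, and it is why the packaged example fixture uses
n = 30 rather than a handful of subjects.

### Synthetic mean maps

The operating characteristics depend on the mean maps only through V and
their cross-correlation, so `make_mean_maps` synthesizes them rather than
requiring cohort data: two Gaussian vectors (optionally smoothed along a
1-D lattice with kernel scale `smoothness`, to mimic spatial
autocorrelation) are standardized to zero mean and unit variance, the
second is residualized against the first, and the pair is rotated so the
*empirical* correlation equals the target exactly (to ~1e-15, validated
at 1e-12 on construction). Defaults emulate the cortical
thickness–sulcal depth pairing (ρ = −0.15); ρ = −0.04 mirrors a
thickness–task-activation pairing. Maps are standardized because the test
statistic is scale-free; only V and ρ matter.

What the generator does **not** emulate: cortical mesh geometry, spatially
heteroscedastic or autocorrelated noise, vertex-level covariates, or
site/age structure. Passing simulations therefore validate calibration and
power of the *test* under exchangeable subjects, not robustness to those
real-data features (the test's validity argument does not rest on them,
but effect sizes in real cohorts will differ).

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| K | permutations per test | 999 | conventional; p-floor 0.001 |
| measure | similarity ψ | pearson | standard in correspondence work |
| sidedness | tail(s) | two_sided | magnitude comparison of the estimator |
| α | nominal level | 0.05 | convention |
| ρ target | mean-map correlation | −0.15 | thickness vs sulcal depth scale |
| V | locations (simulation) | 500 | desk-scale; 10,242 (one-hemisphere atlas resolution) available |
| σ_e² | noise variance | {0.5, 1.5, 3.0, 6.0} grid | spans high to low signal-to-noise |
| σ_a² | signal variance | 0–3 grid | 0 is the exact null |
| n | subjects | {25, 50, 100} grid | small to moderate cohort sizes |
| replicates | per grid cell | 500–1,000 | Monte-Carlo SE ≤ ~0.016 at rates near 5% |

Replicate counts of 500–1,000 (and 2,000 for the uniformity check) keep
each cell's binomial standard error small relative to the effects checked
while letting the whole grid run on a laptop; the test suite's assertions
carry explicit Monte-Carlo tolerances (3 standard errors, or a 99%
binomial interval) so they are statements about the method, not about a
particular seed.

## Seeding and reproducibility

Every stochastic entry point takes one integer seed. Derived streams are
spawned with `numpy.random.SeedSequence(master, spawn_key=...)` and
reduced mod 2³¹ so they can be logged and replayed:

* replicate r of a simulation study → `spawn_key=(r,)`, yielding a
  (simulation seed, permutation seed) pair — any replicate can be re-run
  in isolation (`replicate_seed_pair`);
* grid cell c → `spawn_key=(1, c)`;
* region with label L → `spawn_key=(L,)` (`region_seed`), so a
  whole-surface "region" reproduces the global test bitwise given the
  derived seed, and regions can be run selectively.

Permutations are materialized as `argsort` of i.i.d. uniforms, a standard
uniform-permutation construction that makes the serial stream independent
of any batching.

## Region-stratified testing and multiplicity

`spice_by_region` restricts both modalities to each region's locations
(intersected with any dataset mask), requires at least 3 locations (else
the region is reported as *skipped*, never silently dropped), and runs the
global test per region. Bonferroni control is applied in threshold form —
raw p-values are reported next to `α/m` at full precision (e.g.
0.05/16 = 0.003125; rounding is display-only) — because the attainable
p-value lattice of a permutation test makes p-value inflation misleading.
The comparison count m is the caller's declaration (`--m-comparisons`),
defaulting to the number of regions actually tested: which tests form one
family is a study-design choice, not something the package can infer.

## Numerical choices and edge cases

* Correlations are computed from z-scored vectors and clipped to
  [−1, 1] to absorb last-ulp overshoot; |A0| ≤ 1 is enforced as a result
  invariant.
* Masks: a single location mask applies to both modalities (correlation
  must be computed over a common location set); per-modality masks should
  be intersected by the caller before assembly.
* n = 2 is allowed: only two distinct relabelings exist, so attainable
  p-values are severely limited, but the result remains valid.
* With strict `p < α` rejection and K permutations, the attainable
  rejection probability under the null is `floor(α(K+1))/(K+1)` (e.g.
  0.045 at K = 199, α = 0.05) — the familiar slight conservatism of
  discrete permutation p-values, visible in type-I error estimates.
* GIFTI and FreeSurfer curv store 32-bit floats; round-trips are exact
  only to single precision. File order defines location identity; no
  resampling between surface spaces is attempted.

## Known limitations

* Exchangeability is assumed across all subjects; family structure,
  site blocks, or repeated sessions would call for restricted (block)
  permutations, which are not implemented.
* The similarity menu is Pearson/Spearman; distribution-level comparisons
  (e.g. Kolmogorov–Smirnov between map histograms) are out of scope.
* Volumetric (voxel) inputs and surface resampling are out of scope; maps
  must arrive vertex-aligned in a common space.
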