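# Methods

## Model and procedure

`craniofcm` clusters an n × m table of continuous measurements (specimens
× interlandmark distances, mm) into c fuzzy groups. The membership matrix
U is (c, n) with columns summing to 1, entries in [0, 1] and every row
mass strictly inside (0, n); these three constraints are enforced after
every update (tolerance 1e−9 on column sums, chosen because repeated
floating-point renormalization cannot hold sums exactly).

The objective is

    J_s(U, V) = Σ_i Σ_k u_ik^s · (1/w_ik)^β · D_ik

with three ingredients:

- **Fuzzifier s > 1** controls membership softness; s → 1 approaches crisp
  k-means, large s blurs all memberships toward uniform. Default 2, the
  standard choice for which the update formulas take their simplest form.
- **Influence weighting.** w_ik = u_ik / Σ_k u_ik is specimen k's share of
  cluster i's membership mass (rows of W sum to 1). The factor
  (1/w_ik)^β with influence factor β rescales squared distances:
  β = 0 is neutral, β > 0 polarizes (weakly attached specimens are pushed
  out, strongly attached pulled in), β < 0 does the reverse. Default 0.5.
  W is recomputed once per outer iteration from the previous U and held
  fixed through the membership/centre updates of that iteration. Because
  the share of a crisp non-member is 0 and the weighting is singular
  there, w is floored at 1e−12 before the reciprocal power.
- **Multiple-kernel distance.** D_ik = K\*(x,x) + K\*(v,v) − 2 K\*(x,v) for
  a convex kernel mixture K\*. The default is two Gaussians, widths 30 and
  110 with weights 0.9/0.1 — a narrow kernel resolving within-class
  structure and a wide one preserving global geometry, both on the mm
  scale of raw craniometric data (which is why z-scoring is off by
  default and opt-in). For all-Gaussian mixtures D = 2 − 2K\* ∈ [0, 2).
  The hyperbolic-tangent family is provided but is not Mercer for most
  parameters; its induced "squared distance" can go negative and is
  clamped at 0 with a warning.

The fit alternates: initial U is uniform-random column-normalized
(seeded); initial centres are the plain-FCM fuzzified means; then each
iteration refreshes W, updates U, updates centres by the kernel-weighted
mean

    v_i = Σ_k u_ik^s K*(x_k, v_i) x_k / Σ_k u_ik^s K*(x_k, v_i)

evaluated at the previous centres (a single fixed-point evaluation per
iteration, matching standard kernel-FCM practice; the denominator is
floored at 1e−300 against Gaussian underflow), and stops when the
objective changes by less than ε (default 1e−5) or at max_iter
(default 300; non-convergence is flagged on the result, not raised).

### Membership-update modes

The closed-form kernel-FCM membership update
u_ik ∝ (1 − K\*(x_k, v_i))^{−1/(s−1)} does not contain the influence
weights, so it is not the minimizer of the weighted objective above. The
package exposes both resolutions of this tension:

- `objective_consistent` (default): u_ik ∝ ((1/w_ik)^β D_ik)^{−1/(s−1)},
  the exact Lagrangian minimizer of J_s at fixed W and V. The U-half-step
  is then guaranteed non-increasing in J_s, and the implementation
  asserts this every iteration. (For all-Gaussian mixtures, using D
  rather than 1 − K\* only changes a constant factor 2 that cancels in
  the column normalization.)
- `closed_form`: the unweighted closed form; W then influences the fit
  only through the stopping objective. Useful for comparison with plain
  kernel FCM.

Full-loop trajectories are recorded in the result so that
non-monotonicity introduced by the W refresh (which changes the objective
itself between iterations) is observable rather than hidden. A specimen
coinciding with a centre (zero cost) receives crisp membership there,
split uniformly over coinciding centres. Hard labels are the column
argmax, ties broken toward the lowest cluster index for determinism.

## Evaluation

Anonymous clusters are aligned to labels by exhaustive enumeration of
cluster→label bijections (exact, supported up to 8 clusters), maximizing
overall accuracy with ties broken toward the lexicographically smallest
mapping. Binary reports define the male class as positive: TPR = male
recall, TNR = female recall, ACC = overall proportion correct, all in
percent; accuracy is by construction the class-size-weighted mean of the
two recalls. The stability protocol repeats the fit n_reps times with
per-run seeds master_seed + run_index, records each run's aligned
accuracy (failures are recorded per run, not fatal) and summarizes
min/mean/max; a zero max−min spread means every initialization reached
the same partition quality.

## Synthetic data generator

`generate_dimorphic` draws two multivariate-normal classes over m
features: configurable class sizes (default 100 female / 86 male),
per-feature female means (default spread over 22–175 mm, the range of
typical interlandmark distances), shared within-class standard deviations
(default 2–7 mm), male means offset by a per-feature effect size in sd
units, and a single equicorrelation shared by all feature pairs (default
0.1; positive definite for 0 ≤ ρ < 1). Sampling is bitwise reproducible
per seed.

The default effect size is 3 sd on every feature — a cleanly separable
regime chosen deliberately as *calibration infrastructure*: with known
ground truth and essentially zero Bayes error, any failure to recover the
labels, or any seed-to-seed variation, indicts the optimizer rather than
the data. Real craniometric sexual dimorphism is far weaker (individual
measurements typically overlap at 0.5–2 sd), the equicorrelation model
ignores the block structure of real measurement covariance, and the
Gaussian form ignores asymmetry and measurement error. Passing the
recovery and stability tests therefore demonstrates correctness and
determinism of the algorithm, not expected field accuracy on real skull
tables; the overlap regime can be explored by lowering `effect_size` (at
0 the aligned accuracy collapses to chance, which the tests also check).

## Numerical and design notes

- All randomness flows through one explicit integer seed per fit
  (numpy `default_rng`); the random initial memberships are drawn as a
  (c, n) uniform block and column-normalized, since an un-normalized
  draw would violate the partition constraints.
- The worked three-sample fixture treats the weighted distance as a
  *squared* quantity; the headline values 1.46 and 13.69 are its square
  roots for samples a and c at β = 1. The analogous value for sample b
  under the same convention is √(15/6 · 4) ≈ 3.16.
- Kernel mixture weights and the influence factor are distinct
  parameters throughout (the kernel weights are the mixture
  probabilities p_j; β always denotes the influence factor).
- Kernel specs serialize to strings
  (`gaussian:sigma=30,weight=0.9;gaussian:sigma=110,weight=0.1`) that
  round-trip losslessly through `parse_spec`/`format_spec`.

## Known limitations

- The weighted objective is not guaranteed to decrease across *whole*
  iterations (the W refresh and the fixed-point centre step both sit
  outside the descent argument); in practice trajectories on separable
  data decrease monotonically after the first few iterations.
- Reported accuracies for this family of algorithms on the Iris
  benchmark vary with implementation details. Here the plain-FCM
  baseline gives the canonical 89.33% (16/150 misassigned), and the
  multi-kernel fit at s = 2, β = 0.5, Gaussian widths (3, 0.5) and
  weights (0.7, 0.3) reaches 90.7% (objective-consistent mode) to 91.3%
  (closed-form mode) — an improvement over the baseline, but figures as high
  as 96% sometimes quoted for comparable configurations were not
  reproducible from these update rules at these parameters (a parameter
  sweep over widths 0.3–8, weights 0.5–0.9 and β ∈ [−0.5, 1] tops out
  near 94.7%).
- Exhaustive alignment is exponential in the cluster count and capped at
  8 clusters; the intended use is binary sexing.
- No missing-data handling: tables with missing measurements are
  rejected at load time.
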