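# Methods

This note documents the models, statistics, numerical choices and known
limitations behind `layerprint`. It is written for users who want to know
exactly what the code computes and what the synthetic-data validation does
and does not establish.

## Representational similarity and the synthesis objective

For an image set of size `n` and a network layer with `u` units, the
first-order RSM is the `n × n` matrix of Pearson correlations between the
flattened unit-activation patterns of every image pair. Activations are
flattened channel-major and no spatial pooling is applied before
correlating. Zero-variance patterns raise an error rather than propagating
NaN; during synthesis such a degeneracy triggers a logged restart from
fresh noise (bounded by `max_restarts`).

Each RSM is vectorized as its strict upper triangle in row-major order —
a format guarantee, since every downstream regression consumes these
vectors — giving a length `n(n−1)/2` vector. The second-order matrix `R`
correlates these vectors across layers, and the synthesis cost is
`Σ_{i≠j} R_ij²`. The unit diagonal is excluded: it would contribute a
constant `L` with zero gradient, and excluding it makes 0 mean "perfectly
orthogonalized".

### Gradients

The cost is differentiated analytically down to pixels. Writing
`ρ = corr(u, v)` with centered vectors `u_c, v_c` and unit versions
`û = u_c/‖u_c‖`, the Pearson gradient is `∂ρ/∂u = (v̂ − ρ û)/‖u_c‖`; it is
applied twice — once across layers (triangle vectors) and once across
images (activation patterns) — and the resulting activation cotangents are
pulled back through the network by the adapter's vector-Jacobian product.
The whole chain is validated against central finite differences in the
test-suite to relative error below 1e−6.

### Two phases

Phase 1 (diversification) performs gradient ascent, per image, on the mean
activation of one assigned feature channel, plus a penalty encouraging a
broad RGB distribution. The penalty is the negative mean per-channel pixel
standard deviation (weight `rgb_breadth_weight`, default 0.1) — the
simplest differentiable surrogate for "broad distribution", kept behind a
pluggable interface. Channel objectives use the channel *mean*; target
channels are drawn per image (distinct where possible) by seeded sampling
from a configured layer, defaulting to the deepest.

Phase 2 (orthogonalization) jointly updates all images by plain
fixed-step-size gradient descent on the cost, clamping pixels to the
declared range after every step. Optimization is in raw pixel space (no
Fourier or decorrelated parameterization). The trace records the cost
after each update, so its last entry equals the final image set's cost.

Diversification is not cosmetic. On statistically exchangeable noise
images, RSM triangles are nearly constant, and an orthogonalizer can reach
zero cost by decorrelating numerically tiny fluctuations — geometry too
weak to survive any measurement noise. Phase 1 is what puts recoverable
variance into the triangles. Relatedly, the built-in test CNN centers its
inputs (offset 0.5) and has zero biases: with raw `[0, 1]` inputs every
unit carries a shared baseline that pins all pattern correlations near one
constant, degrading every downstream analysis.

### Profiles

The full-scale protocol is 16 images at 224 × 224 with 28,800
diversification and 1,800 orthogonalization iterations on Inception-V1.
Desk scale, used throughout the tests on the seeded 3-layer NumPy CNN at
64 × 64 with 8 images: 200 + 200 iterations at step 0.05 for
orthogonalization-efficacy checks, and a *structured* profile — 2,000
diversification iterations at step 0.5 + 300 orthogonalization iterations
— wherever recoverable geometry is needed (ground-truth recovery,
calibration of the mapping statistics). At 200 desk iterations the images
remain so similar that triangle standard deviations stay below ~0.02,
under the searchlight correlation-estimation noise floor (~`1/√k` for `k`
voxels), which would make embedded geometry unrecoverable at any
signal-to-noise ratio; the longer profile is the desk analogue of the
full protocol's 28,800-iteration phase.

## Design and GLM

Trial sequences present each of `n_images` images exactly `n_reps` times
(default 16 × 5 = 80), never back-to-back, with inter-stimulus intervals
drawn uniformly from {1.5, 3, 4.5} s after a 1.5 s stimulus; 10% of trials
(rounded up) are flagged as behavioral targets and modeled as ordinary
presentations of their image. The order is built sequentially with
probability proportional to remaining presentation counts (excluding the
previous image); dead ends restart, and infeasible constraint sets fail
after bounded retries.

The HRF is the canonical difference of gamma densities — delays 6 s and
16 s, unit dispersions, undershoot ratio 1/6 — peak-normalized to 1 over a
dense grid; all five parameters are overridable. Note the analytic mode of
a shape-6 gamma is 5 s, so the normalized peak sits near 5 s. Regressors
are boxcars convolved with the HRF at 0.05 s resolution and sampled at
`t = volume_index × TR` (TR 1.5 s, 250 volumes per run; no slice-timing
offsets). Betas are ordinary least squares per voxel with an intercept
nuisance column; rank deficiency raises an error naming the collinear
regressors. High-pass filtering, prewhitening and motion regressors are
deliberately out of scope: the synthetic pipeline generates drift-free
white-noise data by default, with optional AR(1) noise for robustness
tests only.

## Ground-truth simulator

`embed_rsm` draws voxel columns i.i.d. from `N(0, Σ)` with `Σ` equal to the
target RSM (symmetrized; eigenvalues floored at zero within numerical
noise, genuinely non-PSD inputs rejected), so the expected image-by-image
correlation matrix equals the target exactly. Regions are disjoint voxel
sets, each carrying `signal_scale ×` an embedded pattern that is shared
across runs within a participant and jittered additively across
participants by `participant_sd` — shared geometry, idiosyncratic codes.
Everything else is i.i.d. Gaussian noise per run. Default conditions used
in validation: 16³ grid, two 7³ regions, `signal_scale/noise_sd = 2`,
`participant_sd = 0.2`, 6 participants × 2 runs. BOLD simulation composes
the design matrix with simulated betas plus optional (AR(1)) noise, so the
GLM recovers the betas exactly in the noiseless case.

What the simulator does *not* emulate: anatomical geometry, hemodynamic
nonlinearity, spatially correlated or physiological noise, and
between-participant anatomical misalignment. Passing tests therefore
establish the *statistical* correctness and calibration of the estimators
under the stated generative model, not their behavior on real scanner
data.

## Searchlight statistics

Searchlights are 7×7×7 cubes (half-width 3) around every in-mask voxel,
clipped at volume borders and intersected with the mask; centers with
fewer than 2 voxels are undefined (NaN), never zero-filled.

Stability: within-image similarity is the mean correlation of same-image
patterns over all unordered run pairs (`C(R,2)·n`, = 448 at 16 × 8);
between-image similarity uses ordered image pairs over unordered run pairs
(`C(R,2)·n·(n−1)`, = 6,720). The null is built by subsampling, without
replacement, exactly the data set's own within-count from the between
values and averaging, 5,000 times; the statistic is
`z = (within_mean − null_mean)/null_sd`. Participants with fewer runs use
their own counts, matching the number of values averaged into the within
estimate. Subsampling uses a vectorized random-key argpartition, and the
between values are put in canonical sorted order first so the seeded z is
exactly invariant to image relabeling and run order. Whole-brain maps
derive per-center seeds from `(master_seed, center_flat_index)`, making
maps independent of evaluation order.

Layer mapping: per searchlight, each participant's run-averaged RSM
triangle forms a row of a `(P, m)` matrix. For each held-out participant,
the training rows are averaged, a slope+intercept regression of that
average on the layer triangle is fit, and the fitted line evaluated at the
layer triangle is scored against the held-out row with out-of-sample
`R² = 1 − SS_res/SS_tot` — negative values are *not* clipped (clipping
would bias the null). The permutation null shuffles every participant's
triangle independently with a fresh shuffle per permutation (maximal
exchangeability; switchable to a shared shuffle), reruns the full LOPO
procedure 500 times, and stores the across-fold mean R². The calibrated
center-level statistic is `z_mean`, the observed across-fold mean against
this null (approximately standard normal under the null: over 200
simulations, mean −0.06, SD 0.94); per-participant z values against the
same null are exposed for per-participant maps and average exactly to
`z_mean`. Mapping is restricted to centers passing the stability mask.

Residual method: all triangles are z-scored; within each training fold the
averaged searchlight triangle is regressed (with intercept) on the other
layers' triangles, the target layer is fit to the training residuals by
simple regression, and the held-out triangle is residualized with the
*training-fold* coefficients before scoring — a fold-honest order that
prevents leakage from the held-out participant into the residualization.
Collinear predictors after z-scoring are rejected by name. With no other
layers, residualization reduces to the identity (up to z-scoring) and the
procedure equals the plain LOPO fit.

Group inference replaces external cluster-enhanced randomization tools
with a self-contained voxelwise sign-flip max-statistic FWE test: under
the sign-symmetry null, whole participant maps are negated at random 1,000
times, the maximum one-sample t across centers is recorded, and a center
is significant when its corrected (add-one) p falls below alpha,
one-tailed for positive effects. Zero-variance centers with positive mean
are treated as significant (t is unbounded there). This trades the cluster
sensitivity of threshold-free cluster enhancement for portability and
exact validity; per-participant z maps can be exported as 4-D NIfTI for
external cluster-based correction. Consolidated maps label each
significant center with the layer of largest group t, ties going to the
lowest layer index.

## Overlap

The overlap of base map M with N is `|M∩N|/|M|` over significant voxels —
asymmetric by construction. Layers with no significant voxels are
undefined and excluded from summary means entirely (as base *and* as
comparison; keeping their zero ratios as comparisons would drag means down
artificially). Mean overlap is computed over all off-diagonal entries or
the first off-diagonals only (22 entries at L = 12). Regime comparisons
bootstrap per-image-set means with replacement 5,000 times; p-values use
the add-one estimator (never exactly 0), one-tailed toward lower overlap
by default (the direction in which decorrelated stimuli are expected to
help), with a two-sided option.

## Validation summary and problem sizes

The test-suite and `scripts/acceptance.py` exercise, at desk scale chosen
to keep a full run in minutes on one CPU: the printed pairing
combinatorics (448/6,720) and overlap worked example (1.0/0.5); a
trial-sequence audit over 10,000 seeds (2,000 in the script); synthesis
efficacy against the 1st percentile of 100 random-noise baseline sets;
stability-z null coverage (|z| < 3) over 200 pure-noise simulations at
16 images × 8 runs × 50 voxels with 5,000 subsamples; absent-layer z
exceedance (~5% above 1.645) over 400 simulated centers at 6 participants;
ground-truth layer recovery over 20 simulated cohorts (perfect recovery in
the shipped conditions); and the residual-method orthogonality identities
(dot products below 1e−8; across-fold mean R² within 0.05 of zero when a
searchlight is fully explained by the other layers — the exactly-explained
case is degenerate, so 1e−3 per-participant noise keeps residuals
non-degenerate).

## Known limitations

- The built-in CNN is random (untrained); its "feature channels" are
  arbitrary filters, so desk-scale synthesized images are textures, not
  the vivid object-like images a trained Inception-V1 yields.
- Only cubic searchlights are provided (no spheres, surfaces, or
  cross-validated distances).
- The sign-flip group test is voxelwise; it has no cluster sensitivity.
- Out-of-sample R² with slope+intercept weights follows the most direct
  reading of the mapping procedure; correlation-based weighting variants
  are not implemented.
- Simulated noise is white by default; AR(1) is available but spatial
  noise correlation is not modeled.
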