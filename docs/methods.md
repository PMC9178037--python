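# Methods

This note documents the models, conventions and numerical choices behind
`shapelearn`, in the order the pipeline runs.

## Stimulus space

Shapes are closed contours whose radius is a sum of radial frequency
components (RFCs), `r(θ) = r0 (1 + Σ_j a_j s sin(f_j θ + φ_j))` with
seven components. A one-dimensional continuum is built by co-varying the
amplitudes of the 1.11, 1.54 and 4.94 cycles/revolution components over
(0–36, 0–36, 15.58–33.58); five equally spaced shapes are drawn from it.
A fourth component (3.18 cycles/revolution) carries the same/different
task "warp" and is disjoint from the continuum components, keeping the
task dimension orthogonal to the shape dimension.

Choices where the source parameterisation is under-determined: base
radius 1.0, global amplitude scale s = 0.01 (the printed amplitude units
are unrecoverable; only the ordinal/linear structure matters downstream),
all phases 0, and the three remaining components at amplitude 0 with
placeholder frequencies (2.12, 6.0, 9.09). Because several frequencies
are non-integer, `r(2π) ≠ r(0)` in general: contours are sampled on
[0, 2π) and the wrap-around seam is an inherited property of the
parameterisation, so closure is only asserted for integer-frequency
configurations. Decoding never touches rendered geometry — shapes enter
the analysis as abstract positions 1–5 on a circularised axis.

## Designs

Both experiments cross cue identity (2) x validity (75/25) x
same/different (2). Experiment 1 (16 blocks x 32 trials) realises the
full 16-cell crossing at every trial position across blocks; Experiment 2
(4 blocks x 128 trials) balances validity at every position (3 valid / 1
invalid across the four blocks) and cue x same/different over groups of
four positions, with the single invalid cell of each cue x task combo
placed on a distinct position. Warp signs are balanced within
cue x validity cells (to within one trial when a cell is odd-sized);
inter-trial intervals are uniform on [1.25, 4.25] s. All orderings are
seed-deterministic; marginal counts are seed-invariant.

Tone-sequence cues are permutations of {1..5} selected greedily to
minimise the maximum absolute Pearson correlation with the already
selected contours (ties lexicographic, starting from 1-2-3-4-5), offset
by starting tones cycling 1, 4, 7, 10 into a 14-tone set, and paired with
the inverted contour (c → 6 − c) at the same starting tone. This
construction reproduces the published example sequences exactly.

## Synthetic data generator

The generator mirrors the decoder's forward model: patterns are
`B = W·content + noise` with `W` (voxels x 5 channels) having standard
normal rows for informative voxels and zero rows otherwise, and i.i.d.
Gaussian noise. Shape-only trials carry the presented shape's channel
vector at unit gain. Prediction trials mix:

- a prediction gain `α(t)` on the cued shape (valid and invalid alike),
- a presented-stimulus baseline gain (default 0.2), and
- a prediction-error gain `ε(t)` on the presented shape, invalid trials
  only.

Both gains are sigmoids of trial position, scaled so the noiseless
valid-minus-invalid contrast equals
`error_amplitude·sig(t; error) + prediction_amplitude·sig(t; prediction)`
(the channel-overlap factor is 1 to within 2·10⁻⁵ at 72° spacing).
Defaults: error_amplitude −0.3 (midpoint at 1/4 of the block),
prediction_amplitude +0.4 (midpoint at 3/4), slopes 0.2 per trial for
128-trial blocks (rescaled by block length), noise SD 4 pattern units,
200 voxels of which 100 informative, N = 24 participants. With 100
informative voxels and unit-norm channel content, per-trial decoded
evidence noise is roughly 0.5–0.6 — single trials are nearly
undecodable, as in real data, and condition averages over windows carry
the signal.

For informational connectivity, two ROIs share a per-trial standard
normal latent scaled by a sigmoid coupling gain (amplitude 0.5, midpoint
at 3/4 of the block) added to both ROIs' presented-shape gain, so their
evidence co-fluctuates late but not early.

What the generator does **not** emulate: spatially or temporally
correlated noise (an i.i.d. field), haemodynamic nonlinearity, voxel
tuning correlations, model mismatch between encoder and decoder (the
generator uses the decoder's own basis, which is exactly what makes
oracle tests clean), head motion, or physiological confounds. Passing
tests therefore demonstrate the correctness and calibration of the
*analysis*, not that real hippocampal data would behave this way.

Optional BOLD synthesis builds a time series (TR = 1 s) as the
superposition of known per-trial betas times the HRF, for testing the
single-trial estimator.

## Single-trial estimation (LSS)

One GLM per trial: the trial of interest (delta at onset convolved with
the HRF, plus temporal derivative), all other trials combined into one
regressor (also with derivative — whether the original nuisance regressor
carried a derivative is ambiguous; both do here), optional user nuisance
columns, and an intercept. The double-gamma HRF uses the Glover form
`(t/d1)^(d1/b1) e^{-(t-d1)/b1} - c (t/d2)^(d2/b2) e^{-(t-d2)/b2}` with
peak 6 s, undershoot 16 s, dispersions 1 s, ratio 1/6, 32 s support,
peak-normalised; the derivative is a central finite difference
(δ = 0.01 s). With non-overlapping events LSS recovers noiseless betas
exactly; with overlapping responses and heterogeneous neighbouring betas
it is the standard approximation. Rank-deficient designs raise an error
naming the collinear columns.

## Decoder conventions

Five channels sit 72° apart on a 360° circularised shape axis, shape i
centred on channel i; basis value `max(0, cos Δ)^5`; dense grid 1°.
Channel values below 10⁻¹² are snapped to zero so the rectification
boundary (90°) is exact. `C_train` has one column per shape condition
(each shape's position passed through the basis); shape-only trials are
averaged per shape before the weight regression. Evidence is the tuning
curve evaluated at the two shape positions (point evaluation) and
differenced, positive = presented shape.

Voxel selection ranks voxels by the standard deviation of their channel
weights (fit on both shape-only runs), then scores nested fractions
10%–100% by mean shapes-2/4 evidence, training on one run and testing on
the other, both directions averaged; ties go to the smallest count. The
scorer reconstructs channels by least squares so that degenerate
candidate subsets score rather than fail, while the public
reconstruction API raises on rank deficiency with a pointer to voxel
selection. A "most active voxels" rule (default 500) is provided for
retinotopic regions where an activation statistic exists.

## Timecourses and fits

Windows slide over trial positions (length 4 for 32-trial blocks,
16 for 128-trial blocks), pooling trials across blocks; valid and
invalid trials are averaged separately; the predicted-shape contrast is
valid − invalid (an "average with complement" convention, differing by
the affine map x/2 + 1/2, is available behind a flag). Bins with no
invalid trials are missing, never zero. Smoothing is a truncated moving
average (half-width 4 → 9 bins, or 16 → 33 bins), applied after the
contrast; missing bins are skipped within each smoothing window and
dropped (not imputed) by downstream fits.

Sigmoid fits minimise the sum of squared residuals under box bounds
(A ∈ [−1, 1], k ∈ [0.01, 1], x0 within the block; for the two-sigmoid
model x0a in the first half, x0b in the second) by multistart L-BFGS-B
with analytic gradients: 100 uniform random starts within the box by
default, plus the box centre, seeded for reproducibility. The double fit
additionally seeds the best single-sigmoid solution (other amplitude 0),
which makes its residual never exceed the nested single fit's.
Conformance is defined against a dense grid-search oracle, not any
particular optimiser.

## Group statistics

Cluster-based permutation: per-bin one-sample t, two-tailed threshold at
α = 0.05 (critical t at the modal df when bins have missing values),
maximal same-sign supra-threshold runs summed, and a null of 10,000
per-participant sign flips (the exchangeability-preserving permutation
for a one-sample timecourse test) recording each permutation's maximum
absolute cluster sum — i.e. max-statistic familywise correction, with
add-one p-values bounded below by 1/(n_perm + 1). Missing bins break
adjacency. Monte-Carlo p-values agree with exhaustive sign-flip
enumeration (N = 8) to < 0.02, and the familywise error over 500 null
groups sits within [0.03, 0.08] at nominal 0.05.

Scalar tests are two-sided one-sample/paired t (df = N − 1) and one-way
repeated-measures F (df = (L − 1, (L − 1)(N − 1))), computed directly
and cross-checked against an independent implementation in the tests.

Connectivity correlates raw per-trial evidence within the same sliding
windows (not the smoothed bins), pools valid and invalid trials by
default, flags zero-variance windows as missing, and contrasts the last
window against the first by paired t; a Fisher-z option exists (off by
default). If every participant's contrast is exactly zero the t is
reported as 0 with p = 1 rather than failing on zero variance.

## Problem sizes used by the validation suites

Chosen so the whole validation runs in minutes on one core, and recorded
here as the package's own scaling decisions: switch-recovery power uses
50 replicate groups of N = 24 at the generator defaults with 20
multistarts per fit (the pipeline default stays 100); connectivity power
uses 200 replicate groups at 100 voxels / 50 informative without voxel
selection; cluster calibration uses 500 null groups of 24 x 29 bins at
the full 10,000 permutations. Measured on these conditions: switch
recovery ≈ 96% of groups, connectivity power ≈ 99%, familywise error
≈ 5–6%.

## Known limitations

- The generator and decoder share one linear model; none of the suites
  probe encoder–decoder mismatch (an AR(1)/nonlinearity hook is the
  natural extension point).
- Amplitude parameters of the two-sigmoid fit are weakly identified on
  windowed, smoothed data (amplitude trades off against midpoint and
  slope near the block edges); their *signs* and group-level tests are
  the robust quantities, and that is what the validation asserts.
- Anatomical structure is out of scope: ROIs are opaque labels; no
  NIfTI/volume handling, no preprocessing, no within-trial temporal
  dynamics.
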