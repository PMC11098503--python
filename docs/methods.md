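# Methods

This note records the models the package implements, the synthetic
world it is tested against, the numerical choices, and what the tests
do and do not establish.

## The synthetic world

The simulator emulates the statistical structure of a
stimulus–response study with chronically implanted arrays, not its
biology.  Its components:

**Latents.** z-latents are i.i.d. standard normal, truncated by
interpolation toward the latent mean, w' = μ + ψ(w − μ) with μ = 0 and
ψ = 0.7 by default.  ψ-interpolation (rather than coordinate clipping)
is the convention of style-based generators; it makes the
variance-contraction property exact (sample variance scales with ψ²),
which the tests exploit.  The toy z→w map is a fixed seeded orthogonal
mixing; the pipeline adds a strictly monotone elementwise bend
w = y + 0.25 y³ after mixing.  The bend matters: with a purely
orthogonal mixing the z- and w-Gram matrices coincide, so dual-ridge
encoders in the two spaces would be the same model and the w-vs-z
comparison vacuous.  With it, w carries structure that no linear
function of z reproduces, while the map stays bijective.

**Images.** The generator stand-in renders each latent as a sum of
isotropic Gaussian blobs on a 64 × 64 canvas; consecutive groups of
four latent dimensions set one blob's x, y, log-width and signed
amplitude (positions squashed through tanh into the canvas interior).
The renderer is deterministic and latent-disentangled by construction —
each dimension moves exactly one visual attribute — so
feature-disentanglement claims are testable.  The all-zero latent
renders a blank canvas (all amplitudes zero).

**Feature hierarchy.** Level k (k = 1..5) block-mean pools the image
with 2^k blocks and projects the flattened pooled map through a fixed
seeded Gaussian matrix to dimension min(p, max(p/8, 2^(6−k))) where p
is the pooled pixel count — 128, 32, 8, 4, 2 at 64 px.  Two properties
are deliberate: dimensions decrease strictly with level, and the
projection dimension stays below p at every level, so no level's
feature space linearly contains another's.  Without the second
property, coarse-level responses are exactly linear in fine-level
pooled maps (block means of block means) and the complexity-gradient
assignment would be unidentifiable in principle.

**Responses.** Channel c of region r responds at 1 ms bin t with
profile_r(t) · (features_r · weights_r)[c] + bias[c] + ε, ε i.i.d.
N(0, σ²) per (stimulus, repetition, channel, bin).  Temporal profiles
are onset-locked Gaussian bumps (sd 25 ms) peaking 75/100/125 ms after
onset for V1/V4/IT, zero before onset, unit peak.  Ground-truth weights
are Gaussian, rescaled per channel to unit signal sd over the training
stimuli, so σ is directly the per-bin noise-to-signal ratio.  No
trial-to-trial correlation is modelled — the simplest noise model
consistent with repetition averaging.  Default region drivers mirror
the complexity gradient: V1 ← level-1 features, V4 ← level-3, IT ← the
w-latents.

**Scale.** Default study conditions are 1000 training stimuli presented
once, 100 test stimuli presented 20 times, 32 latent dimensions and 96
channels (2 arrays × 16 per region).  These are the package's chosen
desk-scale problem sizes; the 15-array/960-channel/4000-stimulus layout
of the motivating recordings is retained in
`SyntheticConfig.recording_scale()` for structural counts (its response
tensors would occupy several GB and are never materialized).

## Preprocessing

Windows are half-open [start, end) in ms relative to stimulus onset
(25–125 V1, 50–150 V4, 75–175 IT), so a 100 ms window spans exactly 100
one-ms bins.  Repetitions are averaged after windowing (the two
operations commute; both orders are tested).  Channels are z-scored
with statistics of the training split only, applied unchanged to other
splits — pooled statistics would leak test information into the
decoder.  A zero-variance training channel is a hard error naming the
channel.

## Encoding

The ridge problem is solved in the N × N dual, α = (K + λI)⁻¹y with
K = Φ_c Φ_cᵀ; features and responses are mean-centered with training
statistics, which handles intercepts exactly.  At λ = 0 with a
rank-deficient kernel the minimum-norm solution is used (lstsq on the
kernel's nonzero modes): this is the λ→0 limit of the ridge path and
equals min-norm primal OLS.  The alternative — erroring on singular
systems — is unusable here because the dof grid's top point (dof =
rank) maps exactly to λ = 0 and cross-validation legitimately selects
it on nearly noiseless data.

The λ grid places M = 20 dof targets evenly in [1, rank Φ] (M
unspecified in the source analysis; 20 is dense enough for a smooth
path and costs nothing at these sizes).  Each target is inverted by
Newton's method on the strictly monotone dof curve, safeguarded by
bisection on [0, s²_max(rank/target − 1)] with the bracket doubled
until it contains the root; tolerance 1e-6 dof units.  Singular values
below 1e-10 of the largest are treated as zero when counting rank —
centering and near-collinear features otherwise inflate the rank with
noise modes and stall the inversion.

Cross-validation uses a seeded permutation split into k = 5 nearly
equal folds and pools validation MSE over the area's electrodes
(validation correlation is the other defensible criterion; MSE matches
the ridge objective).  Ties break to the smaller λ.  The per-fold grid
sweep reuses one eigendecomposition of the fold kernel, so the whole
grid costs little more than one fit.

Scoring is per-unit Pearson r on held-out stimuli; zero-variance
columns yield NaN rather than a silent 0.  Negative-r zeroing is a
reporting flag only and never enters model selection.  The critical
correlation converts the two-sided t critical value through
r = t/√(t² + df); the df convention follows the reported figures (df =
test-set size, 100 or 200), not n − 2 — at these sizes the difference
is in the fourth decimal.  Encoder banks are compared with a
pooled-variance two-sample t-test across units (df = n_a + n_b − 2,
hence t(1918) for two banks of 960).  Complexity assignment is the
per-unit argmax across candidate feature spaces, ties to the lowest
candidate index with a flag.

## Decoding and attribution

The decoder is OLS from all channels to every latent dimension, solved
by SVD pseudoinverse with rank tolerance 1e-10 · s_max (minimum-norm
when channels ≥ stimuli), intercept via centering.  Decoded latents are
not truncated.

Occlusion replaces the channels of the non-probed areas with their
per-channel mean over the test stimuli — a constant, information-free
placeholder at the channel's operating point.  The source description
("the average response of all but the corresponding response") is
ambiguous between averaging over stimuli, channels or both; the
per-channel stimulus mean is the choice that preserves each channel's
operating point, and attribution is invariant to channel order within
regions either way.  The 'all' row uses unoccluded responses.

Time-resolved decoding applies the same window to all channels (no
region offsets), z-scores with that window's training statistics, and
refits the decoder per window; a fixed-decoder variant is available via
`refit=False` (both behave similarly on synthetic data, as expected
when the response profile only rescales the signal).

## Evaluation

Latent similarity is the per-stimulus cosine between predicted and true
latents.  Perceptual similarity renders both latent sets with the toy
generator and compares whole-level flattened feature vectors per level
(no per-channel averaging — this matches a single sum over activation
elements).  The permutation null redraws complete latent sets from the
test distribution (ψ-truncated Gaussian through the same z→w map),
scores them against the true stimuli, and ranks the observed mean with
the add-one estimator p = (1 + #{null ≥ observed})/(1 + n_iter), which
cannot return 0.  The default 199 iterations resolves p down to 5e-3 in
seconds; raise `n_permutations` to 999+ when smaller p floors matter.

## What the tests show — and do not

With σ = 0 and full-rank drivers the pipeline recovers held-out latents
with cosine similarity 1 to 1e-6: the chain is information-lossless.
At σ = 0.5 recovery sits far above the permutation null's 99th
percentile, and encoding r falls strictly as σ grows through
{0, 0.5, 1, 2} when every region is driven by the encoded space itself.
That last qualifier matters: in the mixed-driver world, V1/V4 units
have a noise-independent misfit floor (their drivers are nonlinear in
the encoded latents) and window/repetition averaging shrinks per-bin
noise ~45-fold, so the σ-effect on mean r is of order 1e-4 and drowns
in realization jitter.  Units simulated from level-k features are
assigned level k for ≥ 90% of units at σ = 0.5 across seeds (~92–96%
observed).

None of this shows the analysis works on real MUA: the simulator has
Gaussian noise with no trial-to-trial or inter-channel correlation, no
adaptation or latency jitter, linear responses within a region, and a
feature hierarchy far poorer than a trained network.  What it does show
is that the machinery is correct: every estimator recovers the quantity
it claims to estimate when the generating assumptions hold, and the
significance machinery is calibrated (null-drawn predictions yield
approximately uniform p-values).

## Known limitations

* Electrode-wise λ is not supported (selection is per area, matching
  the analysis this reimplements).
* The permutation null resamples latents only; it does not model
  decoder refitting, so it tests "better than random content", not
  "better than a random decoder".
* `run_experiment` materializes the full trial-resolved tensor in
  memory; at the default scale that is ~250 MB, but paper-scale
  configurations should not be simulated directly.
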