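# Methods

This note documents the models, estimators and numerical choices behind
`dsmotion`, and what the synthetic-data experiments do and do not show.

## Stimulus model

All stimuli live on a screen model with 7.5 um pixels, 60 Hz refresh and
30 Hz stimulus updates (frame interval dt = 1/30 s ~ 33 ms). Luminance is
normalized to [0, 1] with gray at 0.5; the physical irradiance of the
emulated experiments (6.33 mW/m^2) is metadata only.

**Standard texture.** Binary black/white squares of 30 x 30 um (p = 0.5
each) are smoothed with an isotropic Gaussian of 60 um SD, the deviations
from the mean are scaled by 1.5, and values are clipped to [0, 1]
(smooth -> scale -> clip, in that order). After smoothing the pixel SD is
about 0.10, so the x1.5 scaling leaves values comfortably inside the
displayable range and clipping is a safeguard rather than a routine
event. Pink-noise textures are built in the Fourier domain with a 1/f
amplitude spectrum and standardized to the mean and SD of the paired
standard texture before clipping; arbitrary grayscale images are accepted
and standardized the same way.

**Motion trajectory.** Per frame and component, steps are i.i.d. Gaussian
with sigma = 22.5 um, rounded to multiples of the 7.5 um pixel raster.
The rounding rule is round-half-away-from-zero, fixed for
reproducibility. Rounding inflates the per-component step SD to
sqrt(sigma^2 + q^2/12) ~ 22.6 um; the summed displacement over one second
is therefore 2D Gaussian and its norm Rayleigh with mean
sqrt(30) * 22.6 * sqrt(pi/2) ~ 155 um — the "net drift per second"
statistic the acceptance script recomputes.

**Rendering.** Because steps are quantized to the pixel raster,
translating the texture is an exact integer pixel shift (no
interpolation). The renderer errors (naming the frame) if the trajectory
leaves the texture; textures must be generated large enough for the
planned duration. Frame 0 shows the unshifted texture; frame t the
cumulative shift of steps 1..t. The frame displayed during count bin t is
frame t — a half-frame convention that is irrelevant at the 150-200 ms
response latencies of interest.

**Probe stimuli.** Drifting square-wave gratings (600 um period, 0.75 Hz,
8 directions x 5 repeats, 6.67 s each with 1.67 s gray gaps),
checkerboard white noise (75 um squares at 30 Hz, returned at square
resolution), full-field +-40% flashes (500 ms, 1.5 s gaps), full-field
Gaussian flicker (30% SD, 30 Hz), and jittering grating patches (750 um
circles on a hexagonal grid, 300 um period, +-15 um jitter steps at
30 Hz) with coherent vs per-patch-independent segments. The patch
schedule carries the per-patch jitter sequences so analyses can verify
coherence directly.

**Randomness.** One root seed spawns fixed, named `SeedSequence` streams
(texture, trajectory, spikes, shuffle, ...), so every component is a pure
function of (seed, parameters) and can be regenerated independently.

## Model retina

Each model DS cell filters the motion-step sequence (normalized to unit
variance using the analytic rounded-step SD) with one or two unit-norm
800-ms kernels (24 taps) and passes the drive through a static
nonlinearity; spike counts per frame are Poisson with rate N(g) * dt.
The temporal kernel is a difference of Gaussians peaking 175 ms before
the response with its sign change near 100 ms — within the 150-200 ms
pre-spike window where measured motion STAs peak. A cell's direction
enters by projecting the 2D steps onto (cos theta, sin theta).

Nonlinearities and their defaults:

- exponential (monotonic): N(x) = A e^{Bx}, A = 2 Hz, B = 1.0
  (mean rate ~3.3 Hz for unit-variance Gaussian drive);
- U-shape: N(x) = C + A x^2 e^{Bx}, C = 1 Hz, A = 2.75 Hz, B = 0.25
  (mean ~4.0 Hz).

Both sit inside the 1-10 Hz band of responsive cells. The steepness
values matter: a much steeper exponential (B ~ 1.5) makes the linear
readout of a single cell so distorted that opponent monotonic pairs stop
being redundant — the even-order distortion, shared with opposite sign of
the signal, cancels in the pair and masquerades as synergy. B = 1.0
keeps the monotonic control mildly distorting, which is the regime in
which a monotonic feature encoder behaves like the textbook redundant
case. The near-symmetric U-shape (B = 0.25) reproduces the strongly
compromised single-cell information (severalfold smaller than the
matched monotonic cells) that makes room for synergistic two-cell
readout. Both are overridable per cell.

Populations assign cells round-robin to three preferred directions 120
degrees apart. For two-dimensional experiments, cells can carry a second,
orthogonal filter with a symmetric U-shaped nonlinearity
(`two_component=True`), with rates summed: N(g1, g2) = N1(g1) + N2(g2).
This mirrors the observation that motion orthogonal to the preferred
direction modulates firing through an approximately symmetric U-shape,
and it is required to obtain synergy for 120-degree pairs: single-filter
cells only become synergistic near full opponency (180 degrees).

A separate texture-driven encoder (`simulate_texture_cell`) — an
OFF-rectified center-contrast signal plus a Barlow-Levick-style
correlator over two spatially offset OFF subunits with an asymmetric
delay — drives classification and conditional-texture-STA tests from
rendered movies. It is deliberately labeled synthetic scaffolding; no
quantitative claim rests on its details.

Trial protocols support identity, flip (both step components negated) and
+-1.5 mm texture-offset transforms with independent Poisson noise per
trial, enabling same-trial, shuffled-trial, flipped-trial and
offset-trial pairings.

## Estimators

**Motion STA.** Trajectory windows of L = 24 steps are arranged row-wise
(x taps then y taps, chronological; tap 0 is the oldest) and paired with
the count of the following frame; a = Sseg^T f / sum f. The preferred
direction is the angle of (sum_j a_xj, sum_j a_yj). Significance:
the observed ||a|| is compared with the 95th percentile of 1000
spike-shuffle magnitudes; shuffling redraws the spike times uniformly
over the recording, implemented as multinomial reallocation of the binned
counts (exactly equivalent for binned analyses, and vectorizable). The
alternative reading — permuting inter-spike intervals — is noted but not
used.

**LN nonlinearity.** The drive g uses the unit-norm STA on the
unit-variance stimulus; (g, f) pairs are sorted and split into 15
equal-count bins (stable sort; remainder samples go to the central bins),
with bin rates in Hz (counts / dt). U = (N(g_min) - N(0)) / N(g_max)
with N(0) the central bin.

**STC.** The spike-weighted covariance about the STA is computed on the
normalized stimulus, symmetrized, and eigendecomposed; the two leading
eigenvectors are analyzed, each with a conditional nonlinearity over
segments whose projection on the other eigenvector lies in (-0.5, 0.5).
Note that an exponential nonlinearity does not raise variance along its
filter (it only shifts the spike-triggered mean), so the STC positive
control is a U-shaped (variance-raising) cell.

**Decoder.** Row j of the design holds a constant 1 plus, per cell, the
counts of frames j..j+L-1 — the decoded step is read from the spikes that
*follow* it, so the fitted taps reproduce the time-reversed encoding
kernel (shifted by one frame; tap 0, the same-frame count, carries no
signal). The chronological 70/30 split drops windows straddling the
boundary from both sets; fitting is by `lstsq`, whose minimum-norm
solution doubles as the pseudo-inverse path for rank-deficient designs
(e.g. duplicated cells). No ridge regularization by default.

**Information.** Stimulus and error (e = s - u) are split into
non-overlapping 800-ms segments (no tapering), each axis independently
and after subtracting the global test-block means; per-band one-sided
powers are averaged over segments and the density log2(Ps/Pe) summed over
the 13 bands (0..15 Hz, 1.25 Hz spacing) and both axes, divided by
L dt. Bands where finite sampling makes Pe > Ps are clipped to zero,
keeping the estimate a conservative lower bound (a small downward bias,
visible at low SNR). Zero error power in a band flags the estimate
unbounded. Pairs with summed single-cell information below 0.1 bits/s are
excluded from ratio analyses; for larger populations no exclusion is
applied.

**CCA.** Sliding (stride-1) 2-s windows; the stimulus side is whitened by
its exact sigma^2-identity covariance (the steps are white), the response
side by the symmetric inverse square root of Cf regularized with
shrinkage lambda tr(Cf)/dim, lambda = 1e-3 (spike-count segment
covariances from finite data are near-singular). Component signs are
fixed by making the largest-magnitude element of each stimulus component
positive; singular values are clipped to [0, 1]. The per-component
response correlation is the Pearson r between the two cells' halves of
b_k.

**Classification.** DSI by the vector sum over 8 directions (onset second
of each presentation excluded, applied per presentation), OMSI =
(fd - fc)/(fd + fc), receptive fields by SVD factorization of the
checkerboard STA (500-ms window) with polarity auto-detection and a 2D
Gaussian least-squares fit, contrast indices from flash windows
(50-550 ms post-onset) and the flicker STA (last 200 ms, 7-tail-SD
inclusion). Standard DS: DSI > 0.3, grating rate > 1 Hz, OMSI < 0.7,
patch rate > 1 Hz. Direction groups split at 0/120/240 degrees (ties to
the lower interval); the left/right-eye parameter mirrors the angle sign.

## Experiments and problem sizes

The experiment drivers run the full chain (simulate -> decode singly and
jointly -> spectral bound -> ratio/correlation) per seeded run. Default
test-scale sizes, chosen to keep each experiment's Monte-Carlo error well
below the effect it measures: opponent-pair runs use 300-s
one-dimensional trajectories (100 runs per nonlinearity kind);
population-composition analyses use a single 900-s two-dimensional
trajectory with six two-component cells; perturbation experiments use
300-s trajectories with two repeats; recovery analyses use 20-30 min
recordings (>= 3000 spikes per cell). A `scale="full"` preset raises
runs to 1000 and durations to 30 min. The offset-shuffle perturbation
applied to motion-filter cells is a pure noise-shuffle control (motion
cells ignore the texture layout by construction); texture-offset effects
on shared local contrast require the texture-driven cells via
`apply_trial_protocol`.

## What the synthetic data does and does not show

The generator reproduces the stimulus statistics (step distribution,
quantization, texture spectra), realistic firing rates, Poisson
trial-to-trial variability, and the encoding structure (biphasic filters,
monotonic/U-shaped nonlinearities, three direction groups). It does not
model shared noise between cells (all noise correlations are zero by
construction), adaptation, refractoriness, or the joint
luminance-and-motion drive of real cells (except schematically in the
texture-driven scaffold). Passing tests therefore demonstrate that the
estimators and the synergy/redundancy logic behave correctly on data with
known ground truth — not that any particular biological population is
synergistic; quantitative values (bits/s, ratio magnitudes) depend on the
chosen nonlinearity parameters.

## Known limitations

- The spectral information estimate is a lower bound and mildly biased
  (clipping; finite segments); no bias-corrected estimator is provided.
- STC significance is limited to the top-2-eigenvalue convention; the
  full spectrum is reported but not tested band-wise.
- The decoder offers no regularized or nonlinear extensions.
- CCA is defined for cell pairs only.
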