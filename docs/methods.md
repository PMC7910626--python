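# Methods

## The model

`motionlab` studies how velocity estimation can be implemented by a
compact feed-forward network, and uses full access to that network as a
stand-in for the electrophysiology we cannot do at scale in cortex. The
network has three stages, named for the cortical areas they are
analogous to:

* **V1** — 64 spatiotemporal kernels (6 × 6 px × 6 frames) applied as a
  valid-mode correlation to a 32 × 32 × 6 input sequence, plus a
  per-kernel offset and ReLU. Time collapses (6 − 6 + 1 = 1), leaving 64
  maps of 27 × 27 rectified activities (46,656 units, 10,077,696 input
  connections, 13,888 learnable parameters).
* **MT** — a dense layer mapping all V1 activities to 64 units,
  `r = (W a + b)₊`. The rectification matters: it is what makes MT
  responses non-negative (as tuning analyses assume), what gives the
  pooling prediction a correlation slightly below 1, and what the
  rectified edge cross-correlation simulation emulates.
* **Output** — two linear regression units estimating v_x and v_y in
  px/frame. Speed and direction are read out as ρ = √(v_x² + v_y²),
  φ = atan2(v_y, v_x) (0° = rightward, counterclockwise); φ is undefined
  at ρ = 0 and flagged rather than fabricated.

Training is deliberately plain: mini-batch SGD (batch 32) on the
squared velocity error averaged over the batch, constant learning rate
1 × 10⁻⁴, 25 epochs at full scale. V1 kernels start as Gaussian noise
(SD 0.001); offsets start at zero. The dense and regression weights use
Glorot-uniform initialisation — an all-zero affine stack is a stationary
point of gradient descent (no gradient reaches a hidden layer whose
downstream weights are all zero), so some symmetry breaking in the
hidden weights is required for the network to train at all. Gradients
are hand-coded backpropagation in numpy; they are checked against
central finite differences (relative error < 10⁻⁴) in the test suite,
and the training loop runs in single precision (gradient rounding of
order 10⁻⁷ is far below SGD's own stochasticity; a float64 path exists
for exact-update tests).

## Synthetic training corpus

The training corpus emulates viewing a rigidly translating natural
image through a 32 × 32 window for 6 frames. In place of photographs we
synthesise Gaussian random-field textures whose radially averaged
amplitude spectrum falls as 1/f — the dominant second-order statistic
of natural scenes, and the statistic a linear-then-rectified motion
stage is sensitive to. Defaults: 200 textures of 128 × 128 px, 32,000
sequences, speeds uniform on 0.8–3.8 px/frame, directions uniform on
0–360°, per-sequence min–max scaling to [−1, 1], 75/25 train/test split
(24,000/8,000 at full scale). Subpixel translation accumulates
continuously (frame k at offset k·v) and is sampled bilinearly by
default; a Fourier-shift backend treats the source as periodic and is
exactly invertible. Texture Nyquist components are removed at synthesis:
a half-cycle-per-pixel component has no well-defined subpixel phase
shift in a real image, and keeping it breaks shift invertibility. An
ingest hook accepts user grayscale images instead of textures.

What the generator does **not** emulate: phase structure (edges,
contours, objects), luminance distributions, occlusion, or local
motion. Results that depend only on spatiotemporal correlation (motion
energy) transfer; any claim about object-level or phase-dependent
processing would not. This is why the desk-scale reproduction targets
the *qualitative* signatures (class structure, orderings, reversals)
rather than the exact published coefficients, which depend on the
specific photographs and full-scale training.

## Desk-scale study conditions

Full-scale training (32,000 sequences × 25 epochs × 10 networks) is not
needed to express the phenomena of interest. The package's reproduction
scale keeps the full 25-epoch schedule but reduces the corpus to 8,000
sequences (~4 minutes per network on one CPU): truncating the epoch
count instead leaves the optimisation mid-descent — the held-out loss
is still falling steeply at epoch 10 and the output gain is several
fold too small, which suppresses every amplitude-dependent response
phenomenon. At 8,000 × 25, held-out velocity correlations reach
≈ 0.95 per component (≥ 0.8 already by epoch 10). The test suite
trains a 2-seed ensemble at this scale; the acceptance script trains
10 networks at 10 epochs, which suffices for its one statistic (the
pooling correlation is insensitive to training depth).

## In-silico electrophysiology

**Batteries.** Drifting sinusoidal gratings: 16 directions × 10 spatial
periods (8–25 px/cycle, log-spaced) × 10 temporal periods (4–25
frames/cycle, log-spaced), each averaged over 32 equally spaced starting
phases (1600 conditions). Probe ranges are parameterised as *periods*;
the printed ranges make no sense as frequencies above 1 cycle/frame and
are treated as px/cycle and frames/cycle throughout, converted to
cycles/px and cycles/frame for reporting. A unit's preferred condition
is the grid argmax (ties broken to the lowest index and flagged);
preferred speed is tf/sf. V1 kernels are read out at the centre pixel of
their activity map — a convolutional kernel has a single tuning and the
position is arbitrary (map-mean readout is a config option). Because the
convolution stage is linear and a grating at phase φ is
cos φ·S(0) + sin φ·S(90), each battery convolves only the two
quadrature stimuli per condition and evaluates the rectified/dense
stages per phase; this is verified against brute-force per-phase
forward passes.

**Component vs pattern classification.** For a unit with direction
tuning curve g over 16 directions, the ideal *pattern* prediction for a
135°-plaid response is g itself; the ideal *component* prediction is
g shifted ±67.5° and summed. Raw correlations of the plaid response
with both predictions are partialed against each other
(R_p = (r_p − r_c·r_cp)/√((1 − r_c²)(1 − r_cp²))), Fisher-z transformed
with n = 16, and classified with a one-sided criterion of z ≥ 1.28
(90% confidence, the convention of this literature; configurable).
"Component" requires Z_c to exceed both zero and Z_p by the criterion;
"pattern" symmetrically; anything else is unclassed. The scalar pattern
index is Z_p − Z_c. Correlations are clipped at |r| = 0.9999 before
partialing so that noiseless ideal units classify decisively instead of
dividing by zero. Units that are not direction selective (peak grating
response below twice the opposite-direction response — the same 2:1
ratio used as the direction-selectivity definition elsewhere in the
package) are recorded unclassed with a flag rather than classified: on
a near-flat curve the partial-correlation machinery amplifies sub-1%
shared variance into spurious significance, since model responses carry
no sampling noise. The guard can be disabled by argument.

**Independent vs speed tuning.** Spectral response maps (6 × 6 periods:
8–33 px/cycle, 4–500 frames/cycle, at the unit's preferred direction)
are fit in log₂-period coordinates with an oriented 2-D Gaussian
(offset, amplitude, centre, widths, orientation; standard rotation
coefficients). Two constrained fits provide the ideal predictions:
orientation 0 (cardinal ridge — independent sf/tf tuning) and
orientation 45° (the constant-speed diagonal, since speed =
spatial period / temporal period is a unit-slope line in log-log
coordinates). Fits are initialised from the map argmax and run with 10
seeded random restarts; non-convergence flags the unit unclassed. The
same partial-correlation rule (n = 36 cells) yields
{independent, speed, unclassed} and a speed index Z_speed − Z_indep.

**Connectivity analyses.** A scalar V1→MT weight per (kernel, MT unit)
is the mean of the dense weights over the kernel's 27 × 27 positions
(max available by config). Weight profiles bin kernels by preferred
direction and circularly align each MT unit's profile to its preferred
direction, or to its maximum-excitation/-inhibition direction. The
speed median split assigns each V1 kernel to the MT unit receiving its
largest positive mean weight; kernels with no positive weight are
excluded and counted.

## Reverse-phi and the edge simulation

Phi probes are two frames of 5 white dots (radius 4) on mid-gray,
displaced rightward, followed by four uniform gray frames; reverse-phi
negates dot polarity on the second frame. Decoded velocity and the mean
activity of +v_x/−v_x subpopulations (MT units split by the sign of
their weight to the v_x output; V1 kernels inherit the label of the MT
unit they are most positively weighted to) are averaged over stimulus
seeds, normalised per network, then averaged over networks.

The model-free simulation cross-correlates 16 × 16 × 2 phi/reverse-phi
edge stimuli with 8 × 8 × 2 edge filters tuned left/right in both
polarity orders, keeps only valid-mode positive values (the network's
rectification), averages, and normalises the whole table to its
maximum (global normalisation; the per-panel alternative changes
nothing qualitative). It reproduces: reversal and attenuation of the
reverse-phi correlation at displacement 1, with the left/right
asymmetry growing with displacement for phi and shrinking for
reverse-phi — the mechanism behind the slow-overestimate /
fast-underestimate reverse-phi speed bias.

## Psychophysics

Coherence stimuli are 333 white dots (radius 2) on black, all at 3
px/frame; a fraction move along the signal direction and the rest keep
independent fixed uniform-random directions (re-randomising per frame
is the other convention; fixed-per-sequence is used here). Direction
discrimination: 7 coherences log-spaced 0.001–0.2, 100 trials each,
random signal direction per trial, correct within ±90°; zero decoded
speed scores a seeded coin flip and is flagged. A Weibull
P(x) = 1 − (1 − ½)·exp(−(x/α)^β) is fit by least squares; α is the
threshold at the conventional 1 − (1 − chance)/e point. Speed
estimation uses 10 dots and 5 coherences 0.2–1.0; estimates are
reported relative to the coherence-1.0 estimate, isolating the
coherence-induced bias from the network's generic speed offset (raw
estimates are kept alongside). Speed opponency presents white-on-black
dot fields at a unit's preferred and opposite direction over 8
log₂-spaced speeds 0.8–3.8. The pooling test measures per-MT-unit mean
activity at 0/50/100% coherence and correlates the 0/100 average with
the actual 50% response across the 64 units; a 100%-only control
predictor is reported for comparison.

## Numerical choices and degenerate inputs

* Correlation undefined (zero variance) → flagged, never silently 0.
* Tuning ties → lowest index, warned and flagged.
* Weibull on a flat-at-chance curve → non-identifiable, flagged.
* Training divergence (non-finite loss) → abort with diagnostics.
* All randomness flows from explicit integer seeds; every pipeline
  output is a pure function of (config, seeds), and output tables carry
  the config hash so tables from different runs cannot be mixed.

## Known limitations

* Texture statistics are second-order only (see above).
* Published full-scale coefficients (e.g. the exact pattern–speed
  correlation) are reproduced in sign and significance, not magnitude,
  at desk scale.
* Texture-trained V1 kernels are strongly space-time oriented, and a
  single oriented kernel's phase-averaged spectral map is genuinely
  elongated along the constant-speed diagonal; a substantial fraction
  of V1 kernels therefore classify as speed-tuned on the spectral axis.
  This is a property of the kernels' geometry under this corpus, not of
  the classifier (the count grows with training), and differs from the
  purely separable V1 reported for photograph-trained kernels.
* With the canonical coherence-stimulus parameters (333 dots of radius
  2 on a 32 × 32 canvas) the image is almost fully covered by dots, and
  direction discrimination stays near chance across the 0.001–0.2
  coherence range for texture-trained networks; the chance-level floor
  is expressed, the monotone rise is not.
* The reverse-phi speed bias reproduces the direction reversal and the
  fast-side underestimation; the slow-side overestimation (the crossing
  of the phi and reverse-phi curves) does not appear at desk scale with
  the texture corpus.
* The significance criterion (z ≥ 1.28), the inclusion guard, and the
  ideal component-prediction construction follow the field's
  conventions but are not uniquely determined; all are configurable.
* Dot rasterisation is not anti-aliased; occlusion is heavy at high dot
  counts, as specified.
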