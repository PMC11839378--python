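# Methods

## Scope and model

`beamprobe` screens a black-box learned beamformer for overfitting by
comparing its response to artificial channel-data inputs against a
reference delay-and-sum (DAS) beamformer. The package models a single 0°
plane-wave transmit received on a uniform linear array. All algorithms act
on the data model in `acquisition`: channel data indexed
`[element, time_sample]` (real RF or complex IQ), element positions on the
lateral x-axis, and a rectilinear imaging grid with x lateral and z depth,
images indexed `[row = z, column = x]`. Sample `k` corresponds to time
`t0 + k/fs`.

### Reference beamformer

For a pixel (x, z) and element at x_e, the round-trip travel time of a
plane wave steered at θ is

    τ(x, z, e) = (z·cosθ + x·sinθ + √((x − x_e)² + z²)) / c.

Each channel is converted to its analytic signal (Hilbert transform along
time for RF; for IQ the stored complex samples are phase-rotated by
exp(2πi·f_demod·τ) at the delayed time), sampled at τ by linear
interpolation (delays outside the recording window contribute 0), weighted
(uniform by default, or an f-number mask `|x − x_e| ≤ z/2f#`), summed over
elements, and the magnitude taken. The image is normalized by its global
maximum; a pre-normalization maximum ≤ 10⁻³⁰ returns an all-zero image with
a `degenerate` flag rather than dividing by zero. Taking the magnitude
*after* summation keeps the pipeline linear up to the envelope, so the
normalized image is invariant to positive scaling of the input — a
property the tests verify.

Uniform apodization is the default because the expected ground-truth
response to the all-ones probe is a nearly uniform, low-variance image;
aperture masking is available via `BeamformConfig` for sensitivity studies.

### Artificial probes

Exact zeros cannot be max-normalized, so the near-zero constant
ε = 10⁻²⁰ stands in for 0 everywhere. The center sample is the complement
of the fill value (1 in the zeros probe, ε in the ones probe) so the two
binary probes remain distinguishable after normalization; the center index
is `floor(dim/2)` per axis (a convention is needed for even dimensions).
The Gaussian probe is i.i.d. N(0, 1) min-max normalized globally to [0, 1]
(the simplest reading of a whole-matrix normalization; a per-row variant
was considered and rejected as it changes inter-channel structure). The
Gaussian probe is seeded and treated as stochastic downstream. A `custom`
kind accepts any user matrix, so evaluators can field private patterns a
network developer cannot have anticipated.

## Default acquisition

The defaults emulate a 128-element linear-array plane-wave benchmark
acquisition: pitch 0.30 mm, sound speed 1540 m/s, center frequency
5.208 MHz sampled at 4× (20.832 MHz), 2048 samples, t0 = 0, RF data.
The grid spans the array laterally and 5–50 mm in depth at 0.25 mm
spacing. All values live in `AcquisitionConfig` (YAML round-trip), never in
the algorithms. 2048 samples cover the full round trip to the deepest grid
corner (~73 µs ≈ sample 1526), so no probe energy is lost to the window.

Under these defaults the reference DAS maps the ones probe to an envelope
of mean 1.0000 ± 0.0002 and the zeros probe to 0.0046 ± 0.0332 (printed by
`examples/artificial_probes.py`). The exact acquisition behind the
published reference statistics for this probe family is not public, so
agreement is expected at the 10⁻² level, not to the last digit.

## Simulator

The phantom simulator is a single-scattering linear forward model: each
scatterer contributes a Gaussian-windowed sinusoid (fractional −6 dB
bandwidth 0.6 by default, support ±4σ) delayed by the *same* τ formula the
beamformer uses, plus optional i.i.d. Gaussian electronic noise. Element
directivity, attenuation, and multiple scattering are not modeled. This is
deliberate: the probes need controllable, physically plausible inputs, not
Field-II-grade realism — so passing tests demonstrates internal consistency
of the delay geometry and statistics, not fidelity to any specific scanner.

Speckle phantoms draw uniformly positioned scatterers with N(0, 1)
amplitudes at 400/mm² by default. At the default pulse and a full-aperture
receive, the resolution cell near 20–30 mm depth is ≈ 0.15 mm laterally ×
0.25 mm axially (≈ 0.0375 mm²), so 400/mm² keeps ≈ 15 scatterers per cell —
safely in the fully developed (Rayleigh) speckle regime, where the envelope
std/mean ratio is √(4/π − 1) ≈ 0.5227. At markedly lower densities the
envelope becomes K-distributed and the ratio inflates (≈ 0.56 at 6 per
cell), which is why the default is set where it is.

## Metric suite

ℓ1, ℓ2, NCC, and SSIM operate on normalized envelope images, not
log-compressed ones (the losses are defined on the normalized images; a dB
mode can be had by passing log-compressed arrays explicitly). The
population (1/N) variance convention is used everywhere, matching the 1/N
of the losses. SSIM defaults to the standard windowed form — 11×11
Gaussian weights, σ = 1.5, k1 = 0.01, k2 = 0.03, L = 1, averaged over
fully interior windows — with a `global` mode that evaluates the collapsed
formula once over the whole image. NCC on a zero-variance image raises
`ZeroVarianceError` instead of returning NaN: a constant output is a
degenerate beamformer result that must surface, not vanish into a masked
statistic. Every metric is tested against an independent brute-force loop
oracle (and SSIM additionally against scikit-image's implementation).

## Removal sweep

`removal_sweep` walks fractions 0.00–1.00 in 0.05 steps. The element count
removed is `round(f·n)` with halves away from zero (a rule is needed for
the half case; e.g. 5% of 128 → round(6.4) = 6). Removed rows are wholly
replaced by ε. Removal sets are *nested* by default: one seeded permutation
is drawn and prefixes of it are removed, making the curves
monotone-comparable and bitwise reproducible; `nested=False` draws an
independent subset per fraction. At f = 1 the input is exactly the zeros
probe. The per-step ground truth is DAS applied to the *same* degraded
data, so the curves isolate the network's behavior from the degradation
itself.

## Decision flow

Stage 0 (optional, needs baseline data): NCC of network vs DAS on
realistic data below 0.8 flags. This automates the qualitative side-by-side
checkpoint a human would perform; the B-mode PNGs (60 dB dynamic range) are
still exported for visual review, since a numeric floor is a stand-in, not
a replacement. Stage 1: zeros-probe mean ≥ 0.08 or ones-probe mean ≤ 0.07
flags. The Gaussian probe's mean is deliberately *not* a criterion — the
mean of a beamformed noise image has no predictable separation between
faithful and overfit networks — but its NCC/SSIM floors (Stage 2:
NCC ≤ 0.8, SSIM ≤ 0.2, applied to every probe) do apply. All comparisons
are inclusive. The overall verdict is `overfit-suspected` iff any flag is
raised (a single memorizing behavior should not be averaged away); every
flag quotes the metric value and threshold. `decide()` is a pure function
of reports and thresholds, so verdicts are replayable from saved metrics.

The thresholds are empirical screening values taken from observed
separations between well-behaved and overfit beamforming networks; they
are configuration, not derived constants, and can be tightened per fleet.

Trainable-parameter counting follows the standard convention: dense layers
contribute `in·out (+ out)`, 2-D convolutions `kh·kw·cin·cout (+ cout)`,
anything else declares an explicit count. The reference DAS has no layers:
0 parameters.

## Mock networks and what tests show

The *faithful* mock wraps the reference DAS, optionally scaled by a smooth
seeded gain field with peak deviation ≤ 5%; the *memorizer* ignores its
input and replays a stored image (or a fixed blend), reproducing the
failure mode of a network that memorized training images. The behavioral
guarantee — faithful always passes, memorizer always flagged, across 20
seeds at default thresholds — is tested with the zero-perturbation faithful
mock. A measured caveat recorded here deliberately: a *multiplicative*
gain perturbation, however small, destroys NCC against the ones-probe
ground truth, because that ground truth is nearly constant (std ≈ 4×10⁻⁴)
and the gain field then dominates the pixel variance. The 5%-gain variant
therefore keeps NCC ≥ 0.99 on speckle data (verified) but is not a fair
"faithful" stand-in on the near-constant probe; probe-NCC is informative
only for outputs that track the ground truth's own structure.

## Problem sizes and numerical choices

Unit and behavioral tests run a desk-scale configuration (64 elements,
1024 samples, 0.5 mm grid, low-density speckle) chosen so the full suite
exercises every pipeline end to end in well under a minute; the
ground-truth statistics, PSF, localization and speckle checks run the full
128-element default. The zeros-probe PSF check uses a 50 µm grid because
the arc's half-amplitude width is below one RF sample (c/fs ≈ 74 µm) and a
0.25 mm grid undersamples it into disconnected dots. Linear interpolation
and float64 accumulation are used throughout; ties and degenerate inputs
(all-zero images, zero-variance NCC, SSIM windows exceeding the image) are
handled by explicit guards that raise or flag rather than propagate NaNs.

## Known limitations

* The simulator omits directivity, attenuation, and elevation focusing;
  absolute envelope statistics of real scanners will differ.
* The detector reports a binary verdict with rationales; it does not
  quantify the *level* of overfitting, and blended-memory outputs that
  happen to correlate with a probe's ground truth above the floors would
  pass.
* Thresholds are empirical; recalibration is advisable for imaging regimes
  far from linear-array plane-wave ultrasound.
* The artificial probes are public; a network could in principle be trained
  on them. The `custom` probe kind exists precisely so evaluators can use
  private patterns.
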