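# beamprobe

Overfit detection for learned ultrasound beamformers, using artificial
channel-data probes.

## The problem

Deep networks trained to reconstruct ultrasound images from raw
radiofrequency (RF) channel data can overfit: they perform beautifully on
their training acquisitions while silently failing to *beamform* at all,
instead replaying memorized images. Detecting this normally requires the
training code, the training data, or fresh test acquisitions — none of which
a downstream user of a published network typically has.

`beamprobe` implements a screening method that needs only the network and
its input format. The premise: a true beamformer maps *any* input — real or
artificial — to the image a conventional delay-and-sum (DAS) beamformer
would produce from that same input. So the package feeds three artificial
inputs that no network can plausibly have trained on:

* **zeros** — a near-zero matrix (ε = 10⁻²⁰) with a single unit sample at
  the center: the expected image is the point spread function of that sample;
* **ones** — an all-ones matrix with a near-zero center sample: the expected
  image is nearly uniform white (envelope mean ≈ 1);
* **Gaussian noise** — i.i.d. N(0, 1) samples min-max normalized to [0, 1].

Each probe goes to both the network-under-test and the reference 0°
plane-wave DAS beamformer (the ground truth, which has **0** trainable
parameters). The outputs are compared with a metric suite — envelope
mean ± std, and with ground truth x versus network output y over N pixels:

    ℓ1 = (1/N) Σ |xₙ − yₙ|                ℓ2 = (1/N) Σ (xₙ − yₙ)²
    NCC = Σ(xₙ−μx)(yₙ−μy) / √(Σ(xₙ−μx)² Σ(yₙ−μy)²)
    SSIM = (2μxμy+C₁)(2σxy+C₂) / ((μx²+μy²+C₁)(σx²+σy²+C₂))

A staged decision flow raises flags (inclusive thresholds: zeros-probe
mean ≥ 0.08, ones-probe mean ≤ 0.07, NCC ≤ 0.8, SSIM ≤ 0.2) and any flag
yields an `overfit-suspected` verdict with the tripping metric quoted.

A complementary *progressive channel removal* sweep degrades realistic data
toward the zeros probe in 5% element increments (removed rows replaced by
ε; 100% removal *is* the zeros probe) and tracks NCC/SSIM against the
per-step DAS ground truth: faithful networks stay correlated and peak at
100%; memorizers collapse, bottoming out at 100%.

Everything needed is built in: a data model for channel data and geometry
(HDF5/NPZ containers), the reference DAS beamformer, a single-scattering
plane-wave simulator (point and speckle phantoms) for realistic inputs, the
metric suite, mock networks representing both behavioral extremes, and a
plugin contract for attaching real networks.

## Worked example

```python
import beamprobe as bp

cfg = bp.default_config()          # 128-element linear array, 0° plane wave
shape = (cfg.geometry.n_elements, cfg.n_samples)

for kind in ("zeros", "ones", "gaussian"):
    spec = bp.ArtificialInputSpec(kind=kind, shape=shape, seed=0)
    data = bp.make_artificial_input(spec, cfg)
    env = bp.beamform_das(data, cfg.geometry, cfg.grid)
    mean, std = bp.image_mean_std(env)
    print(f"{kind:>8} probe -> ground-truth envelope mean {mean:.4f} ± {std:.4f}")
```

prints

```
   zeros probe -> ground-truth envelope mean 0.0046 ± 0.0332
    ones probe -> ground-truth envelope mean 1.0000 ± 0.0002
gaussian probe -> ground-truth envelope mean 0.9364 ± 0.0148
```

The zeros probe images as a nearly black field with one point-spread arc
(mean ≈ 0) and the ones probe as a nearly uniform white image (mean ≈ 1):
these are the reference responses a genuine beamformer must reproduce. A
network whose zeros-probe output has mean ≥ 0.08, or whose ones-probe
output has mean ≤ 0.07, is emitting content unrelated to its input.

The `examples/` directory holds one short script per capability
(`artificial_probes.py`, `point_scatterer_psf.py`, `removal_sweep.py`,
`overfit_detection.py`); each prints its numbers with a line on what they
mean. A thin CLI mirrors the library:

```bash
beamprobe generate --kind zeros --shape 128,2048 --out probe.h5
beamprobe evaluate --net memorizer --out report/      # verdict + PNGs + CSV
beamprobe sweep --net faithful --phantom speckle --seed 1 --out sweep.csv
```

External networks attach via `--net plugin:path/to/module.py`, where the
module exposes `network(data, geom, grid) -> EnvelopeImage`.

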