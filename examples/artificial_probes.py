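"""Ground-truth statistics of the three artificial probes.

Generates the zeros, ones, and Gaussian-noise channel-data probes, beamforms
each with the reference delay-and-sum beamformer at the default 128-element
plane-wave configuration, and prints the mean ± std of each normalized
envelope image.  A genuine beamformer maps the zeros probe (one unit sample
in a near-zero field) to a nearly black image with a single point-spread
arc (mean ≈ 0), and the ones probe to a nearly uniform white image
(mean ≈ 1); these are the reference values a network-under-test is judged
against.
"""

import beamprobe as bp

cfg = bp.default_config()
shape = (cfg.geometry.n_elements, cfg.n_samples)

for kind in ("zeros", "ones", "gaussian"):
    spec = bp.ArtificialInputSpec(kind=kind, shape=shape, seed=0)
    data = bp.make_artificial_input(spec, cfg)
    env = bp.beamform_das(data, cfg.geometry, cfg.grid)
    mean, std = bp.image_mean_std(env)
    print(f"{kind:>8} probe -> ground-truth envelope mean {mean:.4f} ± {std:.4f}")

print(
    "\nzeros ≈ 0 and ones ≈ 1 are the expected beamformer responses; a "
    "network output far from these means is a first sign of overfitting."
)
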