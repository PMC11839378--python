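"""Synthetic single 0° plane-wave channel-data simulator.

A minimal single-scattering forward model: each point scatterer returns a
Gaussian-windowed sinusoid (the two-way pulse) delayed by the same
transmit-plus-receive travel time the beamformer uses, summed linearly over
scatterers, with optional i.i.d. Gaussian electronic noise.  Element
directivity and attenuation are deliberately not modeled — the probes only
need plausible, controllable data, not acoustic-simulation fidelity.

Sharing the delay formula with :func:`beamprobe.das.compute_delays`
guarantees the simulate→beamform round trip localizes scatterers exactly
where they were placed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acquisition import ArrayGeometry, ChannelData
from .errors import TruncationWarning, ValidationError

__all__ = [
    "Phantom",
    "simulate_channel_data",
    "make_point_phantom",
    "make_speckle_phantom",
    "gaussian_pulse_sigma",
]


@dataclass(frozen=True)
class Phantom:
    """Point-scatterer medium plus pulse and noise parameters.

    ``scatterers`` is a list of ``(x, z, amplitude)`` tuples (meters,
    unitless).  ``pulse_fractional_bandwidth`` is the −6 dB (FWHM) spectral
    width of the Gaussian pulse relative to ``pulse_center_freq``;
    ``noise_std`` is the standard deviation of additive Gaussian noise per
    RF sample.
    """

    scatterers: tuple[tuple[float, float, float], ...]
    pulse_center_freq: float = 5.208e6
    pulse_fractional_bandwidth: float = 0.6
    noise_std: float = 0.0

    def __post_init__(self):
        sc = tuple((float(x), float(z), float(a)) for x, z, a in self.scatterers)
        object.__setattr__(self, "scatterers", sc)
        for x, z, a in sc:
            if z <= 0:
                raise ValidationError("scatterer depths z must be positive")
            if not np.isfinite(a):
                raise ValidationError("scatterer amplitudes must be finite")
        if not (0 < self.pulse_fractional_bandwidth < 2):
            raise ValidationError("fractional bandwidth must lie in (0, 2)")
        if self.noise_std < 0:
            raise ValidationError("noise_std must be non-negative")


def gaussian_pulse_sigma(center_freq: float, fractional_bandwidth: float) -> float:
    """Temporal sigma (seconds) of a Gaussian pulse with the given FWHM bandwidth."""
    bw = fractional_bandwidth * center_freq  # FWHM in Hz
    sigma_f = bw / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return 1.0 / (2.0 * np.pi * sigma_f)


def simulate_channel_data(
    phantom: Phantom,
    geom: ArrayGeometry,
    fs: float,
    c: float = 1540.0,
    n_samples: int = 2048,
    seed: int = 0,
    t0: float = 0.0,
) -> ChannelData:
    """Forward-simulate RF channel data for a 0° plane-wave transmit.

    Per element e, ``samples(t) = Σ_k a_k · p(t − τ_k,e) + noise`` where
    τ uses the plane-wave delay formula and ``p`` is a Gaussian-windowed
    sinusoid at the pulse center frequency.  Echoes whose support extends
    past the recording window raise :class:`TruncationWarning` and are
    truncated.  Reproducible given ``seed``.
    """
    if fs <= 0 or c <= 0 or n_samples < 1:
        raise ValidationError("fs, c must be positive and n_samples >= 1")
    sigma_t = gaussian_pulse_sigma(
        phantom.pulse_center_freq, phantom.pulse_fractional_bandwidth
    )
    half = 4.0 * sigma_t  # pulse support, ±4σ
    support = int(np.ceil(2 * half * fs)) + 1
    offsets = np.arange(support)

    samples = np.zeros((geom.n_elements, n_samples), dtype=np.float64)
    ex = geom.element_x
    truncated = False
    for x, z, a in phantom.scatterers:
        tau = (z + np.sqrt((x - ex) ** 2 + z**2)) / c  # 0° plane wave
        start = np.floor((tau - half - t0) * fs).astype(np.int64)  # (n_el,)
        idx = start[:, None] + offsets  # (n_el, support)
        t_rel = t0 + idx / fs - tau[:, None]
        pulse = a * np.exp(-(t_rel**2) / (2.0 * sigma_t**2)) * np.cos(
            2.0 * np.pi * phantom.pulse_center_freq * t_rel
        )
        inside = (idx >= 0) & (idx < n_samples)
        if not inside.all():
            truncated = True
        rows = np.broadcast_to(np.arange(geom.n_elements)[:, None], idx.shape)
        np.add.at(samples, (rows[inside], idx[inside]), pulse[inside])

    if truncated:
        warnings.warn(
            "scatterer echoes extend beyond the recording window; truncated",
            TruncationWarning,
            stacklevel=2,
        )
    if phantom.noise_std > 0:
        rng = np.random.default_rng(seed)
        samples += rng.normal(0.0, phantom.noise_std, samples.shape)
    return ChannelData(
        samples=samples, sampling_rate=fs, sound_speed=c, t0=t0, tx_angle=0.0
    )


def make_point_phantom(
    positions: list[tuple[float, float]],
    amplitude: float = 1.0,
    **pulse_kwargs,
) -> Phantom:
    """Phantom of isolated unit-amplitude point targets."""
    if not positions:
        raise ValidationError("positions must be non-empty")
    return Phantom(
        scatterers=tuple((x, z, amplitude) for x, z in positions), **pulse_kwargs
    )


def make_speckle_phantom(
    region: tuple[float, float, float, float],
    density: float = 400e6,
    seed: int = 0,
    **pulse_kwargs,
) -> Phantom:
    """Diffuse sub-resolution scatterer field over ``(x0, x1, z0, z1)``.

    ``density`` is scatterers per square meter.  The default (400 per mm²)
    keeps more than ten scatterers per resolution cell for the default pulse
    and a full-aperture receive (cell ≈ 0.15 mm × 0.25 mm at 20–30 mm
    depth), the regime where the beamformed envelope develops fully Rayleigh
    speckle (std/mean ≈ 0.52).  Amplitudes are N(0, 1); seeded and
    reproducible.
    """
    x0, x1, z0, z1 = region
    if x1 <= x0 or z1 <= z0:
        raise ValidationError("region must have positive extent")
    area = (x1 - x0) * (z1 - z0)
    n = int(round(density * area))
    if n < 1:
        raise ValidationError("region too small for the requested density")
    rng = np.random.default_rng(seed)
    xs = rng.uniform(x0, x1, n)
    zs = rng.uniform(z0, z1, n)
    amps = rng.normal(0.0, 1.0, n)
    return Phantom(scatterers=tuple(zip(xs, zs, amps)), **pulse_kwargs)
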