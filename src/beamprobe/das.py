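"""Reference 0° plane-wave delay-and-sum (DAS) beamformer.

DAS reconstructs each pixel by time-aligning the per-element echoes to the
pixel's round-trip travel time and summing across the aperture.  For a plane
wave steered at angle θ, the transmit path to pixel (x, z) is
``z·cosθ + x·sinθ`` and the receive path back to element e at lateral
position x_e is ``sqrt((x − x_e)² + z²)``, so

    delay(x, z, e) = (z·cosθ + x·sinθ + sqrt((x − x_e)² + z²)) / c.

Envelope detection uses the per-channel analytic signal (Hilbert transform
along time for RF; phase rotation by the demodulation frequency for IQ),
with the magnitude taken after summation.  The output image is normalized
by its global maximum, with an explicit guard for the all-zero degenerate
case.  This beamformer has no trainable parameters; it is the ground truth
against which networks-under-test are compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import hilbert

from .acquisition import (
    ArrayGeometry,
    BModeImage,
    ChannelData,
    EnvelopeImage,
    ImagingGrid,
)
from .errors import ValidationError

__all__ = ["BeamformConfig", "compute_delays", "beamform_das", "log_compress"]

_DEGENERATE_MAX = 1e-30  # pre-normalization maxima at or below this are all-zero


@dataclass(frozen=True)
class BeamformConfig:
    """Receive-side beamforming options.

    ``apodization='uniform'`` weights every element equally; the near-unity
    low-variance image this yields for an all-ones input is the expected
    ground-truth behavior.  ``'fnumber-masked'`` restricts each pixel's
    receive aperture to elements within ``z / (2·f_number)`` laterally.
    Interpolation at the delayed sample times is linear; delays outside the
    recording window contribute 0.
    """

    apodization: Literal["uniform", "fnumber-masked"] = "uniform"
    f_number: float = 1.0
    interpolation: Literal["linear"] = "linear"
    out_of_bounds_value: float = 0.0

    def __post_init__(self):
        if self.apodization not in ("uniform", "fnumber-masked"):
            raise ValidationError(f"unknown apodization {self.apodization!r}")
        if self.apodization == "fnumber-masked" and self.f_number <= 0:
            raise ValidationError("f_number must be positive when masked")
        if self.interpolation != "linear":
            raise ValidationError("only linear interpolation is supported")


def compute_delays(
    grid: ImagingGrid,
    geom: ArrayGeometry,
    angle: float = 0.0,
    c: float = 1540.0,
) -> np.ndarray:
    """Round-trip travel time to every (pixel, element) pair.

    Returns an array of shape ``(n_z, n_x, n_elements)`` in seconds.
    """
    if c <= 0:
        raise ValidationError("sound speed c must be positive")
    X, Z = grid.meshgrid()  # (n_z, n_x)
    tx = Z * np.cos(angle) + X * np.sin(angle)
    rx = np.sqrt((X[..., None] - geom.element_x) ** 2 + Z[..., None] ** 2)
    return (tx[..., None] + rx) / c


def _analytic(data: ChannelData) -> np.ndarray:
    """Per-channel analytic signal along the time axis."""
    if data.is_iq:
        return np.asarray(data.samples, dtype=np.complex128)
    return hilbert(np.asarray(data.samples, dtype=np.float64), axis=1)


def beamform_das(
    data: ChannelData,
    geom: ArrayGeometry,
    grid: ImagingGrid,
    cfg: BeamformConfig | None = None,
) -> EnvelopeImage:
    """Delay, apodize, and sum channel data onto the grid; return the envelope.

    The pre-normalization beamformed image is linear in the input, so the
    normalized envelope is invariant to positive scaling of the samples.
    An all-zero pre-normalization image returns zeros with the
    ``degenerate`` flag set instead of dividing by zero.
    """
    cfg = cfg or BeamformConfig()
    if data.n_elements != geom.n_elements:
        raise ValidationError(
            "channel-data element count does not match the array geometry"
        )
    analytic = _analytic(data)
    delays = compute_delays(grid, geom, data.tx_angle, data.sound_speed)
    fs, t0, n = data.sampling_rate, data.t0, data.n_samples
    X, Z = grid.meshgrid()

    acc = np.zeros(grid.shape, dtype=np.complex128)
    for e in range(geom.n_elements):
        tau = delays[..., e]
        s = (tau - t0) * fs  # fractional sample position
        i0 = np.floor(s).astype(np.int64)
        frac = s - i0
        valid = (i0 >= 0) & (i0 <= n - 2)
        i0c = np.clip(i0, 0, n - 2)
        ch = analytic[e]
        val = (1.0 - frac) * ch[i0c] + frac * ch[i0c + 1]
        val = np.where(valid, val, cfg.out_of_bounds_value)
        if data.is_iq:
            val = val * np.exp(2j * np.pi * data.demod_freq * tau)
        if cfg.apodization == "fnumber-masked":
            apod = (
                np.abs(X - geom.element_x[e]) <= Z / (2.0 * cfg.f_number)
            ).astype(np.float64)
            val = val * apod
        acc += val

    env = np.abs(acc)
    peak = float(env.max())
    if peak <= _DEGENERATE_MAX:
        return EnvelopeImage(
            values=np.zeros(grid.shape), normalization_max=peak, degenerate=True
        )
    return EnvelopeImage(values=env / peak, normalization_max=peak)


def log_compress(env: EnvelopeImage, dynamic_range: float = 60.0) -> BModeImage:
    """Log-compress a normalized envelope for display.

    ``db = 20·log10(max(values, 10^(−DR/20)))`` clips to [−DR, 0] dB; a value
    of 1 maps to 0 dB.
    """
    if dynamic_range <= 0:
        raise ValidationError("dynamic_range must be positive")
    floor = 10.0 ** (-dynamic_range / 20.0)
    db = 20.0 * np.log10(np.maximum(env.values, floor))
    return BModeImage(db_values=db, dynamic_range=float(dynamic_range))
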