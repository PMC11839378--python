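"""Artificial channel-data probes: zeros, ones, Gaussian noise, and custom.

These inputs are deliberately unlike any real acquisition, so a network that
truly beamforms should map them to the same predictable images a conventional
delay-and-sum beamformer produces, while a network that memorized its training
set will not.  Exact zeros are avoided because an all-zero envelope cannot be
max-normalized; a near-zero constant ``epsilon`` (default 1e-20) stands in,
and one sample at the matrix center carries the complementary binary value so
the zeros and ones probes remain distinguishable after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .acquisition import AcquisitionConfig, ChannelData, default_config
from .errors import ValidationError

__all__ = [
    "ArtificialInputSpec",
    "make_zeros_input",
    "make_ones_input",
    "make_gaussian_input",
    "make_artificial_input",
    "center_index",
]

Kind = Literal["zeros", "ones", "gaussian", "custom"]
_KINDS = ("zeros", "ones", "gaussian", "custom")


@dataclass(frozen=True)
class ArtificialInputSpec:
    """Recipe for one artificial probe.

    ``epsilon`` is the near-zero stand-in for 0 (must stay far below any
    signal scale); ``seed`` only affects the Gaussian probe.  ``custom``
    probes carry a user-supplied matrix so evaluators can field private
    patterns a network developer cannot have trained on.
    """

    kind: Kind
    shape: tuple[int, int]
    epsilon: float = 1e-20
    seed: int = 0
    gaussian_mean: float = 0.0
    gaussian_std: float = 1.0
    custom_samples: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValidationError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if len(self.shape) != 2 or any(int(d) < 1 for d in self.shape):
            raise ValidationError("shape must be two dimensions, each >= 1")
        object.__setattr__(self, "shape", (int(self.shape[0]), int(self.shape[1])))
        if not (0 < self.epsilon < 1e-10):
            raise ValidationError("epsilon must lie in (0, 1e-10)")
        if self.kind == "custom" and self.custom_samples is None:
            raise ValidationError("custom kind requires custom_samples")


def center_index(shape: tuple[int, int]) -> tuple[int, int]:
    """Center sample index: floor(dim / 2) on each axis."""
    return (shape[0] // 2, shape[1] // 2)


def _wrap(samples: np.ndarray, config: AcquisitionConfig | None) -> ChannelData:
    cfg = config if config is not None else default_config(n_elements=samples.shape[0])
    return ChannelData(
        samples=samples,
        sampling_rate=cfg.sampling_rate,
        sound_speed=cfg.sound_speed,
        demod_freq=cfg.demod_freq,
        tx_angle=0.0,
        t0=cfg.t0,
    )


def make_zeros_input(
    spec: ArtificialInputSpec, config: AcquisitionConfig | None = None
) -> ChannelData:
    """Near-zero matrix with a single unit sample at the center.

    Every sample equals ``epsilon`` except the center sample, which is 1.
    Through a delay-and-sum beamformer the unit sample acts as an impulse,
    so the expected image is the point spread function of that sample.
    """
    if spec.kind != "zeros":
        raise ValidationError(f"spec kind must be 'zeros', got {spec.kind!r}")
    samples = np.full(spec.shape, spec.epsilon, dtype=np.float64)
    samples[center_index(spec.shape)] = 1.0
    return _wrap(samples, config)


def make_ones_input(
    spec: ArtificialInputSpec, config: AcquisitionConfig | None = None
) -> ChannelData:
    """All-ones matrix with a near-zero center sample (complement of zeros)."""
    if spec.kind != "ones":
        raise ValidationError(f"spec kind must be 'ones', got {spec.kind!r}")
    samples = np.ones(spec.shape, dtype=np.float64)
    samples[center_index(spec.shape)] = spec.epsilon
    return _wrap(samples, config)


def make_gaussian_input(
    spec: ArtificialInputSpec, config: AcquisitionConfig | None = None
) -> ChannelData:
    """I.i.d. N(mean, std) samples min-max normalized to [0, 1].

    Normalization is global over the whole matrix (min maps to 0, max to 1),
    matching the range of the binary probes.  Reproducible given ``seed``.
    """
    if spec.kind != "gaussian":
        raise ValidationError(f"spec kind must be 'gaussian', got {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    raw = rng.normal(spec.gaussian_mean, spec.gaussian_std, spec.shape)
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        raise ValidationError("degenerate Gaussian draw: all samples equal")
    return _wrap((raw - lo) / (hi - lo), config)


def make_artificial_input(
    spec: ArtificialInputSpec, config: AcquisitionConfig | None = None
) -> ChannelData:
    """Dispatch on ``spec.kind``; ``custom`` wraps the user-supplied matrix."""
    if spec.kind == "zeros":
        return make_zeros_input(spec, config)
    if spec.kind == "ones":
        return make_ones_input(spec, config)
    if spec.kind == "gaussian":
        return make_gaussian_input(spec, config)
    samples = np.asarray(spec.custom_samples, dtype=np.float64)
    if samples.shape != spec.shape:
        raise ValidationError("custom_samples shape must match spec.shape")
    return _wrap(samples, config)
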