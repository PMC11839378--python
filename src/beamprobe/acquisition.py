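"""Core data model: array geometry, channel data, imaging grids, and container I/O.

Conventions used throughout the package:

* ``x`` is the lateral coordinate along the array axis, ``z`` is depth; both in
  meters.  Images are indexed ``[row = z, column = x]``.
* Time samples are 0-based; sample ``k`` of a channel corresponds to time
  ``t0 + k / sampling_rate``.
* Channel data are stored ``[element, time_sample]``, real RF or complex IQ.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import yaml

from .errors import SchemaError, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ArrayGeometry",
    "ChannelData",
    "ImagingGrid",
    "EnvelopeImage",
    "BModeImage",
    "AcquisitionConfig",
    "default_config",
    "read_channel_data",
    "write_channel_data",
]

_POSITION_TOL = 1e-9  # meters; tolerance on element-position symmetry/uniformity


@dataclass(frozen=True)
class ArrayGeometry:
    """Linear-array geometry: element centers on the lateral (x) axis.

    Parameters
    ----------
    element_x
        Lateral element-center positions in meters, strictly increasing,
        uniformly spaced, and symmetric about x = 0.
    pitch
        Element spacing in meters; must equal the common difference of
        ``element_x``.
    """

    element_x: np.ndarray
    pitch: float

    def __post_init__(self):
        ex = np.asarray(self.element_x, dtype=np.float64)
        object.__setattr__(self, "element_x", ex)
        if ex.ndim != 1 or ex.size < 1:
            raise ValidationError("element_x must be a non-empty 1-D array")
        if not np.all(np.isfinite(ex)):
            raise ValidationError("element_x must be finite")
        if self.pitch <= 0:
            raise ValidationError("pitch must be positive")
        if ex.size > 1:
            diffs = np.diff(ex)
            if np.any(diffs <= 0):
                raise ValidationError("element_x must be strictly increasing")
            if np.any(np.abs(diffs - self.pitch) > _POSITION_TOL):
                raise ValidationError("element_x spacing must equal pitch")
        if abs(ex[0] + ex[-1]) > 2 * _POSITION_TOL:
            raise ValidationError("element_x must be symmetric about 0")

    @property
    def n_elements(self) -> int:
        return int(self.element_x.size)

    @property
    def aperture(self) -> float:
        """Total aperture span (first to last element center), meters."""
        return float(self.element_x[-1] - self.element_x[0])

    @classmethod
    def linear(cls, n_elements: int, pitch: float) -> "ArrayGeometry":
        """Uniform linear array of ``n_elements`` centered on x = 0."""
        idx = np.arange(n_elements, dtype=np.float64)
        x = (idx - (n_elements - 1) / 2.0) * pitch
        return cls(element_x=x, pitch=float(pitch))


@dataclass(frozen=True)
class ChannelData:
    """Per-element received signals plus the acquisition constants.

    ``samples`` is indexed ``[element, time_sample]``; real-valued RF or
    complex IQ (``demod_freq`` > 0 marks IQ).  ``tx_angle`` is the plane-wave
    steering angle in radians (0 for the single broadside transmit considered
    here); ``t0`` is the receive time of the first sample in seconds.
    """

    samples: np.ndarray
    sampling_rate: float
    sound_speed: float
    demod_freq: float = 0.0
    tx_angle: float = 0.0
    t0: float = 0.0

    def __post_init__(self):
        s = np.asarray(self.samples)
        if not np.iscomplexobj(s):
            s = s.astype(np.float64, copy=False)
        object.__setattr__(self, "samples", s)
        if s.ndim != 2:
            raise ValidationError("samples must be a 2-D [element, time] array")
        if not np.all(np.isfinite(s)):
            raise ValidationError("samples must be finite")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.sound_speed <= 0:
            raise ValidationError("sound_speed must be positive")
        if self.demod_freq < 0:
            raise ValidationError("demod_freq must be non-negative")

    @property
    def n_elements(self) -> int:
        return int(self.samples.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[1])

    @property
    def is_iq(self) -> bool:
        return self.demod_freq > 0

    def with_samples(self, samples: np.ndarray) -> "ChannelData":
        """Copy of this acquisition with the sample matrix replaced."""
        return replace(self, samples=samples)


@dataclass(frozen=True)
class ImagingGrid:
    """Rectilinear pixel grid: lateral coordinates ``x``, depths ``z`` (meters)."""

    x: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=np.float64)
        z = np.asarray(self.z, dtype=np.float64)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        for name, v in (("x", x), ("z", z)):
            if v.ndim != 1 or v.size < 1:
                raise ValidationError(f"grid {name} must be a non-empty 1-D array")
            if v.size > 1 and np.any(np.diff(v) <= 0):
                raise ValidationError(f"grid {name} must be strictly increasing")
        if np.any(z <= 0):
            raise ValidationError("grid depths z must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape ``(n_z, n_x)`` = (rows, columns)."""
        return (int(self.z.size), int(self.x.size))

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel coordinate matrices ``(X, Z)`` of shape ``(n_z, n_x)``."""
        return np.meshgrid(self.x, self.z)


@dataclass(frozen=True)
class EnvelopeImage:
    """Max-normalized envelope image on an imaging grid.

    ``values`` lies in [0, 1]; ``normalization_max`` is the pre-normalization
    global maximum that was divided out.  ``degenerate`` marks an all-zero
    pre-normalization image for which no meaningful normalization exists.
    """

    values: np.ndarray
    normalization_max: float = 1.0
    degenerate: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValidationError("envelope values must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValidationError("envelope values must be finite")
        if v.min(initial=0.0) < 0 or v.max(initial=0.0) > 1 + 1e-12:
            raise ValidationError("envelope values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.values.shape)


@dataclass(frozen=True)
class BModeImage:
    """Log-compressed display image in decibels over a fixed dynamic range."""

    db_values: np.ndarray
    dynamic_range: float = 60.0

    def __post_init__(self):
        v = np.asarray(self.db_values, dtype=np.float64)
        object.__setattr__(self, "db_values", v)
        if self.dynamic_range <= 0:
            raise ValidationError("dynamic_range must be positive")
        if v.min(initial=0.0) < -self.dynamic_range - 1e-9 or v.max(initial=0.0) > 1e-9:
            raise ValidationError("db_values must lie in [-dynamic_range, 0]")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Bundle of geometry, grid, and acquisition constants.

    The defaults emulate a 128-element linear-array, single 0° plane-wave
    acquisition of the kind used by public plane-wave imaging benchmarks;
    every value is configurable and none is hard-coded in the algorithms.
    """

    geometry: ArrayGeometry
    grid: ImagingGrid
    sampling_rate: float
    sound_speed: float
    center_frequency: float
    n_samples: int
    t0: float = 0.0
    demod_freq: float = 0.0

    def to_dict(self) -> dict:
        return {
            "n_elements": self.geometry.n_elements,
            "pitch": self.geometry.pitch,
            "grid_x_min": float(self.grid.x[0]),
            "grid_x_max": float(self.grid.x[-1]),
            "grid_z_min": float(self.grid.z[0]),
            "grid_z_max": float(self.grid.z[-1]),
            "grid_dx": float(self.grid.x[1] - self.grid.x[0]) if self.grid.x.size > 1 else 0.0,
            "grid_dz": float(self.grid.z[1] - self.grid.z[0]) if self.grid.z.size > 1 else 0.0,
            "sampling_rate": self.sampling_rate,
            "sound_speed": self.sound_speed,
            "center_frequency": self.center_frequency,
            "n_samples": self.n_samples,
            "t0": self.t0,
            "demod_freq": self.demod_freq,
        }

    def to_yaml(self, path: str | os.PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        base = default_config().to_dict()
        unknown = set(d) - set(base)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        base.update(d)
        geom = ArrayGeometry.linear(int(base["n_elements"]), float(base["pitch"]))
        grid = ImagingGrid(
            x=_spaced(base["grid_x_min"], base["grid_x_max"], base["grid_dx"]),
            z=_spaced(base["grid_z_min"], base["grid_z_max"], base["grid_dz"]),
        )
        return cls(
            geometry=geom,
            grid=grid,
            sampling_rate=float(base["sampling_rate"]),
            sound_speed=float(base["sound_speed"]),
            center_frequency=float(base["center_frequency"]),
            n_samples=int(base["n_samples"]),
            t0=float(base["t0"]),
            demod_freq=float(base["demod_freq"]),
        )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "AcquisitionConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _spaced(lo: float, hi: float, step: float) -> np.ndarray:
    if step <= 0:
        return np.array([lo])
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def default_config(
    n_elements: int = 128,
    pitch: float = 0.30e-3,
    sound_speed: float = 1540.0,
    center_frequency: float = 5.208e6,
    sampling_rate: float | None = None,
    n_samples: int = 2048,
    grid_spacing: float = 0.25e-3,
    z_min: float = 5e-3,
    z_max: float = 50e-3,
) -> AcquisitionConfig:
    """Default 128-element linear-array plane-wave configuration.

    Sampling defaults to 4x the 5.208 MHz center frequency (20.832 MHz).
    The imaging grid spans the array laterally at 0.25 mm spacing and covers
    5-50 mm in depth, a typical field of view for this probe class.
    """
    if sampling_rate is None:
        sampling_rate = 4.0 * center_frequency
    geom = ArrayGeometry.linear(n_elements, pitch)
    grid = ImagingGrid(
        x=_spaced(float(geom.element_x[0]), float(geom.element_x[-1]), grid_spacing),
        z=_spaced(z_min, z_max, grid_spacing),
    )
    return AcquisitionConfig(
        geometry=geom,
        grid=grid,
        sampling_rate=float(sampling_rate),
        sound_speed=float(sound_speed),
        center_frequency=float(center_frequency),
        n_samples=int(n_samples),
    )


# ---------------------------------------------------------------------------
# Container I/O.  HDF5 is the primary format; NPZ is used for ``.npz`` paths.
# ---------------------------------------------------------------------------

_SCALAR_FIELDS = ("sampling_rate", "sound_speed", "demod_freq", "tx_angle", "t0")
_REQUIRED_FIELDS = ("samples", "element_x") + _SCALAR_FIELDS


def write_channel_data(
    data: ChannelData, geom: ArrayGeometry, path: str | os.PathLike
) -> None:
    """Write an acquisition to an HDF5 (or ``.npz``) container file.

    The file holds ``samples`` ([n_elements, n_samples], float32 or
    complex64 as recorded), ``element_x`` (float64, meters), and the scalar
    acquisition constants; :func:`read_channel_data` inverts it losslessly.
    """
    if data.n_elements != geom.n_elements:
        raise ValidationError(
            "samples first dimension must equal the geometry element count"
        )
    path = Path(path)
    if path.exists():
        log.info("overwriting existing container file %s", path)
    payload = {
        "samples": data.samples,
        "element_x": geom.element_x,
        **{k: np.float64(getattr(data, k)) for k in _SCALAR_FIELDS},
    }
    if path.suffix == ".npz":
        np.savez(path, **payload)
        return
    with h5py.File(path, "w") as f:
        for k, v in payload.items():
            f.create_dataset(k, data=v)


def read_channel_data(path: str | os.PathLike) -> tuple[ChannelData, ArrayGeometry]:
    """Read an acquisition container written by :func:`write_channel_data`.

    Raises
    ------
    SchemaError
        If a required dataset is missing (the error names the field).
    ValidationError
        If the stored values violate the data-model invariants.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as f:
            raw = {k: f[k] for k in f.files}
    else:
        with h5py.File(path, "r") as f:
            raw = {k: f[k][()] for k in f.keys()}
    for k in _REQUIRED_FIELDS:
        if k not in raw:
            raise SchemaError(k, str(path))
    geom_x = np.asarray(raw["element_x"], dtype=np.float64)
    pitch = float(np.diff(geom_x).mean()) if geom_x.size > 1 else 1.0
    geom = ArrayGeometry(element_x=geom_x, pitch=pitch)
    data = ChannelData(
        samples=np.asarray(raw["samples"]),
        **{k: float(raw[k]) for k in _SCALAR_FIELDS},
    )
    if data.n_elements != geom.n_elements:
        raise ValidationError(
            "samples first dimension must equal the geometry element count"
        )
    return data, geom
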