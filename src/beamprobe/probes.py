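"""Probe protocols: artificial-input probing and progressive channel removal.

A *network-under-test* is any callable mapping (ChannelData, ArrayGeometry,
ImagingGrid) to a normalized EnvelopeImage.  The probing protocols are pure
evaluations: the same inputs go to both the network and the reference DAS
beamformer, and the resulting image pairs are scored with the metric suite.
Mock networks — a *faithful* beamformer and a training-set *memorizer* —
reproduce the two behavioral extremes the detector must separate.

Progressive channel removal degrades realistic channel data toward the
artificial zeros probe: at each step a seeded random subset of element rows
is replaced with the near-zero constant, and at 100% removal the input *is*
the zeros probe (single unit sample at the matrix center).  A genuine
beamformer degrades gracefully and snaps to the point-spread-function image
at 100%; a memorizer keeps emitting learned patterns, so its agreement with
the per-step ground truth collapses instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .acquisition import ArrayGeometry, ChannelData, EnvelopeImage, ImagingGrid
from .artificial import ArtificialInputSpec, make_artificial_input, make_zeros_input
from .das import BeamformConfig, beamform_das
from .errors import ContractViolationError, ValidationError
from .metrics import MetricConfig, MetricReport, compute_report

__all__ = [
    "NetworkUnderTest",
    "RemovalProtocol",
    "RemovalSweepResult",
    "ProbeResult",
    "remove_channels",
    "removal_sweep",
    "run_artificial_probe",
    "mock_faithful_net",
    "mock_memorizer_net",
    "round_half_away",
]

BeamformerFn = Callable[[ChannelData, ArrayGeometry, ImagingGrid], EnvelopeImage]


@dataclass(frozen=True)
class NetworkUnderTest:
    """Callable contract for a beamformer under evaluation.

    ``fn`` must be deterministic in inference mode and return an
    EnvelopeImage matching the grid shape with values in [0, 1].
    ``declared_params`` optionally carries the layer list used for
    trainable-parameter counting.
    """

    fn: BeamformerFn
    name: str = "network"
    declared_params: Sequence | None = None

    def __call__(
        self, data: ChannelData, geom: ArrayGeometry, grid: ImagingGrid
    ) -> EnvelopeImage:
        out = self.fn(data, geom, grid)
        if not isinstance(out, EnvelopeImage):
            raise ContractViolationError(
                f"network {self.name!r} returned {type(out).__name__}, "
                "expected EnvelopeImage"
            )
        if out.shape != grid.shape:
            raise ContractViolationError(
                f"network {self.name!r} output shape {out.shape} does not "
                f"match grid shape {grid.shape}"
            )
        return out


@dataclass(frozen=True)
class RemovalProtocol:
    """Channel-removal sweep settings.

    5% increments by default; removed element rows are replaced wholly by
    ``replacement_value``.  ``nested=True`` draws one seeded element
    permutation and removes cumulatively, so the removed sets form a chain;
    ``nested=False`` draws a fresh subset at every fraction.
    """

    increment: float = 0.05
    replacement_value: float = 1e-20
    nested: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.increment <= 1):
            raise ValidationError("increment must lie in (0, 1]")
        if self.replacement_value <= 0:
            raise ValidationError("replacement_value must be positive")

    @property
    def fractions(self) -> tuple[float, ...]:
        n = int(round(1.0 / self.increment))
        return tuple(round(i * self.increment, 10) for i in range(n + 1))


@dataclass(frozen=True)
class RemovalSweepResult:
    """Per-fraction removal sets and similarity curves for one network."""

    fractions: tuple[float, ...]
    removed_elements: tuple[frozenset, ...]
    ncc_curve: tuple[float, ...]
    ssim_curve: tuple[float, ...]
    network: str = "network"


@dataclass(frozen=True)
class ProbeResult:
    """One artificial probe: the network and ground-truth images plus metrics."""

    kind: str
    net_image: EnvelopeImage
    truth_image: EnvelopeImage
    report: MetricReport


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def remove_channels(
    data: ChannelData,
    fraction: float,
    protocol: RemovalProtocol | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ChannelData, frozenset]:
    """Replace a random ``fraction`` of element rows with the near-zero value.

    ``round(fraction · n_elements)`` rows (nearest integer, halves away from
    zero) are selected with the protocol's seed.  ``fraction = 1`` returns
    the artificial zeros input of the same shape, completing the transition
    from real data to the fully artificial probe.
    """
    protocol = protocol or RemovalProtocol()
    if not (0.0 <= fraction <= 1.0):
        raise ValidationError("fraction must lie in [0, 1]")
    n = data.n_elements
    if fraction == 1.0:
        spec = ArtificialInputSpec(
            kind="zeros",
            shape=(n, data.n_samples),
            epsilon=protocol.replacement_value,
        )
        zeros = make_zeros_input(spec)
        return data.with_samples(zeros.samples), frozenset(range(n))
    k = round_half_away(fraction * n)
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    removed = frozenset(rng.choice(n, size=k, replace=False).tolist())
    samples = data.samples.copy()
    if removed:
        samples[sorted(removed), :] = protocol.replacement_value
    return data.with_samples(samples), removed


def removal_sweep(
    net: NetworkUnderTest,
    data: ChannelData,
    geom: ArrayGeometry,
    grid: ImagingGrid,
    protocol: RemovalProtocol | None = None,
    beamform_cfg: BeamformConfig | None = None,
    metric_cfg: MetricConfig | None = None,
) -> RemovalSweepResult:
    """Progressive channel-removal sweep for one network.

    At each fraction the *same* degraded data go to both the reference DAS
    (the per-step ground truth) and the network; NCC and SSIM of the network
    output against that ground truth are recorded.  Deterministic given the
    protocol seed.
    """
    protocol = protocol or RemovalProtocol()
    n = geom.n_elements
    rng = np.random.default_rng(protocol.seed)
    order = rng.permutation(n)  # used in nested mode

    fractions, removed_sets, nccs, ssims = [], [], [], []
    for f in protocol.fractions:
        if f >= 1.0:
            degraded, removed = remove_channels(data, 1.0, protocol)
        elif protocol.nested:
            k = round_half_away(f * n)
            removed = frozenset(order[:k].tolist())
            samples = data.samples.copy()
            if removed:
                samples[sorted(removed), :] = protocol.replacement_value
            degraded = data.with_samples(samples)
        else:
            degraded, removed = remove_channels(data, f, protocol, rng=rng)
        truth = beamform_das(degraded, geom, grid, beamform_cfg)
        out = net(degraded, geom, grid)
        report = compute_report(truth, out, metric_cfg)
        fractions.append(f)
        removed_sets.append(removed)
        nccs.append(report.ncc)
        ssims.append(report.ssim)
    return RemovalSweepResult(
        fractions=tuple(fractions),
        removed_elements=tuple(removed_sets),
        ncc_curve=tuple(nccs),
        ssim_curve=tuple(ssims),
        network=net.name,
    )


def run_artificial_probe(
    net: NetworkUnderTest,
    specs: Sequence[ArtificialInputSpec],
    geom: ArrayGeometry,
    grid: ImagingGrid,
    beamform_cfg: BeamformConfig | None = None,
    metric_cfg: MetricConfig | None = None,
) -> list[ProbeResult]:
    """Feed each artificial probe to both the reference DAS and the network.

    For every spec the identical input goes to both beamformers and a full
    MetricReport of the network output against the DAS ground truth is
    attached.  Pure evaluation: neither the network nor the inputs are
    mutated.
    """
    if not specs:
        raise ValidationError("specs must be non-empty")
    results = []
    for spec in specs:
        data = make_artificial_input(spec)
        truth = beamform_das(data, geom, grid, beamform_cfg)
        out = net(data, geom, grid)
        results.append(
            ProbeResult(
                kind=spec.kind,
                net_image=out,
                truth_image=truth,
                report=compute_report(truth, out, metric_cfg),
            )
        )
    return results


# ---------------------------------------------------------------------------
# Mock networks: the behavioral extremes used to validate the detector.
# ---------------------------------------------------------------------------


def mock_faithful_net(
    cfg: BeamformConfig | None = None,
    perturbation: float = 0.0,
    seed: int = 0,
    name: str = "faithful-mock",
) -> NetworkUnderTest:
    """A well-behaved network: the reference DAS plus a small gain field.

    ``perturbation`` bounds the maximum multiplicative deviation (≤ 0.05
    keeps the output within 5% of the reference); the gain field is smooth,
    seeded Gaussian noise.  With ``perturbation = 0`` the mock is bitwise
    identical to the reference beamformer.
    """
    if not (0.0 <= perturbation <= 0.05):
        raise ValidationError("perturbation must lie in [0, 0.05]")

    def fn(data: ChannelData, geom: ArrayGeometry, grid: ImagingGrid) -> EnvelopeImage:
        env = beamform_das(data, geom, grid, cfg)
        if perturbation == 0.0:
            return env
        rng = np.random.default_rng(seed)
        rough = rng.standard_normal(grid.shape)
        smooth = gaussian_filter(rough, sigma=4.0)
        peak = np.abs(smooth).max()
        gain = 1.0 + perturbation * (smooth / peak if peak > 0 else smooth)
        values = env.values * gain
        vmax = values.max()
        if vmax > 0:
            values = values / vmax
        return EnvelopeImage(values=values, normalization_max=env.normalization_max)

    return NetworkUnderTest(fn=fn, name=name, declared_params=None)


def mock_memorizer_net(
    stored_images: Sequence[EnvelopeImage],
    blend_rule: str = "first",
    name: str = "memorizer-mock",
) -> NetworkUnderTest:
    """An overfit network: ignores its input and replays a stored image.

    ``blend_rule='first'`` always returns the first stored image;
    ``'mean'`` returns the fixed renormalized pixel-wise mean of the store.
    Either way the output is identical across all probes, emulating a
    network that reproduces its training data regardless of input.
    """
    if not stored_images:
        raise ValidationError("stored_images must be non-empty")
    if blend_rule not in ("first", "mean"):
        raise ValidationError(f"unknown blend_rule {blend_rule!r}")
    if blend_rule == "first":
        fixed = stored_images[0]
    else:
        stack = np.mean([img.values for img in stored_images], axis=0)
        peak = stack.max()
        fixed = EnvelopeImage(values=stack / peak if peak > 0 else stack)

    def fn(data: ChannelData, geom: ArrayGeometry, grid: ImagingGrid) -> EnvelopeImage:
        return fixed

    return NetworkUnderTest(fn=fn, name=name, declared_params=None)
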