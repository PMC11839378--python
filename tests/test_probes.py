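import numpy as np
import pytest

import beamprobe as bp
from beamprobe.errors import ContractViolationError, ValidationError
from beamprobe.probes import round_half_away


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected",
        [(6.4, 6), (6.5, 7), (6.6, 7), (0.0, 0), (0.5, 1), (12.8, 13), (128.0, 128)],
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestRemoveChannels:
    @pytest.fixture()
    def data(self, small_cfg):
        rng = np.random.default_rng(0)
        return bp.ChannelData(
            samples=rng.normal(size=(64, 1024)),
            sampling_rate=small_cfg.sampling_rate,
            sound_speed=small_cfg.sound_speed,
        )

    def test_zero_fraction_unchanged(self, data):
        out, removed = bp.remove_channels(data, 0.0)
        assert removed == frozenset()
        np.testing.assert_array_equal(out.samples, data.samples)

    def test_five_percent_of_128_removes_six(self):
        d = bp.ChannelData(
            samples=np.ones((128, 64)), sampling_rate=1e7, sound_speed=1540.0
        )
        _, removed = bp.remove_channels(d, 0.05)
        assert len(removed) == 6  # round(6.4) = 6

    def test_removed_rows_hold_replacement_value(self, data):
        out, removed = bp.remove_channels(data, 0.25)
        assert len(removed) == 16
        for e in removed:
            np.testing.assert_array_equal(out.samples[e], 1e-20)
        kept = sorted(set(range(64)) - removed)
        np.testing.assert_array_equal(out.samples[kept], data.samples[kept])

    def test_full_removal_equals_zeros_probe(self, data):
        out, removed = bp.remove_channels(data, 1.0)
        assert removed == frozenset(range(64))
        spec = bp.ArtificialInputSpec(kind="zeros", shape=(64, 1024))
        np.testing.assert_array_equal(out.samples, bp.make_zeros_input(spec).samples)

    @pytest.mark.parametrize("fraction", [-0.1, 1.1])
    def test_out_of_range_fraction_rejected(self, data, fraction):
        with pytest.raises(ValidationError):
            bp.remove_channels(data, fraction)

    def test_seeded_selection_reproducible(self, data):
        p = bp.RemovalProtocol(seed=11)
        _, r1 = bp.remove_channels(data, 0.5, p)
        _, r2 = bp.remove_channels(data, 0.5, p)
        assert r1 == r2


class TestRemovalSweep:
    def test_default_fraction_ladder(self):
        fr = bp.RemovalProtocol().fractions
        assert len(fr) == 21
        assert fr[0] == 0.0 and fr[-1] == 1.0
        np.testing.assert_allclose(np.diff(fr), 0.05)

    def test_faithful_net_perfect_correlation(self, small_cfg, speckle_base):
        data, _ = speckle_base
        net = bp.mock_faithful_net()
        result = bp.removal_sweep(
            net, data, small_cfg.geometry, small_cfg.grid, bp.RemovalProtocol(seed=3)
        )
        assert len(result.fractions) == 21
        assert all(abs(v - 1.0) < 1e-9 for v in result.ncc_curve)
        assert all(abs(v - 1.0) < 1e-9 for v in result.ssim_curve)

    def test_nested_sets_form_a_chain(self, small_cfg, speckle_base):
        data, _ = speckle_base
        net = bp.mock_faithful_net()
        result = bp.removal_sweep(
            net, data, small_cfg.geometry, small_cfg.grid,
            bp.RemovalProtocol(seed=3, nested=True),
        )
        for a, b in zip(result.removed_elements, result.removed_elements[1:]):
            assert a <= b
        counts = [len(s) for s in result.removed_elements]
        assert counts == [round_half_away(f * 64) for f in result.fractions]

    def test_sweep_seed_determinism_bitwise(self, small_cfg, speckle_base):
        data, _ = speckle_base
        net = bp.mock_faithful_net()
        a = bp.removal_sweep(net, data, small_cfg.geometry, small_cfg.grid,
                             bp.RemovalProtocol(seed=5))
        b = bp.removal_sweep(net, data, small_cfg.geometry, small_cfg.grid,
                             bp.RemovalProtocol(seed=5))
        assert a == b

    def test_non_nested_draws_need_not_chain(self, small_cfg, speckle_base):
        data, _ = speckle_base
        net = bp.mock_faithful_net()
        result = bp.removal_sweep(
            net, data, small_cfg.geometry, small_cfg.grid,
            bp.RemovalProtocol(seed=3, nested=False),
        )
        chained = all(
            a <= b
            for a, b in zip(result.removed_elements, result.removed_elements[1:])
        )
        assert not chained  # independent draws of 64 elements will not nest


class TestArtificialProbeProtocol:
    def test_faithful_net_is_perfect_on_every_probe(self, small_cfg):
        specs = [
            bp.ArtificialInputSpec(kind="zeros", shape=(64, 1024)),
            bp.ArtificialInputSpec(kind="ones", shape=(64, 1024)),
            bp.ArtificialInputSpec(kind="gaussian", shape=(64, 1024), seed=0),
        ]
        results = bp.run_artificial_probe(
            bp.mock_faithful_net(), specs, small_cfg.geometry, small_cfg.grid
        )
        assert [r.kind for r in results] == ["zeros", "ones", "gaussian"]
        for r in results:
            assert r.report.l1 == 0.0 and r.report.l2 == 0.0
            assert r.report.ncc == pytest.approx(1.0, abs=1e-12)

    def test_memorizer_ignores_its_input(self, small_cfg, speckle_base):
        _, stored = speckle_base
        net = bp.mock_memorizer_net([stored])
        specs = [
            bp.ArtificialInputSpec(kind="zeros", shape=(64, 1024)),
            bp.ArtificialInputSpec(kind="ones", shape=(64, 1024)),
        ]
        results = bp.run_artificial_probe(
            net, specs, small_cfg.geometry, small_cfg.grid
        )
        np.testing.assert_array_equal(
            results[0].net_image.values, results[1].net_image.values
        )
        assert results[0].report.mean == pytest.approx(stored.values.mean())

    def test_empty_specs_rejected(self, small_cfg):
        with pytest.raises(ValidationError):
            bp.run_artificial_probe(
                bp.mock_faithful_net(), [], small_cfg.geometry, small_cfg.grid
            )

    def test_contract_violation_names_the_network(self, small_cfg):
        bad = bp.NetworkUnderTest(
            fn=lambda d, g, gr: bp.EnvelopeImage(values=np.zeros((2, 2))),
            name="shape-liar",
        )
        specs = [bp.ArtificialInputSpec(kind="zeros", shape=(64, 1024))]
        with pytest.raises(ContractViolationError, match="shape-liar"):
            bp.run_artificial_probe(bad, specs, small_cfg.geometry, small_cfg.grid)


class TestMocks:
    def test_faithful_zero_perturbation_is_reference(self, small_cfg, speckle_base):
        data, _ = speckle_base
        ref = bp.beamform_das(data, small_cfg.geometry, small_cfg.grid)
        out = bp.mock_faithful_net()(data, small_cfg.geometry, small_cfg.grid)
        np.testing.assert_array_equal(out.values, ref.values)

    def test_faithful_gain_field_stays_correlated(self, small_cfg, speckle_base):
        data, _ = speckle_base
        ref = bp.beamform_das(data, small_cfg.geometry, small_cfg.grid)
        out = bp.mock_faithful_net(perturbation=0.05, seed=1)(
            data, small_cfg.geometry, small_cfg.grid
        )
        assert bp.ncc(ref, out) >= 0.99

    def test_faithful_perturbation_bound_enforced(self):
        with pytest.raises(ValidationError):
            bp.mock_faithful_net(perturbation=0.2)

    def test_memorizer_requires_store(self):
        with pytest.raises(ValidationError):
            bp.mock_memorizer_net([])

    def test_memorizer_mean_blend(self, small_cfg, speckle_base):
        _, stored = speckle_base
        other = bp.EnvelopeImage(values=np.zeros(stored.values.shape))
        net = bp.mock_memorizer_net([stored, other], blend_rule="mean")
        out = net(
            bp.make_zeros_input(
                bp.ArtificialInputSpec(kind="zeros", shape=(64, 1024)), small_cfg
            ),
            small_cfg.geometry,
            small_cfg.grid,
        )
        assert out.values.max() == pytest.approx(1.0)
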