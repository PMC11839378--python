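import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from skimage.metrics import structural_similarity as skimage_ssim

import beamprobe as bp
from beamprobe.errors import ValidationError, ZeroVarianceError
from beamprobe.metrics import MetricConfig


# ---------------------------------------------------------------------------
# Independent brute-force oracles: explicit loops, no vectorized shortcuts.
# ---------------------------------------------------------------------------

def oracle_l1(x, y):
    total = 0.0
    for a, b in zip(x.ravel(), y.ravel()):
        total += abs(a - b)
    return total / x.size


def oracle_l2(x, y):
    total = 0.0
    for a, b in zip(x.ravel(), y.ravel()):
        total += (a - b) ** 2
    return total / x.size


def oracle_ncc(x, y):
    xf, yf = x.ravel(), y.ravel()
    mx = sum(xf) / len(xf)
    my = sum(yf) / len(yf)
    num = sxx = syy = 0.0
    for a, b in zip(xf, yf):
        num += (a - mx) * (b - my)
        sxx += (a - mx) ** 2
        syy += (b - my) ** 2
    return num / math.sqrt(sxx * syy)


def oracle_ssim_global(x, y, c1, c2):
    xf, yf = x.ravel(), y.ravel()
    n = len(xf)
    mx, my = sum(xf) / n, sum(yf) / n
    vx = sum((a - mx) ** 2 for a in xf) / n
    vy = sum((b - my) ** 2 for b in yf) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(xf, yf)) / n
    return ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )


def oracle_ssim_windowed(x, y, cfg: MetricConfig):
    """Per-window loop: Gaussian-weighted stats over every interior window."""
    r = cfg.window // 2
    k1d = np.exp(-((np.arange(cfg.window) - r) ** 2) / (2 * cfg.sigma**2))
    k1d /= k1d.sum()
    w = np.outer(k1d, k1d)
    c1, c2 = cfg.c1, cfg.c2
    vals = []
    for i in range(r, x.shape[0] - r):
        for j in range(r, x.shape[1] - r):
            px = x[i - r : i + r + 1, j - r : j + r + 1]
            py = y[i - r : i + r + 1, j - r : j + r + 1]
            mx = float((w * px).sum())
            my = float((w * py).sum())
            vx = float((w * px * px).sum()) - mx**2
            vy = float((w * py * py).sum()) - my**2
            cov = float((w * px * py).sum()) - mx * my
            vals.append(
                ((2 * mx * my + c1) * (2 * cov + c2))
                / ((mx**2 + my**2 + c1) * (vx + vy + c2))
            )
    return float(np.mean(vals))


def random_pair(rng, shape=(9, 7)):
    return rng.uniform(0, 1, shape), rng.uniform(0, 1, shape)


class TestMeanStd:
    def test_all_ones(self):
        assert bp.image_mean_std(np.ones((4, 4))) == (1.0, 0.0)

    def test_binary_population_std(self):
        m, s = bp.image_mean_std(np.array([[0.0, 1.0]]))
        assert (m, s) == (0.5, 0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            bp.image_mean_std(np.empty((0, 0)))


class TestLosses:
    def test_identity_and_closed_form(self):
        x = np.array([[0.0, 1.0]])
        y = np.array([[1.0, 1.0]])
        assert bp.l1_loss(x, x) == 0.0 and bp.l2_loss(x, x) == 0.0
        assert bp.l1_loss(x, y) == 0.5
        assert bp.l2_loss(x, y) == 0.5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            bp.l1_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            x, y = random_pair(rng)
            assert bp.l1_loss(x, y) == pytest.approx(oracle_l1(x, y), abs=1e-12)
            assert bp.l2_loss(x, y) == pytest.approx(oracle_l2(x, y), abs=1e-12)

    @given(
        x=arrays(np.float64, (3, 4), elements=st.floats(0, 1)),
        y=arrays(np.float64, (3, 4), elements=st.floats(0, 1)),
        z=arrays(np.float64, (3, 4), elements=st.floats(0, 1)),
    )
    def test_metric_axioms(self, x, y, z):
        """Symmetry, identity of indiscernibles, ℓ1 triangle inequality."""
        assert bp.l1_loss(x, y) == bp.l1_loss(y, x)
        assert bp.l2_loss(x, y) == bp.l2_loss(y, x)
        assert (bp.l1_loss(x, y) == 0.0) == bool(np.array_equal(x, y))
        assert bp.l1_loss(x, z) <= bp.l1_loss(x, y) + bp.l1_loss(y, z) + 1e-12


class TestNcc:
    def test_affine_invariance(self, rng):
        x, _ = random_pair(rng)
        assert bp.ncc(x, 3.0 * x + 0.2) == pytest.approx(1.0, abs=1e-12)
        assert bp.ncc(x, -2.0 * x + 1.0) == pytest.approx(-1.0, abs=1e-12)

    def test_exact_anticorrelation(self):
        assert bp.ncc(np.array([[1.0, 2.0, 3.0]]), np.array([[3.0, 2.0, 1.0]])) == \
            pytest.approx(-1.0, abs=1e-15)

    def test_matches_pearson_oracle(self, rng):
        for _ in range(10):
            x, y = random_pair(rng)
            assert bp.ncc(x, y) == pytest.approx(oracle_ncc(x, y), abs=1e-12)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ZeroVarianceError):
            bp.ncc(np.full((3, 3), 0.5), np.ones((3, 3)))

    def test_range(self, rng):
        for _ in range(20):
            x, y = random_pair(rng, (5, 5))
            assert -1.0 <= bp.ncc(x, y) <= 1.0


class TestSsim:
    def test_identity_both_modes(self, rng):
        x = rng.uniform(0, 1, (16, 16))
        assert bp.ssim(x, x) == pytest.approx(1.0, abs=1e-9)
        assert bp.ssim(x, x, MetricConfig(ssim_mode="global")) == \
            pytest.approx(1.0, abs=1e-9)

    def test_global_closed_form_example(self):
        """Constant-zero vs half-bright image: SSIM collapses to ~1.43e-6."""
        x = np.array([[0.0, 0.0, 1.0, 1.0]])
        y = np.zeros((1, 4))
        val = bp.ssim(x, y, MetricConfig(ssim_mode="global"))
        assert val == pytest.approx(1.434e-6, rel=1e-3)
        assert val == pytest.approx(oracle_ssim_global(x, y, 1e-4, 9e-4), rel=1e-12)

    def test_windowed_matches_window_loop_oracle(self, rng):
        cfg = MetricConfig()
        for _ in range(5):
            x, y = random_pair(rng, (15, 13))
            assert bp.ssim(x, y, cfg) == pytest.approx(
                oracle_ssim_windowed(x, y, cfg), abs=1e-9
            )

    def test_windowed_matches_reference_library(self, rng):
        """Cross-check against scikit-image's Gaussian-weighted SSIM."""
        for _ in range(5):
            x, y = random_pair(rng, (32, 24))
            ours = bp.ssim(x, y)
            theirs = skimage_ssim(
                x, y, win_size=11, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False, data_range=1.0,
            )
            assert ours == pytest.approx(theirs, abs=1e-7)

    def test_symmetry(self, rng):
        x, y = random_pair(rng, (14, 14))
        assert bp.ssim(x, y) == pytest.approx(bp.ssim(y, x), abs=1e-12)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValidationError):
            bp.ssim(np.zeros((5, 5)), np.zeros((5, 5)))

    def test_bad_config(self):
        with pytest.raises(ValidationError):
            MetricConfig(window=10)
        with pytest.raises(ValidationError):
            MetricConfig(ssim_k1=0.0)


class TestComputeReport:
    def test_report_bundles_all_metrics(self, rng):
        x, y = random_pair(rng, (16, 16))
        r = bp.compute_report(x, y)
        assert r.n_pixels == 256
        assert r.l1 == bp.l1_loss(x, y)
        assert r.l2 == bp.l2_loss(x, y)
        assert r.ncc == bp.ncc(x, y)
        assert r.ssim == bp.ssim(x, y)
        assert (r.mean, r.std) == bp.image_mean_std(y)
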