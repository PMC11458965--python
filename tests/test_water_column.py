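"""Attenuation-ratio estimation and depth-invariant indices."""

from itertools import combinations

import numpy as np
import pytest

from reefchange.preprocessing import preprocess_scene
from reefchange.synthetic import CLASS_CODES, VISIBLE_BANDS
from reefchange.water_column import (
    attenuation_ratio,
    band_pair_stats,
    build_dii_stack,
    depth_invariant_index,
)


def _log_normal_pixels(slope: float, n: int = 20, seed: int = 0):
    """Corrected radiances whose logs satisfy ln(Y) = slope * ln(X)."""
    rng = np.random.default_rng(seed)
    lx = rng.normal(0.0, 1.0, n)
    return np.exp(lx), np.exp(slope * lx)


class TestBandPairStats:
    def test_proportional_logs_brute_force(self):
        # oracle: explicit sample-moment sums over the 20 listed numbers
        x, y = _log_normal_pixels(0.5)
        stats = band_pair_stats(x, y, np.ones(20, bool))
        lx, ly = np.log(x), np.log(y)
        n = len(lx)
        var_x = np.sum((lx - lx.mean()) ** 2) / (n - 1)
        cov_xy = np.sum((lx - lx.mean()) * (ly - ly.mean())) / (n - 1)
        assert stats.var_i == pytest.approx(var_x, rel=1e-12)
        assert stats.cov == pytest.approx(cov_xy, rel=1e-12)
        assert stats.cov == pytest.approx(0.5 * stats.var_i, rel=1e-12)

    def test_identical_bands(self):
        x, _ = _log_normal_pixels(1.0)
        stats = band_pair_stats(x, x, np.ones(20, bool))
        assert stats.var_i == pytest.approx(stats.var_j)
        assert stats.cov == pytest.approx(stats.var_i)
        est = attenuation_ratio(stats)
        assert est.a == pytest.approx(0.0, abs=1e-12)
        assert est.ratio == pytest.approx(1.0, rel=1e-12)

    def test_constant_band_rejected(self):
        x = np.full(20, 2.0)
        stats = band_pair_stats(x, x, np.ones(20, bool))
        with pytest.raises(ValueError, match="zero covariance"):
            attenuation_ratio(stats)

    def test_too_few_pixels(self):
        x, y = _log_normal_pixels(0.5, n=5)
        with pytest.raises(ValueError, match="calibration pixels"):
            band_pair_stats(x, y, np.ones(5, bool))

    def test_nonpositive_pixels_rejected(self):
        x = np.linspace(-1, 1, 20)
        with pytest.raises(ValueError, match="positive"):
            band_pair_stats(x, np.abs(x) + 1, np.ones(20, bool))


class TestAttenuationRatio:
    def test_closed_form_single_bottom(self):
        # one bottom type at varying depth: ln(L-Ls) = const - f*k*z,
        # so the moment formula returns ki/kj exactly (a = 0.75 -> ratio 2)
        ki, kj, f = 0.10, 0.05, 2.0
        z = np.linspace(0.5, 12.0, 50)
        ci = 0.8 * np.exp(-f * ki * z)
        cj = 0.6 * np.exp(-f * kj * z)
        est = attenuation_ratio(band_pair_stats(ci, cj, np.ones(50, bool)))
        assert est.a == pytest.approx(0.75, rel=1e-12)
        assert est.ratio == pytest.approx(2.0, rel=1e-12)

    def test_swap_antisymmetry(self):
        x, y = _log_normal_pixels(0.7, seed=4)
        fwd = attenuation_ratio(band_pair_stats(x, y, np.ones(20, bool)))
        rev = attenuation_ratio(band_pair_stats(y, x, np.ones(20, bool)))
        assert rev.a == pytest.approx(-fwd.a, rel=1e-12)
        assert fwd.ratio * rev.ratio == pytest.approx(1.0, rel=1e-12)

    def test_ratio_identity(self):
        x, y = _log_normal_pixels(0.3, seed=9)
        est = attenuation_ratio(band_pair_stats(x, y, np.ones(20, bool)))
        assert est.ratio == pytest.approx(est.a + np.sqrt(est.a**2 + 1), rel=1e-15)
        assert est.ratio > 0


class TestDepthInvariantIndex:
    def test_equal_inputs_unit_ratio(self):
        c = np.full((5, 5), 3.0)
        np.testing.assert_allclose(depth_invariant_index(c, c, 1.0), 0.0)

    def test_arithmetic_example(self):
        out = depth_invariant_index(np.array([[2.0]]), np.array([[4.0]]), 0.5)
        assert out[0, 0] == pytest.approx(np.log(2) - 0.5 * np.log(4), abs=1e-15)

    def test_validity_propagation(self):
        ci = np.array([[1.0, -1.0], [2.0, 3.0]])
        cj = np.array([[1.0, 1.0], [0.0, 3.0]])
        out = depth_invariant_index(ci, cj, 1.0)
        assert np.isnan(out[0, 1]) and np.isnan(out[1, 0])
        assert np.isfinite(out[0, 0]) and np.isfinite(out[1, 1])


class TestOnSyntheticScenes:
    def test_exact_ratio_recovery_noiseless(self, noiseless_pair, noiseless_params):
        _, pair = noiseless_pair
        stack = build_dii_stack(pair.scene1, pair.truth1 == CLASS_CODES["sand"])
        for (i, j), est in stack.provenance.items():
            truth = noiseless_params.attenuation_ratio(i, j)
            assert est.ratio == pytest.approx(truth, rel=1e-9)

    def test_depth_invariance_noiseless(self, noiseless_pair):
        # same bottom class at any two depths maps to the same DII
        _, pair = noiseless_pair
        stack = build_dii_stack(pair.scene1, pair.truth1 == CLASS_CODES["sand"])
        for code in CLASS_CODES.values():
            sel = (pair.truth1 == code) & stack.valid
            if sel.sum() < 2:
                continue
            for layer in stack.layers.values():
                assert np.var(layer[sel]) <= 1e-18

    def test_within_class_variance_much_below_between(self, noisy_pair):
        _, pair = noisy_pair
        stack = build_dii_stack(
            pair.scene1,
            pair.truth1 == CLASS_CODES["sand"],
            deep_strategy="region",
            deep_region=pair.deep_region,
        )
        for layer in stack.layers.values():
            means, within = [], []
            for code in CLASS_CODES.values():
                sel = (pair.truth1 == code) & stack.valid
                if sel.sum() < 10:
                    continue
                means.append(layer[sel].mean())
                within.append(layer[sel].var())
            # class means spread at least 5x wider than within-class scatter
            assert np.var(means) > 5 * np.mean(within)

    def test_default_pairs_and_single_pair(self, noiseless_pair):
        _, pair = noiseless_pair
        calib = pair.truth1 == CLASS_CODES["sand"]
        stack = build_dii_stack(pair.scene1, calib)
        assert stack.pairs == list(combinations(VISIBLE_BANDS, 2))
        single = build_dii_stack(pair.scene1, calib, pairs=[("green", "red")])
        assert single.pairs == [("green", "red")]

    def test_non_visible_pair_rejected(self, noiseless_pair):
        _, pair = noiseless_pair
        with pytest.raises(ValueError, match="visible"):
            build_dii_stack(
                pair.scene1, pair.truth1 > 0, pairs=[("blue", "nir")]
            )

    def test_dii_antisymmetry_on_scene(self, noiseless_pair):
        # DII_ji = -ratio_ji * DII_ij for the noiseless construction
        _, pair = noiseless_pair
        calib = pair.truth1 == CLASS_CODES["sand"]
        fwd = build_dii_stack(pair.scene1, calib, pairs=[("blue", "green")])
        rev = build_dii_stack(pair.scene1, calib, pairs=[("green", "blue")])
        r_rev = rev.provenance[("green", "blue")].ratio
        sel = fwd.valid & rev.valid
        np.testing.assert_allclose(
            rev.layers[("green", "blue")][sel],
            -r_rev * fwd.layers[("blue", "green")][sel],
            atol=1e-9,
        )
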