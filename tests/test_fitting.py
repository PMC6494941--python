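"""Voxel-wise fitting: thresholds, mono-exponential, IVIM MCMC, derived maps."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mpqmri.fitting import (
    AcquisitionSeries,
    IvimSamplerConfig,
    apply_signal_threshold,
    compute_enhancement,
    compute_fat_fraction,
    estimate_snr,
    fit_ivim_mcmc,
    fit_monoexponential,
    recommend_upper_b,
)


def _series_from_decay(s0, rate, x, kind="dwi"):
    vol = (s0 * np.exp(-rate * np.asarray(x)))[None, None, None, :]
    return AcquisitionSeries(vol, x, kind)


class TestSignalThreshold:
    def test_no_exclusions_when_signal_high(self, rng):
        vol = rng.uniform(50, 100, size=(6, 6, 3, 4))
        series = AcquisitionSeries(vol, [0, 100, 400, 800], "dwi")
        assert not apply_signal_threshold(series, noise_sd=1.0, k=3.0).any()

    def test_exactly_fat_voxels_excluded(self, noiseless_phantom):
        vols, series, _ = noiseless_phantom
        excluded = apply_signal_threshold(series["dwi_adc"], noise_sd=5.0, k=3.0)
        assert np.array_equal(excluded & vols.tumor_mask, vols.fat_mask())

    def test_matches_brute_force_scan(self, rng):
        vol = rng.uniform(0, 30, size=(5, 4, 3, 5))
        series = AcquisitionSeries(vol, [0, 50, 200, 500, 900], "dwi")
        mask = apply_signal_threshold(series, noise_sd=4.0, k=2.0)
        count = 0
        for i in range(5):
            for j in range(4):
                for k in range(3):
                    if vol[i, j, k, 0] < 2.0 * 4.0:
                        count += 1
                        assert mask[i, j, k]
        assert count == int(mask.sum())


class TestMonoexponential:
    def test_two_point_noiseless_adc(self):
        series = _series_from_decay(100.0, 1.70e-3, [50.0, 900.0])
        pmap, diag = fit_monoexponential(series)
        assert pmap.values[0, 0, 0] == pytest.approx(1.70e-3, rel=1e-9)
        assert diag.n_voxels_converged == 1

    def test_constant_signal_gives_zero_rate(self):
        series = _series_from_decay(80.0, 0.0, [0.0, 100.0, 400.0])
        pmap, _ = fit_monoexponential(series)
        assert pmap.values[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert pmap.valid_mask[0, 0, 0]

    def test_six_echo_r2star_matches_loglinear_oracle(self):
        te = np.array([5, 10, 15, 20, 25, 30]) * 1e-3
        series = _series_from_decay(90.0, 18.50, te, kind="gre")
        pmap, _ = fit_monoexponential(series)
        # independent closed-form slope of ln(S) on TE
        y = series.volumes[0, 0, 0]
        tbar = te.mean()
        slope = ((te - tbar) * (np.log(y) - np.log(y).mean())).sum() / ((te - tbar) ** 2).sum()
        assert pmap.values[0, 0, 0] == pytest.approx(-slope, rel=1e-9)
        assert pmap.values[0, 0, 0] == pytest.approx(18.50, rel=1e-9)

    def test_all_zero_voxel_invalidated_not_fatal(self):
        vol = np.zeros((1, 2, 1, 3))
        vol[0, 0, 0] = 50 * np.exp(-1e-3 * np.array([0, 400, 800]))
        series = AcquisitionSeries(vol, [0, 400, 800], "dwi")
        pmap, diag = fit_monoexponential(series)
        assert pmap.valid_mask[0, 0, 0] and not pmap.valid_mask[0, 1, 0]
        assert diag.n_voxels_attempted == 2
        assert diag.n_voxels_converged == 1 and diag.n_voxels_failed == 1

    def test_min_encoding_drops_low_b(self):
        b = np.array([0.0, 50.0, 400.0, 900.0])
        series = _series_from_decay(100.0, 1.2e-3, b)
        pmap, _ = fit_monoexponential(series, min_encoding=50.0)
        assert pmap.values[0, 0, 0] == pytest.approx(1.2e-3, rel=1e-9)


def _ivim_grid_oracle(b, y, d_grid, f_grid, ds_grid):
    """Exhaustive grid-search least squares with S0 profiled analytically."""
    best = (np.inf, None)
    for d in d_grid:
        for f in f_grid:
            for ds in ds_grid:
                if ds <= d:
                    continue
                m = (1 - f) * np.exp(-b * d) + f * np.exp(-b * ds)
                s0 = (y * m).sum() / (m * m).sum()
                sse = ((s0 * m - y) ** 2).sum()
                if sse < best[0]:
                    best = (sse, (d, f, ds))
    return best[1]


class TestIvimMcmc:
    B = np.array([0.0, 50.0, 100.0, 200.0, 400.0, 600.0, 900.0])

    def _series(self, d, f, ds, s0=100.0):
        sig = s0 * ((1 - f) * np.exp(-self.B * d) + f * np.exp(-self.B * ds))
        vol = np.tile(sig, (2, 2, 1, 1))
        return AcquisitionSeries(vol, self.B, "dwi")

    def test_f_zero_reduces_to_monoexponential(self):
        series = self._series(1.4e-3, 0.0, 40e-3)
        maps, _ = fit_ivim_mcmc(series, config=IvimSamplerConfig(seed=3))
        adc, _ = fit_monoexponential(series)
        sel = maps["D"].valid_mask
        assert sel.any()
        assert np.allclose(maps["D"].values[sel], adc.values[sel], rtol=1e-3)
        assert np.all(maps["f"].values[sel] < 0.01)

    def test_noiseless_recovery_and_grid_oracle(self):
        d, f, ds = 1.65e-3, 0.0685, 41.36e-3
        series = self._series(d, f, ds)
        maps, diag = fit_ivim_mcmc(series, config=IvimSamplerConfig(seed=4))
        sel = maps["D"].valid_mask
        assert sel.any()
        assert np.allclose(maps["D"].values[sel], d, rtol=0.05)
        assert np.allclose(maps["f"].values[sel], f, rtol=0.20)
        assert np.allclose(maps["Dstar"].values[sel], ds, rtol=0.20)
        # independent exhaustive grid oracle on one voxel
        y = series.volumes[0, 0, 0]
        od, of, ods = _ivim_grid_oracle(
            self.B, y,
            np.linspace(1.0e-3, 2.5e-3, 40),
            np.linspace(0.0, 0.2, 30),
            np.geomspace(10e-3, 120e-3, 40),
        )
        i = tuple(np.argwhere(sel)[0])
        assert maps["D"].values[i] == pytest.approx(od, rel=0.05)
        assert maps["f"].values[i] == pytest.approx(of, rel=0.25)
        assert maps["Dstar"].values[i] == pytest.approx(ods, rel=0.25)

    def test_same_seed_reproducible(self):
        series = self._series(1.2e-3, 0.08, 30e-3)
        cfg = IvimSamplerConfig(seed=11, n_steps=1200, n_burn=400)
        a, _ = fit_ivim_mcmc(series, config=cfg)
        b, _ = fit_ivim_mcmc(series, config=cfg)
        for name in ("D", "f", "Dstar"):
            assert np.array_equal(a[name].values, b[name].values)

    def test_too_few_b_values_rejected(self):
        vol = np.ones((2, 2, 1, 3))
        series = AcquisitionSeries(vol, [0.0, 100.0, 500.0], "dwi")
        with pytest.raises(ValueError, match="four distinct"):
            fit_ivim_mcmc(series)

    def test_dstar_exceeds_d_in_posterior(self):
        series = self._series(1.5e-3, 0.05, 25e-3)
        maps, _ = fit_ivim_mcmc(series, config=IvimSamplerConfig(seed=5, n_steps=1200, n_burn=400))
        sel = maps["D"].valid_mask
        assert np.all(maps["Dstar"].values[sel] > maps["D"].values[sel])


class TestFatFraction:
    def test_examples(self):
        water = np.full((2, 2, 1), 10.0)
        assert np.all(compute_fat_fraction(np.zeros((2, 2, 1)), water).values == 0.0)
        assert np.all(compute_fat_fraction(water, water).values == 0.5)

    def test_phantom_value_recovered(self):
        ff = 0.8509
        fat, water = np.full((1, 1, 1), 100 * ff), np.full((1, 1, 1), 100 * (1 - ff))
        assert compute_fat_fraction(fat, water).values[0, 0, 0] == pytest.approx(ff)

    def test_zero_sum_invalid_and_shape_mismatch(self):
        pmap = compute_fat_fraction(np.zeros((2, 1, 1)), np.zeros((2, 1, 1)))
        assert not pmap.valid_mask.any()
        with pytest.raises(ValueError, match="congruent"):
            compute_fat_fraction(np.zeros((2, 1, 1)), np.zeros((1, 1, 1)))

    def test_ff_plus_water_fraction_is_one(self, rng):
        fat = rng.uniform(0.1, 50, (4, 4, 2))
        water = rng.uniform(0.1, 50, (4, 4, 2))
        ff = compute_fat_fraction(fat, water)
        wf = compute_fat_fraction(water, fat)
        assert np.allclose(ff.values + wf.values, 1.0)


class TestEnhancement:
    def test_no_change_gives_zero(self):
        pre = np.full((2, 2, 1), 40.0)
        ef, eps = compute_enhancement(pre, pre.copy(), np.ones_like(pre, bool))
        assert ef == 0.0
        assert np.all(eps.values == 0.0)

    def test_four_voxel_example(self):
        pre = np.full((4, 1, 1), 100.0)
        post = np.array([106.0, 104.0, 100.0, 95.0]).reshape(4, 1, 1)
        ef, _ = compute_enhancement(pre, post, np.ones((4, 1, 1), bool))
        assert ef == pytest.approx(25.0)

    def test_fractional_enhancement_formula(self):
        pre = np.full((1, 1, 1), 100.0)
        post = np.full((1, 1, 1), 200.0)
        _, eps = compute_enhancement(pre, post, np.ones((1, 1, 1), bool))
        assert eps.values[0, 0, 0] == pytest.approx(1.0 / 3.0)

    def test_empty_mask_rejected(self):
        pre = np.ones((2, 2, 1))
        with pytest.raises(ValueError, match="empty"):
            compute_enhancement(pre, pre, np.zeros((2, 2, 1), bool))

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_scaling_invariance(self, scale):
        rng = np.random.default_rng(99)
        pre = rng.uniform(10, 100, (3, 3, 2))
        post = pre * rng.uniform(0.9, 1.3, (3, 3, 2))
        mask = np.ones_like(pre, bool)
        ef1, eps1 = compute_enhancement(pre, post, mask)
        ef2, eps2 = compute_enhancement(scale * pre, scale * post, mask)
        assert ef1 == ef2
        assert np.allclose(eps1.values, eps2.values)


class TestSnr:
    @staticmethod
    def _unit_sd_block():
        # two voxels {0, sqrt(2)}: sample SD (ddof=1) exactly 1
        return np.array([0.0, math.sqrt(2.0)])

    def test_unit_noise_sd_example(self):
        vol = np.zeros((20, 20, 1))
        tumor = np.zeros_like(vol, bool)
        vol[5:10, 5:10, 0] = 100.0
        tumor[5:10, 5:10, 0] = True
        na = np.zeros_like(vol, bool)
        nb = np.zeros_like(vol, bool)
        na[0, :2, 0] = True
        nb[19, :2, 0] = True
        vol[0, :2, 0] = self._unit_sd_block()
        vol[19, :2, 0] = self._unit_sd_block()
        assert estimate_snr(vol, tumor, (na, nb)) == pytest.approx(66.0)

    def test_mean_over_slices(self):
        vol = np.zeros((20, 20, 2))
        tumor = np.zeros_like(vol, bool)
        na = np.zeros_like(vol, bool)
        nb = np.zeros_like(vol, bool)
        for z, s_tumor in ((0, 60 / 0.66), (1, 72 / 0.66)):
            vol[5:10, 5:10, z] = s_tumor
            tumor[5:10, 5:10, z] = True
            vol[0, :2, z] = self._unit_sd_block()
            vol[19, :2, z] = self._unit_sd_block()
            na[0, :2, z] = True
            nb[19, :2, z] = True
        assert estimate_snr(vol, tumor, (na, nb)) == pytest.approx(66.0)

    def test_zero_noise_sd_rejected(self):
        vol = np.zeros((8, 8, 1))
        tumor = np.zeros_like(vol, bool)
        tumor[3:5, 3:5, 0] = True
        vol[tumor] = 50.0
        na = np.zeros_like(vol, bool)
        nb = np.zeros_like(vol, bool)
        na[0, :4, 0] = True
        nb[7, :4, 0] = True
        with pytest.raises(ValueError, match="zero noise"):
            estimate_snr(vol, tumor, (na, nb))


class TestRecommendUpperB:
    @pytest.mark.parametrize(
        "adc,expected", [(0.95e-3, 1158), (2.77e-3, 397), (1.1e-3, 1000)]
    )
    def test_design_rule(self, adc, expected):
        assert recommend_upper_b(adc) == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            recommend_upper_b(0.0)
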