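"""Phantom generator: geometry, signal models, noise and simulators."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpqmri.phantom import (
    DEFAULT_TISSUE_CLASSES,
    EllipsoidRegion,
    PhantomSpec,
    RepeatCohortSpec,
    add_rician_noise,
    generate_phantom,
    simulate_histology_table,
    simulate_repeat_cohort,
    synthesize_acquisitions,
)


def _single_class_spec(label="cellular", **overrides):
    params = dataclasses.replace(DEFAULT_TISSUE_CLASSES[label], **overrides)
    return PhantomSpec(
        grid_shape=(16, 16, 6),
        tumor_geometry=(EllipsoidRegion((8, 8, 3), (5, 5, 2), label),),
        class_assignment={label: params},
        noise_sigma=0.0,
        target_snr=None,
    )


class TestGeneratePhantom:
    def test_single_class_adc_constant(self):
        vols = generate_phantom(_single_class_spec(ADC_true=1.70e-3))
        assert vols.tumor_mask.any()
        assert np.all(vols.truth["ADC"][vols.tumor_mask] == 1.70e-3)
        assert np.all(vols.truth["ADC"][~vols.tumor_mask] == 0.0)

    def test_empty_geometry_gives_background(self):
        spec = PhantomSpec(grid_shape=(8, 8, 4), tumor_geometry=(), noise_sigma=0.0, target_snr=None)
        vols = generate_phantom(spec)
        assert not vols.tumor_mask.any()
        assert vols.slice_masks() == {}
        assert all(np.all(v == 0) for v in vols.truth.values())

    def test_two_disjoint_regions_bimodal_ff(self):
        fat = dataclasses.replace(DEFAULT_TISSUE_CLASSES["fat"], FF_true=0.85)
        cell = dataclasses.replace(DEFAULT_TISSUE_CLASSES["cellular"], FF_true=0.05)
        spec = PhantomSpec(
            grid_shape=(24, 16, 6),
            tumor_geometry=(
                EllipsoidRegion((6, 8, 3), (3, 3, 2), "fat"),
                EllipsoidRegion((17, 8, 3), (3, 3, 2), "cellular"),
            ),
            class_assignment={"fat": fat, "cellular": cell},
            noise_sigma=0.0,
            target_snr=None,
        )
        vols = generate_phantom(spec)
        assert set(np.unique(vols.truth["FF"][vols.tumor_mask])) == {0.05, 0.85}

    def test_conflicting_overlap_rejected(self):
        spec = PhantomSpec(
            grid_shape=(16, 16, 6),
            tumor_geometry=(
                EllipsoidRegion((8, 8, 3), (4, 4, 2), "fat"),
                EllipsoidRegion((9, 8, 3), (4, 4, 2), "cellular"),
            ),
            noise_sigma=0.0,
            target_snr=None,
        )
        with pytest.raises(ValueError, match="overlap"):
            generate_phantom(spec)

    def test_region_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            PhantomSpec(
                grid_shape=(8, 8, 4),
                tumor_geometry=(EllipsoidRegion((7, 4, 2), (4, 2, 1), "cellular"),),
                noise_sigma=0.0,
                target_snr=None,
            )

    def test_slice_masks_cover_tumor(self):
        vols = generate_phantom(_single_class_spec())
        rebuilt = np.zeros_like(vols.tumor_mask)
        for z, m in vols.slice_masks().items():
            rebuilt[:, :, z] = m
        assert np.array_equal(rebuilt, vols.tumor_mask)


class TestSynthesizeAcquisitions:
    def test_ivim_signal_matches_scalar_formula(self):
        # direct independent evaluation of the two-compartment sum
        d, f, dstar, s0, b = 1.65e-3, 0.0685, 41.36e-3, 100.0, 900.0
        cell = dataclasses.replace(
            DEFAULT_TISSUE_CLASSES["cellular"], S0=s0, D_true=d, f_true=f, Dstar_true=dstar
        )
        vols = generate_phantom(_single_class_spec())
        vols.truth["S0"][vols.tumor_mask] = s0
        vols.truth["D"][vols.tumor_mask] = d
        vols.truth["f"][vols.tumor_mask] = f
        vols.truth["Dstar"][vols.tumor_mask] = dstar
        series = synthesize_acquisitions(vols, b_values=(0.0, 50.0, 400.0, 900.0))
        expected = s0 * ((1 - f) * math.exp(-b * d) + f * math.exp(-b * dstar))
        got = series["dwi_ivim"].volumes[vols.tumor_mask][:, -1]
        assert np.allclose(got, expected, rtol=1e-12)

    def test_b_zero_returns_s0(self, noiseless_phantom):
        vols, series, _ = noiseless_phantom
        nonfat = vols.tumor_mask & ~vols.fat_mask()
        assert np.allclose(
            series["dwi_ivim"].volumes[nonfat][:, 0], vols.truth["S0"][nonfat]
        )

    def test_f_zero_is_monoexponential(self):
        vols = generate_phantom(_single_class_spec(f_true=0.0))
        b = np.array([0.0, 100.0, 500.0, 900.0])
        series = synthesize_acquisitions(vols, b_values=b)
        sig = series["dwi_ivim"].volumes[vols.tumor_mask][0]
        d = DEFAULT_TISSUE_CLASSES["cellular"].D_true
        assert np.allclose(sig, sig[0] * np.exp(-b * d), rtol=1e-12)

    def test_fat_suppression_attenuates_dwi_and_gre_only(self, noiseless_phantom):
        vols, series, _ = noiseless_phantom
        fat = vols.fat_mask()
        s0_fat = vols.truth["S0"][fat]
        assert np.allclose(series["dwi_adc"].volumes[fat][:, 0], 0.05 * s0_fat)
        assert series["dixon"].volumes[fat].sum(axis=-1) == pytest.approx(s0_fat)

    def test_duplicate_encodings_rejected(self, noiseless_phantom):
        vols, _, _ = noiseless_phantom
        with pytest.raises(ValueError, match="strictly increasing"):
            synthesize_acquisitions(vols, b_values=(0.0, 100.0, 100.0, 500.0))


class TestRicianNoise:
    def test_sigma_zero_is_identity(self, rng):
        x = rng.random((5, 5, 5))
        assert np.array_equal(add_rician_noise(x, 0.0), x)

    def test_background_mean_is_rayleigh(self):
        # E[magnitude | S = 0] = sigma * sqrt(pi / 2); SD = sigma * sqrt(2 - pi/2)
        sigma, n = 2.0, 100_000
        bg = add_rician_noise(np.zeros(n), sigma, seed=42)
        se = sigma * math.sqrt(2 - math.pi / 2) / math.sqrt(n)
        assert abs(bg.mean() - sigma * math.sqrt(math.pi / 2)) < 3 * se

    def test_high_snr_mean(self):
        s, sigma, n = 100.0, 2.0, 100_000
        noisy = add_rician_noise(np.full(n, s), sigma, seed=43)
        se = sigma / math.sqrt(n)
        assert abs(noisy.mean() - math.sqrt(s**2 + sigma**2)) < 3 * se

    def test_reproducible_under_seed(self):
        x = np.ones((4, 4))
        assert np.array_equal(add_rician_noise(x, 1.0, seed=7), add_rician_noise(x, 1.0, seed=7))


class TestRepeatCohort:
    def test_zero_within_subject_sd_gives_identical_baselines(self):
        df = simulate_repeat_cohort(RepeatCohortSpec(n_patients=10, s_w_true=0.0, seed=1))
        assert np.allclose(df["baseline1"], df["baseline2"])

    def test_within_subject_log_sd_recovered(self):
        spec = RepeatCohortSpec(n_patients=20_000, s_w_true=0.05, seed=2)
        df = simulate_repeat_cohort(spec)
        d = np.log(df["baseline2"]) - np.log(df["baseline1"])
        s_w = math.sqrt(float((d**2).sum()) / (2 * len(d)))
        assert s_w == pytest.approx(0.05, rel=0.03)

    def test_treatment_effect_shifts_post(self):
        spec = RepeatCohortSpec(n_patients=5000, s_w_true=0.02, treatment_effect_log=0.1, seed=3)
        df = simulate_repeat_cohort(spec)
        shift = np.log(df["post_rt"]) - np.log(df["true_value"])
        assert shift.mean() == pytest.approx(0.1, abs=0.01)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            RepeatCohortSpec(n_patients=1)


class TestHistologyTable:
    def test_perfect_negative_coupling(self):
        # a consistent target triple collapses the NSR latent onto -z_ADC
        rho_d = -6 / math.pi * math.asin(0.45)
        df = simulate_histology_table(n_rois=60, rho_adc=-1.0, rho_d=rho_d, seed=5)
        rho = stats.spearmanr(df["ADC"], df["nuclear_to_stromal_ratio"]).statistic
        assert rho == pytest.approx(-1.0)

    def test_infeasible_coupling_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            simulate_histology_table(n_rois=30, rho_adc=-1.0, rho_d=0.9)

    def test_reproducible_and_schema(self):
        a = simulate_histology_table(n_rois=3, seed=9)
        b = simulate_histology_table(n_rois=3, seed=9)
        pd.testing.assert_frame_equal(a, b)
        assert (a.groupby("tumor_id").size() <= 3).all()
        fibrous = a["stroma_type"] == "fibrous"
        assert (a.loc[fibrous, "fibrous_grade"] >= 1).all()
        assert (a.loc[~fibrous, "fibrous_grade"] == 0).all()

    def test_minimum_rois(self):
        with pytest.raises(ValueError, match="at least 3"):
            simulate_histology_table(n_rois=2)
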