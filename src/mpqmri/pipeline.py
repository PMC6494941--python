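"""End-to-end reproducible runs: phantom -> acquisitions -> fits -> reports.

A single YAML-configurable entry point sequences the full analysis on a
digital tumor: ground-truth generation, acquisition synthesis with Rician
noise, voxel-wise fitting, VOI summaries, double-baseline repeatability,
pre/post-radiotherapy response and imaging-histology correlation, writing
NIfTI/CSV artifacts plus a JSON manifest that fully determines the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import filter_fat_rois, rank_sum_test, spearman_ci
from .fitting import (
    AcquisitionSeries,
    IvimSamplerConfig,
    apply_signal_threshold,
    compute_enhancement,
    compute_fat_fraction,
    fit_ivim_mcmc,
    fit_monoexponential,
)
from .phantom import (
    DEFAULT_B_VALUES,
    DEFAULT_ECHO_TIMES,
    PhantomSpec,
    RepeatCohortSpec,
    add_rician_noise,
    default_tumor_geometry,
    generate_phantom,
    noise_sigma_for_snr,
    simulate_histology_table,
    simulate_repeat_cohort,
    synthesize_acquisitions,
)
from .repeatability import bland_altman_points, repeatability_metrics
from .response import cohort_response_table
from .voi import VOIMask, classify_fat_dominant, summarize_map

__all__ = ["RunConfig", "run_pipeline", "save_nifti", "load_nifti"]

logger = logging.getLogger(__name__)


def save_nifti(data: np.ndarray, voxel_size, path: Path) -> None:
    affine = np.diag([*voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), tuple(float(z) for z in img.header.get_zooms()[:3])


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; loadable from YAML."""

    out_dir: str = "mpqmri_run"
    seed: int = 0
    grid_shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 5.0)
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES
    target_snr: float | None = 386.0
    noise_sigma: float | None = None
    fat_threshold_k: float = 3.0
    ef_threshold: float = 0.05
    fat_dominance_threshold: float = 0.80
    adc_min_b: float = 50.0
    include_contrast: bool = True
    ivim_steps: int = 2000
    ivim_burn: int = 500
    ivim_chains: int = 3
    cohort_n: int = 27
    cohort_s_w: float = 0.025
    cohort_between_sd: float = 0.2
    treatment_effect_log: float = 0.1
    histology_n_rois: int = 48
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0 < self.ef_threshold < 1 and 0 < self.fat_dominance_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.fat_threshold_k <= 0:
            raise ValueError("fat_threshold_k must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("grid_shape", "voxel_size", "b_values", "echo_times"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def record(path: Path) -> Path:
        artifacts.append(str(path.relative_to(out)))
        return path

    # --- stage 1: phantom -------------------------------------------------
    spec = PhantomSpec(
        grid_shape=config.grid_shape,
        voxel_size=config.voxel_size,
        tumor_geometry=default_tumor_geometry(config.grid_shape),
        noise_sigma=config.noise_sigma,
        target_snr=config.target_snr if config.noise_sigma is None else None,
        seed=config.seed,
    )
    vols = generate_phantom(spec)
    for name, arr in vols.truth.items():
        save_nifti(arr, config.voxel_size, record(out / f"truth_{name}.nii"))
    save_nifti(vols.tumor_mask.astype(float), config.voxel_size, record(out / "tumor_mask.nii"))

    # --- stage 2: acquisitions --------------------------------------------
    series = synthesize_acquisitions(
        vols,
        b_values=config.b_values,
        echo_times=config.echo_times,
        include_contrast=config.include_contrast,
    )
    if config.noise_sigma is not None:
        sigma = config.noise_sigma
    else:
        sigma = noise_sigma_for_snr(series["dwi_adc"], vols.tumor_mask, config.target_snr)
    rng = np.random.default_rng(config.seed)
    noisy = {
        name: add_rician_noise(s, sigma, rng=rng) if sigma > 0 else s
        for name, s in series.items()
    }
    for name, s in noisy.items():
        save_nifti(s.volumes, config.voxel_size, record(out / f"series_{name}.nii"))

    # --- stage 3: voxel-wise fits ------------------------------------------
    threshold_sd = sigma if sigma > 0 else 0.05 * float(vols.truth["S0"].max())
    excluded = apply_signal_threshold(noisy["dwi_adc"], threshold_sd, k=config.fat_threshold_k)
    fit_mask = vols.tumor_mask & ~excluded

    maps = {}
    adc_map, adc_diag = fit_monoexponential(
        noisy["dwi_adc"], fit_mask, min_encoding=config.adc_min_b, parameter="ADC"
    )
    maps["ADC"] = adc_map
    r2_map, r2_diag = fit_monoexponential(noisy["gre"], fit_mask, parameter="R2star")
    maps["R2star"] = r2_map
    ivim_cfg = IvimSamplerConfig(
        n_chains=config.ivim_chains,
        n_steps=config.ivim_steps,
        n_burn=config.ivim_burn,
        seed=config.seed,
        noise_sd=sigma if sigma > 0 else None,
    )
    ivim_maps, ivim_diag = fit_ivim_mcmc(noisy["dwi_ivim"], fit_mask, ivim_cfg)
    maps.update(ivim_maps)
    ff_map = compute_fat_fraction(noisy["dixon"].volumes[..., 0], noisy["dixon"].volumes[..., 1])
    maps["FF"] = ff_map

    ef_pct = None
    if "contrast" in noisy:
        ef_pct, eps_map = compute_enhancement(
            noisy["contrast"].volumes[..., 0],
            noisy["contrast"].volumes[..., 1],
            vols.tumor_mask,
            threshold=config.ef_threshold,
        )
        maps["epsF"] = eps_map
    else:
        logger.info("no contrast pair configured: EF/epsF stage skipped")

    for name, pmap in maps.items():
        save_nifti(pmap.values, config.voxel_size, record(out / f"map_{name}.nii"))
        save_nifti(
            pmap.valid_mask.astype(float), config.voxel_size, record(out / f"map_{name}_valid.nii")
        )
    diag_payload = {
        "ADC": {"attempted": adc_diag.n_voxels_attempted, "converged": adc_diag.n_voxels_converged},
        "R2star": {"attempted": r2_diag.n_voxels_attempted, "converged": r2_diag.n_voxels_converged},
        "IVIM": {
            "attempted": ivim_diag.n_voxels_attempted,
            "converged": ivim_diag.n_voxels_converged,
            "acceptance_rate": ivim_diag.mcmc_acceptance_rate,
            "chain_length": ivim_diag.mcmc_chain_length,
        },
        "n_thresholded_out": int((vols.tumor_mask & excluded).sum()),
    }
    with open(record(out / "fit_diagnostics.json"), "w") as fh:
        json.dump(diag_payload, fh, indent=2, sort_keys=True)

    # --- stage 4: VOI summaries --------------------------------------------
    voi = VOIMask(mask=vols.tumor_mask, voxel_size=config.voxel_size)
    rows = []
    ff_summary = summarize_map(ff_map, voi)
    fat_dominant = classify_fat_dominant(ff_summary, config.fat_dominance_threshold)
    for name, pmap in maps.items():
        if fat_dominant and name in ("ADC", "D", "f", "Dstar", "R2star"):
            logger.info("tumor is >%.0f%% fat: %s summary excluded",
                        100 * config.fat_dominance_threshold, name)
            continue
        s = summarize_map(pmap, voi)
        for stat in ("median", "mean", "sd", "p10", "p25", "p75", "p90",
                     "skew", "kurtosis", "n_voxels", "volume_cm3"):
            rows.append({"parameter": name, "statistic": stat, "value": getattr(s, stat)})
    if ef_pct is not None:
        rows.append({"parameter": "EF", "statistic": "percent", "value": ef_pct})
    _df_to_csv(pd.DataFrame(rows), record(out / "voi_summaries.csv"))

    # --- stage 5: repeatability --------------------------------------------
    cohort = simulate_repeat_cohort(
        RepeatCohortSpec(
            n_patients=config.cohort_n,
            s_w_true=config.cohort_s_w,
            between_patient_log_sd=config.cohort_between_sd,
            seed=config.seed + 1,
        )
    )
    rep = repeatability_metrics(
        cohort["baseline1"], cohort["baseline2"], scale="log_percent", statistic="median_ADC"
    )
    rep_row = {
        "statistic": rep.statistic, "n": rep.n, "s_w": rep.s_w, "cov_pct": rep.cov_pct,
        "loa_upper_pct": rep.loa_upper_pct, "loa_lower_pct": rep.loa_lower_pct,
        "ci_cov_low": rep.ci_cov[0], "ci_cov_high": rep.ci_cov[1],
    }
    _df_to_csv(pd.DataFrame([rep_row]), record(out / "repeatability.csv"))
    _df_to_csv(
        bland_altman_points(cohort["baseline1"], cohort["baseline2"], cohort["patient"]),
        record(out / "bland_altman_points.csv"),
    )

    # --- stage 6: response --------------------------------------------------
    treated = simulate_repeat_cohort(
        RepeatCohortSpec(
            n_patients=14,
            s_w_true=config.cohort_s_w,
            between_patient_log_sd=config.cohort_between_sd,
            treatment_effect_log=config.treatment_effect_log,
            seed=config.seed + 2,
        )
    )
    records = treated.rename(columns={"post_rt": "post_rt"}).assign(statistic="median_ADC")[
        ["patient", "statistic", "baseline1", "baseline2", "post_rt"]
    ]
    report = cohort_response_table(records, loa={"median_ADC": rep})
    _df_to_csv(report.patient_table, record(out / "response_patients.csv"))
    _df_to_csv(report.cohort_table, record(out / "response_cohort.csv"))

    # --- stage 7: correlation ------------------------------------------------
    histo = simulate_histology_table(n_rois=config.histology_n_rois, seed=config.seed + 3)
    _df_to_csv(histo, record(out / "histology_rois.csv"))
    filt = filter_fat_rois(histo, threshold=config.fat_dominance_threshold)
    corr_rows = []
    ln_nsr = np.log(filt.diffusion["nuclear_to_stromal_ratio"].to_numpy())
    for param in ("ADC", "D"):
        res = spearman_ci(filt.diffusion[param].to_numpy(), ln_nsr)
        corr_rows.append({"pair": f"{param}~ln(NSR)", "rho": res.rho, "pvalue": res.pvalue,
                          "ci_low": res.ci_low, "ci_high": res.ci_high, "n": res.n})
    res_ff = spearman_ci(filt.fat["FF"].to_numpy(), filt.fat["histo_fat_fraction"].to_numpy())
    corr_rows.append({"pair": "FF~histo_FF", "rho": res_ff.rho, "pvalue": res_ff.pvalue,
                      "ci_low": res_ff.ci_low, "ci_high": res_ff.ci_high, "n": res_ff.n})
    fib = filt.diffusion[filt.diffusion["stroma_type"] == "fibrous"]
    low = fib[fib["fibrous_grade"].isin([1, 2])]["ADC"]
    high = fib[fib["fibrous_grade"].isin([3, 4, 5])]["ADC"]
    if len(low) and len(high):
        rs = rank_sum_test(low, high)
        corr_rows.append({"pair": "ADC:fibrous_grade_1-2_vs_3-5", "rho": float("nan"),
                          "pvalue": rs.pvalue, "ci_low": float("nan"),
                          "ci_high": float("nan"), "n": rs.n_a + rs.n_b})
    _df_to_csv(pd.DataFrame(corr_rows), record(out / "correlation.csv"))

    # --- manifest -------------------------------------------------------------
    manifest = {
        "mpqmri_version": __version__,
        "numpy_version": np.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "noise_sigma_used": float(sigma),
        "fat_dominant_tumor": bool(fat_dominant),
        "ef_percent": ef_pct,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
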