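"""Digital multi-parametric tumor phantoms and cohort/histology simulators.

Retroperitoneal sarcomas are heterogeneous, with sub-regions of cellular
tumor, myxoid or fibrous stroma, fat and necrosis.  This module builds
piecewise-homogeneous ellipsoidal digital tumors carrying ground-truth
parameter volumes (S0, ADC, IVIM D/f/D*, R2*, fat fraction, contrast
enhancement), synthesises the acquisition series the analysis consumes,
adds Rician magnitude noise, and simulates double-baseline cohorts and
histology-like ROI tables with configurable rank-correlation structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import beta as beta_dist

from .fitting import AcquisitionSeries

__all__ = [
    "TissueClassParams",
    "EllipsoidRegion",
    "PhantomSpec",
    "PhantomVolumes",
    "RepeatCohortSpec",
    "DEFAULT_TISSUE_CLASSES",
    "DEFAULT_B_VALUES",
    "DEFAULT_ECHO_TIMES",
    "default_tumor_geometry",
    "generate_phantom",
    "synthesize_acquisitions",
    "add_rician_noise",
    "noise_sigma_for_snr",
    "simulate_repeat_cohort",
    "simulate_histology_table",
]

CLASS_LABELS = ("cellular", "myxoid", "fibrous", "fat", "necrotic")

#: Default diffusion weightings, s/mm^2.  Covers b = 0 for IVIM and the
#: b = 50 floor used for ADC fitting, up to a high weighting near 1.1/ADC
#: for mid-range tumor diffusivities.
DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 200.0, 400.0, 600.0, 900.0)

#: Default gradient-echo times, seconds (5-30 ms).
DEFAULT_ECHO_TIMES = (5e-3, 10e-3, 15e-3, 20e-3, 25e-3, 30e-3)

TRUTH_FIELDS = ("S0", "ADC", "D", "f", "Dstar", "R2star", "FF", "enhancement")


@dataclass(frozen=True)
class TissueClassParams:
    """Ground-truth parameters of one tissue class.

    Diffusivities in mm^2/s, R2* in 1/s, f and FF dimensionless in [0, 1],
    enhancement as the fractional post-contrast signal change.
    """

    class_label: str
    S0: float
    ADC_true: float
    D_true: float
    f_true: float
    Dstar_true: float
    R2star_true: float
    FF_true: float
    enhancement_true: float

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown tissue class {self.class_label!r}")
        if min(self.ADC_true, self.D_true, self.Dstar_true) <= 0:
            raise ValueError("diffusivities must be positive")
        if self.Dstar_true <= self.D_true:
            raise ValueError("Dstar_true must exceed D_true")
        if not (0 <= self.f_true <= 1 and 0 <= self.FF_true <= 1):
            raise ValueError("f_true and FF_true must lie in [0, 1]")
        if self.R2star_true < 0:
            raise ValueError("R2star_true must be non-negative")
        if self.S0 <= 0:
            raise ValueError("S0 must be positive")


#: Representative tissue classes.  Values sit inside the cohort ranges seen
#: in retroperitoneal sarcoma (median ADC spanning ~0.95-2.77e-3 mm^2/s,
#: f of a few percent, D* tens of 1e-3 mm^2/s, R2* ~5-58 1/s, fat fraction
#: up to ~0.85 in well-differentiated liposarcoma).
DEFAULT_TISSUE_CLASSES: Mapping[str, TissueClassParams] = {
    "cellular": TissueClassParams(
        "cellular", S0=100.0, ADC_true=1.10e-3, D_true=0.99e-3, f_true=0.0685,
        Dstar_true=41.36e-3, R2star_true=18.50, FF_true=0.05, enhancement_true=0.45,
    ),
    "myxoid": TissueClassParams(
        "myxoid", S0=110.0, ADC_true=2.40e-3, D_true=2.30e-3, f_true=0.03,
        Dstar_true=30.0e-3, R2star_true=8.0, FF_true=0.08, enhancement_true=0.20,
    ),
    "fibrous": TissueClassParams(
        "fibrous", S0=90.0, ADC_true=1.45e-3, D_true=1.40e-3, f_true=0.05,
        Dstar_true=35.0e-3, R2star_true=25.0, FF_true=0.06, enhancement_true=0.30,
    ),
    "fat": TissueClassParams(
        "fat", S0=120.0, ADC_true=0.40e-3, D_true=0.35e-3, f_true=0.02,
        Dstar_true=20.0e-3, R2star_true=45.0, FF_true=0.85, enhancement_true=0.05,
    ),
    "necrotic": TissueClassParams(
        "necrotic", S0=105.0, ADC_true=2.70e-3, D_true=2.65e-3, f_true=0.021,
        Dstar_true=15.0e-3, R2star_true=5.5, FF_true=0.03, enhancement_true=0.02,
    ),
}


@dataclass(frozen=True)
class EllipsoidRegion:
    """One ellipsoidal sub-region in voxel-index space."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    class_label: str


@dataclass
class PhantomSpec:
    """Geometry, tissue assignment and noise level of one digital tumor.

    Exactly one of ``noise_sigma`` (Rician scale, a.u.) or ``target_snr``
    may be set; set ``noise_sigma=0.0`` for a noiseless phantom.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 12)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 5.0)
    tumor_geometry: Sequence[EllipsoidRegion] = ()
    class_assignment: Mapping[str, TissueClassParams] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_CLASSES)
    )
    noise_sigma: float | None = None
    target_snr: float | None = 386.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.noise_sigma is None) == (self.target_snr is None):
            raise ValueError("set exactly one of noise_sigma / target_snr")
        for region in self.tumor_geometry:
            if region.class_label not in self.class_assignment:
                raise ValueError(f"no tissue class assigned for {region.class_label!r}")
            for c, a, n in zip(region.center, region.semi_axes, self.grid_shape):
                if a <= 0:
                    raise ValueError("semi-axes must be positive")
                if c - a < -0.5 or c + a > n - 0.5:
                    raise ValueError("sub-region extends outside the grid")


def default_tumor_geometry(
    grid_shape: tuple[int, int, int] = (48, 48, 12)
) -> tuple[EllipsoidRegion, ...]:
    """A three-component tumor (cellular core, myxoid rim region, fat nodule)."""
    nx, ny, nz = grid_shape
    return (
        EllipsoidRegion((nx * 0.38, ny * 0.5, nz * 0.5), (nx * 0.16, ny * 0.22, nz * 0.30), "cellular"),
        EllipsoidRegion((nx * 0.68, ny * 0.36, nz * 0.5), (nx * 0.12, ny * 0.14, nz * 0.25), "myxoid"),
        EllipsoidRegion((nx * 0.66, ny * 0.70, nz * 0.5), (nx * 0.10, ny * 0.11, nz * 0.22), "fat"),
    )


@dataclass
class PhantomVolumes:
    """Ground-truth volumes of a generated phantom (background is zero)."""

    truth: dict[str, np.ndarray]
    class_labels: np.ndarray  # int codes into CLASS_LABELS, -1 = background
    tumor_mask: np.ndarray
    voxel_size: tuple[float, float, float]

    def slice_masks(self, slice_axis: int = 2) -> dict[int, np.ndarray]:
        """Per-slice ROI masks covering exactly the tumor voxels."""
        out = {}
        for z in range(self.tumor_mask.shape[slice_axis]):
            sl = [slice(None)] * 3
            sl[slice_axis] = z
            m = self.tumor_mask[tuple(sl)]
            if m.any():
                out[z] = m.copy()
        return out

    def fat_mask(self) -> np.ndarray:
        return self.class_labels == CLASS_LABELS.index("fat")


def generate_phantom(spec: PhantomSpec) -> PhantomVolumes:
    """Rasterise the sub-regions of ``spec`` into ground-truth volumes.

    Overlapping sub-regions with conflicting tissue classes are rejected;
    overlapping same-class regions merge.
    """
    shape = tuple(spec.grid_shape)
    labels = np.full(shape, -1, dtype=int)
    coords = np.indices(shape, dtype=float)
    for region in spec.tumor_geometry:
        r2 = np.zeros(shape)
        for ax in range(3):
            r2 += ((coords[ax] - region.center[ax]) / region.semi_axes[ax]) ** 2
        inside = r2 <= 1.0
        code = CLASS_LABELS.index(region.class_label)
        conflict = inside & (labels >= 0) & (labels != code)
        if conflict.any():
            raise ValueError(
                f"sub-region {region.class_label!r} overlaps a different tissue class"
            )
        labels[inside] = code

    truth = {name: np.zeros(shape) for name in TRUTH_FIELDS}
    for label, params in spec.class_assignment.items():
        sel = labels == CLASS_LABELS.index(label)
        if not sel.any():
            continue
        truth["S0"][sel] = params.S0
        truth["ADC"][sel] = params.ADC_true
        truth["D"][sel] = params.D_true
        truth["f"][sel] = params.f_true
        truth["Dstar"][sel] = params.Dstar_true
        truth["R2star"][sel] = params.R2star_true
        truth["FF"][sel] = params.FF_true
        truth["enhancement"][sel] = params.enhancement_true

    return PhantomVolumes(
        truth=truth,
        class_labels=labels,
        tumor_mask=labels >= 0,
        voxel_size=tuple(spec.voxel_size),
    )


def synthesize_acquisitions(
    vols: PhantomVolumes,
    b_values: Sequence[float] = DEFAULT_B_VALUES,
    echo_times: Sequence[float] = DEFAULT_ECHO_TIMES,
    fat_suppression: float = 0.05,
    include_contrast: bool = True,
) -> dict[str, AcquisitionSeries]:
    """Noiseless acquisition series from ground-truth volumes.

    Two DWI series are produced, mirroring a protocol that acquires one
    diffusion series for ADC estimation and a separate one for IVIM:

    * ``dwi_adc``  - S(b) = S0 * exp(-b * ADC)
    * ``dwi_ivim`` - S(b) = S0 * [(1 - f) exp(-b D) + f exp(-b D*)]
    * ``gre``      - S(TE) = S0 * exp(-TE * R2*)
    * ``dixon``    - fat = S0 * FF, water = S0 * (1 - FF)
    * ``contrast`` - pre = S0, post = S0 * (1 + enhancement)

    Fat-class voxels are attenuated by ``fat_suppression`` in the DWI and
    GRE series, emulating fat-suppressed acquisition; the Dixon and
    contrast series are not suppressed.
    """
    b = np.asarray(b_values, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if np.any(np.diff(b) <= 0) or np.any(np.diff(te) <= 0):
        raise ValueError("encoding lists must be strictly increasing")
    if np.any(b < 0) or np.any(te <= 0):
        raise ValueError("b-values must be >= 0 and echo times > 0")
    t = vols.truth
    supp = np.where(vols.fat_mask(), fat_suppression, 1.0)
    s0_supp = t["S0"] * supp

    dwi_adc = s0_supp[..., None] * np.exp(-b * t["ADC"][..., None])
    dwi_ivim = s0_supp[..., None] * (
        (1.0 - t["f"][..., None]) * np.exp(-b * t["D"][..., None])
        + t["f"][..., None] * np.exp(-b * t["Dstar"][..., None])
    )
    gre = s0_supp[..., None] * np.exp(-te * t["R2star"][..., None])
    dixon = np.stack([t["S0"] * t["FF"], t["S0"] * (1.0 - t["FF"])], axis=-1)

    out = {
        "dwi_adc": AcquisitionSeries(dwi_adc, b, "dwi"),
        "dwi_ivim": AcquisitionSeries(dwi_ivim, b, "dwi"),
        "gre": AcquisitionSeries(gre, te, "gre"),
        "dixon": AcquisitionSeries(dixon, None, "dixon_pair"),
    }
    if include_contrast:
        contrast = np.stack([t["S0"], t["S0"] * (1.0 + t["enhancement"])], axis=-1)
        out["contrast"] = AcquisitionSeries(contrast, None, "contrast_pair")
    return out


def add_rician_noise(
    data: np.ndarray | AcquisitionSeries,
    sigma: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Rician magnitude noise: sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma).

    Accepts a raw array or an AcquisitionSeries (returned as a new series).
    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if isinstance(data, AcquisitionSeries):
        noisy = add_rician_noise(data.volumes, sigma, seed=seed, rng=rng)
        return AcquisitionSeries(noisy, data.encodings, data.kind)
    arr = np.asarray(data, dtype=float)
    if sigma == 0:
        return arr.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    n1 = rng.normal(scale=sigma, size=arr.shape)
    n2 = rng.normal(scale=sigma, size=arr.shape)
    return np.sqrt((arr + n1) ** 2 + n2**2)


def noise_sigma_for_snr(
    series: AcquisitionSeries, tumor_mask: np.ndarray, target_snr: float
) -> float:
    """Gaussian noise scale giving the requested ROI SNR.

    The ROI SNR estimator reports 0.66 * S_tumor / SD(background magnitude);
    for background Rayleigh noise SD = sigma * sqrt(2 - pi/2), so the
    estimator returns ~S_tumor/sigma and the required scale is the mean
    tumor signal in the lowest-encoding image divided by ``target_snr``.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    s_ref = float(series.volumes[..., 0][np.asarray(tumor_mask, bool)].mean())
    return s_ref / target_snr


# ---------------------------------------------------------------------------
# cohort and histology simulators
# ---------------------------------------------------------------------------

@dataclass
class RepeatCohortSpec:
    """Double-baseline cohort on the log scale.

    Per patient: a true log-value ~ Normal(mean_log, between_patient_log_sd);
    each baseline replicate adds Normal(0, s_w_true); an optional
    post-treatment value adds ``treatment_effect_log`` to the true value.
    Defaults reproduce a 27-patient repeatability cohort of median ADC with
    within-subject log-SD 0.025 (CoV 2.5%).
    """

    n_patients: int = 27
    s_w_true: float = 0.025
    between_patient_log_sd: float = 0.2
    mean_log: float = math.log(1.70e-3)
    treatment_effect_log: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.s_w_true < 0 or self.between_patient_log_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def simulate_repeat_cohort(spec: RepeatCohortSpec) -> pd.DataFrame:
    """Simulate paired baseline (and optional post-treatment) summary values.

    Returns a DataFrame with columns patient, true_value, baseline1,
    baseline2 (and post_rt when a treatment effect is specified).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    true_log = rng.normal(spec.mean_log, spec.between_patient_log_sd, size=n)
    b1 = true_log + rng.normal(0.0, spec.s_w_true, size=n)
    b2 = true_log + rng.normal(0.0, spec.s_w_true, size=n)
    df = pd.DataFrame(
        {
            "patient": np.arange(1, n + 1),
            "true_value": np.exp(true_log),
            "baseline1": np.exp(b1),
            "baseline2": np.exp(b2),
        }
    )
    if spec.treatment_effect_log is not None:
        post = true_log + spec.treatment_effect_log + rng.normal(0.0, spec.s_w_true, size=n)
        df["post_rt"] = np.exp(post)
    return df


def _spearman_to_pearson(rho_s: float) -> float:
    """Latent Gaussian-copula Pearson r yielding Spearman rho_s."""
    if not -1.0 <= rho_s <= 1.0:
        raise ValueError("Spearman target must lie in [-1, 1]")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


STROMA_TYPES = ("fibrous", "myxoid", "fibromyxoid")


def simulate_histology_table(
    n_rois: int = 48,
    rho_adc: float = -0.42,
    rho_d: float = -0.45,
    rho_ff: float = 0.79,
    seed: int = 0,
) -> pd.DataFrame:
    """Histology-like ROI table with targeted Spearman couplings.

    Latent Gaussian copula: the ADC and D latents are correlated (r = 0.9,
    both reflect water diffusivity); the nuclear-to-stromal-ratio latent is
    the linear combination of the two that achieves both Spearman targets
    (``rho_adc``, ``rho_d``) simultaneously; the histology fat-fraction
    latent couples to the imaging-FF latent at ``rho_ff``.  Marginals are
    strictly monotone in the latents, so the targets are exact population
    rank correlations.  Incompatible target triples (those requiring a
    latent variance above 1) are rejected.
    """
    if n_rois < 3:
        raise ValueError("n_rois must be at least 3")
    rng = np.random.default_rng(seed)
    r_adc = _spearman_to_pearson(rho_adc)
    r_d = _spearman_to_pearson(rho_d)
    r_ff = _spearman_to_pearson(rho_ff)
    r_dd = 0.9  # latent correlation between ADC and D

    z_adc = rng.standard_normal(n_rois)
    z_d = r_dd * z_adc + math.sqrt(1 - r_dd**2) * rng.standard_normal(n_rois)
    denom = 1.0 - r_dd**2
    alpha = (r_adc - r_dd * r_d) / denom
    beta = (r_d - r_dd * r_adc) / denom
    var_expl = alpha**2 + beta**2 + 2 * r_dd * alpha * beta
    if var_expl > 1.0 + 1e-9:
        raise ValueError("incompatible Spearman targets for ADC and D couplings")
    resid_sd = math.sqrt(max(1.0 - var_expl, 0.0))
    z_nsr = alpha * z_adc + beta * z_d + resid_sd * rng.standard_normal(n_rois)

    z_ffi = rng.standard_normal(n_rois)
    z_ffh = r_ff * z_ffi + math.sqrt(1 - r_ff**2) * rng.standard_normal(n_rois)

    # monotone marginals
    adc = np.exp(math.log(1.70e-3) + 0.28 * z_adc)
    d_img = np.exp(math.log(1.65e-3) + 0.27 * z_d)
    nsr = np.exp(math.log(20.0) + 0.8 * z_nsr)  # percent
    ff_img = beta_dist.ppf(ndtr(z_ffi), 0.6, 1.6)
    ff_histo = beta_dist.ppf(ndtr(z_ffh), 0.6, 1.6)

    stroma = rng.choice(STROMA_TYPES, size=n_rois, p=(0.6, 0.25, 0.15))
    fibrous = stroma == "fibrous"
    grade = np.where(
        fibrous, np.clip(np.ceil(5 * ndtr(z_nsr)), 1, 5).astype(int), 0
    )

    df = pd.DataFrame(
        {
            "roi_id": np.arange(1, n_rois + 1),
            "tumor_id": np.arange(n_rois) // 3 + 1,  # up to 3 ROIs per tumor
            "nuclear_to_stromal_ratio": nsr,
            "histo_fat_fraction": ff_histo,
            "vessel_density": rng.integers(0, 4, size=n_rois),
            "stroma_type": stroma,
            "fibrous_grade": grade,
            "ADC": adc,
            "D": d_img,
            "f": np.exp(math.log(0.0685) + 0.4 * rng.standard_normal(n_rois)),
            "Dstar": np.exp(math.log(41.36e-3) + 0.4 * rng.standard_normal(n_rois)),
            "R2star": np.exp(math.log(18.5) + 0.5 * rng.standard_normal(n_rois)),
            "FF": ff_img,
            "epsF": np.clip(rng.normal(0.34, 0.15, size=n_rois), 0.0, 0.64),
        }
    )
    return df
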