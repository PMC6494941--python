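"""Voxel-wise parameter estimation from quantitative MRI series.

Implements the per-voxel fits used for whole-tumor analysis of soft-tissue
sarcoma: Levenberg-Marquardt mono-exponential fits (ADC from diffusion
weighted series, R2* from multi-echo gradient-echo series), Markov-chain
Monte Carlo fitting of the intra-voxel incoherent motion (IVIM)
bi-exponential model

    S(b) = S0 * [(1 - f) * exp(-b * D) + f * exp(-b * D*)],

Dixon fat-fraction maps, enhancing fraction / fractional enhancement from a
pre/post-contrast pair, ROI-based SNR estimation, signal thresholding to
exclude suppressed fat, and a two-point b-value design helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.special import ndtri

__all__ = [
    "AcquisitionSeries",
    "ParameterMap",
    "FitDiagnostics",
    "IvimPriors",
    "IvimSamplerConfig",
    "apply_signal_threshold",
    "fit_monoexponential",
    "fit_ivim_mcmc",
    "compute_fat_fraction",
    "compute_enhancement",
    "estimate_snr",
    "recommend_upper_b",
]

SERIES_KINDS = ("dwi", "gre", "dixon_pair", "contrast_pair")

PARAMETER_UNITS = {
    "ADC": "mm^2/s",
    "D": "mm^2/s",
    "Dstar": "mm^2/s",
    "f": "dimensionless",
    "R2star": "1/s",
    "FF": "dimensionless",
    "epsF": "dimensionless",
    "S0": "a.u.",
}


@dataclass
class AcquisitionSeries:
    """A 4D magnitude image stack with its encoding axis.

    ``volumes`` has shape (x, y, z, n_encodings) for ``dwi``/``gre`` series,
    or (x, y, z, 2) for paired kinds (Dixon fat/water, pre/post contrast),
    in which case ``encodings`` is None.  b-values are in s/mm^2 and echo
    times in seconds.
    """

    volumes: np.ndarray
    encodings: np.ndarray | None
    kind: str

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.kind not in SERIES_KINDS:
            raise ValueError(f"unknown series kind {self.kind!r}")
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4D (x, y, z, encoding)")
        if np.any(self.volumes < 0):
            raise ValueError("magnitude data must be non-negative")
        if self.kind in ("dwi", "gre"):
            if self.encodings is None:
                raise ValueError(f"{self.kind} series requires encodings")
            self.encodings = np.asarray(self.encodings, dtype=float)
            if self.encodings.ndim != 1 or len(self.encodings) != self.volumes.shape[3]:
                raise ValueError("encodings must match the 4th volume axis")
            if np.any(np.diff(self.encodings) <= 0):
                raise ValueError("encodings must be strictly increasing (no duplicates)")
            if np.any(self.encodings < 0):
                raise ValueError("encodings must be non-negative")
        else:
            if self.volumes.shape[3] != 2:
                raise ValueError(f"{self.kind} series must hold exactly two volumes")
            self.encodings = None

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[:3]


@dataclass
class ParameterMap:
    """One fitted/derived 3D quantity plus the mask of voxels it is valid on."""

    values: np.ndarray
    valid_mask: np.ndarray
    parameter: str
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must be congruent")
        if self.parameter in PARAMETER_UNITS and not self.units:
            self.units = PARAMETER_UNITS[self.parameter]
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("values must be finite where valid")

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


@dataclass
class FitDiagnostics:
    """Bookkeeping for one voxel-wise fit.

    ``n_voxels_attempted == n_voxels_converged + n_voxels_failed +
    n_voxels_thresholded_out`` always holds.
    """

    n_voxels_attempted: int = 0
    n_voxels_converged: int = 0
    n_voxels_failed: int = 0
    n_voxels_thresholded_out: int = 0
    residual_norm: np.ndarray | None = None
    mcmc_acceptance_rate: float | None = None
    mcmc_chain_length: int | None = None
    mcmc_rhat: np.ndarray | None = None

    def __post_init__(self) -> None:
        total = self.n_voxels_converged + self.n_voxels_failed + self.n_voxels_thresholded_out
        if self.n_voxels_attempted != total:
            raise ValueError("attempted must equal converged + failed + thresholded_out")


# ---------------------------------------------------------------------------
# signal threshold and simple derived maps
# ---------------------------------------------------------------------------

def apply_signal_threshold(
    series: AcquisitionSeries, noise_sd: float, k: float = 3.0
) -> np.ndarray:
    """Exclusion mask for suppressed-fat voxels.

    A voxel is excluded (True) when its signal in the lowest-encoding image
    falls below ``k * noise_sd``, mirroring the signal-intensity threshold
    applied before ADC/IVIM/R2* analysis of fat-suppressed acquisitions.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    lowest = series.volumes[..., 0]
    return lowest < k * noise_sd


def compute_fat_fraction(fat: np.ndarray, water: np.ndarray) -> ParameterMap:
    """Dixon fat fraction FF = fat / (fat + water), voxel-wise.

    Voxels where fat + water == 0 are marked invalid.
    """
    fat = np.asarray(fat, dtype=float)
    water = np.asarray(water, dtype=float)
    if fat.shape != water.shape:
        raise ValueError("fat and water volumes must be congruent")
    if np.any(fat < 0) or np.any(water < 0):
        raise ValueError("Dixon magnitudes must be non-negative")
    total = fat + water
    valid = total > 0
    values = np.zeros_like(fat)
    np.divide(fat, total, out=values, where=valid)
    return ParameterMap(values=values, valid_mask=valid, parameter="FF")


def compute_enhancement(
    pre: np.ndarray,
    post: np.ndarray,
    mask: np.ndarray,
    threshold: float = 0.05,
) -> tuple[float, ParameterMap]:
    """Enhancing fraction and fractional-enhancement map.

    EF is the percentage of VOI voxels whose signal rises by more than
    ``threshold`` (relative to the pre-contrast signal) after contrast;
    eps_F = (S1 - S0) / (S1 + S0) per voxel.  Voxels with S1 + S0 == 0 are
    invalid for eps_F; voxels with S0 == 0 cannot enhance by a relative
    criterion and never count toward EF's numerator (they stay in the
    denominator).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pre.shape != post.shape or pre.shape != mask.shape:
        raise ValueError("pre, post and mask must be congruent")
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise ValueError("mask is empty")

    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (post - pre) / pre
    enhancing = mask & (pre > 0) & (rel > threshold)
    ef_pct = 100.0 * enhancing.sum() / n_mask

    total = post + pre
    valid = total > 0
    eps = np.zeros_like(pre)
    np.divide(post - pre, total, out=eps, where=valid)
    eps_map = ParameterMap(values=eps, valid_mask=valid, parameter="epsF")
    return ef_pct, eps_map


def estimate_snr(
    series: AcquisitionSeries | np.ndarray,
    tumor_mask: np.ndarray,
    noise_masks: tuple[np.ndarray, np.ndarray],
    factor: float = 0.66,
    slice_axis: int = 2,
) -> float:
    """ROI-based SNR of the lowest-encoding image.

    Per tumor-bearing slice, SNR = factor * mean(tumor signal) / mean of the
    standard deviations in two background noise ROIs; the result is the mean
    over tumor-bearing slices.  The 0.66 factor converts the Rayleigh-reduced
    standard deviation measured in a background magnitude image back to the
    underlying Gaussian noise level.
    """
    if isinstance(series, AcquisitionSeries):
        volume = series.volumes[..., 0]
    else:
        volume = np.asarray(series, dtype=float)
        if volume.ndim != 3:
            raise ValueError("expected a 3D lowest-encoding volume")
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if len(noise_masks) != 2:
        raise ValueError("exactly two noise ROIs are required")
    noise_a, noise_b = (np.asarray(m, dtype=bool) for m in noise_masks)
    for m in (tumor_mask, noise_a, noise_b):
        if m.shape != volume.shape:
            raise ValueError("masks must be congruent with the volume")

    slice_snrs = []
    for z in range(volume.shape[slice_axis]):
        sl = [slice(None)] * 3
        sl[slice_axis] = z
        sl = tuple(sl)
        t = tumor_mask[sl]
        if not t.any():
            continue
        sds = []
        for m in (noise_a[sl], noise_b[sl]):
            if m.sum() < 2:
                raise ValueError(f"noise ROI too small on slice {z}")
            sds.append(float(np.std(volume[sl][m], ddof=1)))
        sd_noise = float(np.mean(sds))
        if sd_noise == 0:
            raise ValueError(f"zero noise SD on slice {z}")
        slice_snrs.append(factor * float(np.mean(volume[sl][t])) / sd_noise)
    if not slice_snrs:
        raise ValueError("no tumor-bearing slices")
    return float(np.mean(slice_snrs))


def recommend_upper_b(adc: float) -> int:
    """Upper b-value (s/mm^2) for a two-point ADC scheme: 1.1 / ADC.

    Rounded half away from zero to the nearest integer.
    """
    if adc <= 0:
        raise ValueError("adc must be positive")
    return int(math.floor(1.1 / adc + 0.5))


# ---------------------------------------------------------------------------
# mono-exponential fitting
# ---------------------------------------------------------------------------

def loglinear_monoexp(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form log-linear solution of y = S0 * exp(-rate * x).

    Ordinary least squares of ln(y) on x over strictly positive samples.
    Returns (S0, rate); raises if fewer than two positive samples remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = y > 0
    if pos.sum() < 2:
        raise ValueError("need at least two positive samples")
    slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
    return float(np.exp(intercept)), float(-slope)


def fit_monoexponential(
    series: AcquisitionSeries,
    mask: np.ndarray | None = None,
    min_encoding: float | None = None,
    parameter: str | None = None,
) -> tuple[ParameterMap, FitDiagnostics]:
    """Voxel-wise Levenberg-Marquardt fit of S0 * exp(-rate * x).

    ``min_encoding`` drops encodings below the given value before fitting
    (e.g. exclude b = 0 from the ADC fit).  The rate is reported as ADC for
    DWI series (x in s/mm^2) or R2* for gradient-echo series (x in s).
    Voxels with all-zero signal, too few positive samples, a failed
    optimisation, or a strictly negative rate are invalidated; a zero rate
    (constant signal) is a legitimate estimate and stays valid.
    """
    if series.kind not in ("dwi", "gre"):
        raise ValueError("mono-exponential fit needs a dwi or gre series")
    if parameter is None:
        parameter = "ADC" if series.kind == "dwi" else "R2star"
    x = series.encodings
    vols = series.volumes
    if min_encoding is not None:
        keep = x >= min_encoding
        if keep.sum() < 2:
            raise ValueError("fewer than two encodings remain after min_encoding")
        x = x[keep]
        vols = vols[..., keep]
    if len(x) < 2:
        raise ValueError("need at least two encodings")

    shape = series.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask must be congruent with the series grid")

    values = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    resid = np.full(shape, np.nan)
    n_attempted = int(mask.sum())
    n_converged = 0
    n_failed = 0

    idx = np.argwhere(mask)
    for i, j, k in idx:
        y = vols[i, j, k, :]
        if not np.any(y > 0):
            n_failed += 1
            continue
        try:
            s0_init, rate_init = loglinear_monoexp(x, y)
        except ValueError:
            n_failed += 1
            continue

        def residuals(p: np.ndarray, _x=x, _y=y) -> np.ndarray:
            return p[0] * np.exp(-p[1] * _x) - _y

        scale = np.array([max(abs(s0_init), 1e-12), max(abs(rate_init), 1e-12)])
        try:
            res = optimize.least_squares(
                residuals, x0=[s0_init, rate_init], method="lm", x_scale=scale
            )
        except Exception:
            n_failed += 1
            continue
        if not res.success or not np.all(np.isfinite(res.x)):
            n_failed += 1
            continue
        rate = float(res.x[1])
        if -1e-10 <= rate < 0:  # numerical noise around an exactly-zero rate
            rate = 0.0
        values[i, j, k] = rate
        resid[i, j, k] = float(np.linalg.norm(res.fun))
        if rate >= 0:
            valid[i, j, k] = True
            n_converged += 1
        else:
            n_failed += 1

    pmap = ParameterMap(values=values, valid_mask=valid, parameter=parameter)
    diag = FitDiagnostics(
        n_voxels_attempted=n_attempted,
        n_voxels_converged=n_converged,
        n_voxels_failed=n_failed,
        residual_norm=resid,
    )
    return pmap, diag


# ---------------------------------------------------------------------------
# IVIM MCMC fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IvimPriors:
    """Uniform priors for the IVIM parameters (natural units).

    Bounds span the ranges observed in retroperitoneal sarcoma with
    headroom; S0 carries a flat positive prior.  D* > D is enforced.
    """

    d_bounds: tuple[float, float] = (0.1e-3, 4.0e-3)
    f_bounds: tuple[float, float] = (0.0, 0.5)
    dstar_bounds: tuple[float, float] = (3.0e-3, 300.0e-3)


@dataclass(frozen=True)
class IvimSamplerConfig:
    """Settings for the component-wise adaptive Metropolis IVIM sampler.

    ``noise_sd`` is the Gaussian likelihood scale; when None it is estimated
    per voxel from the residuals of the initialisation fit, floored at
    ``noise_floor_frac`` times the voxel's peak signal so that noiseless
    input yields a sharply peaked but still samplable posterior.
    """

    n_chains: int = 3
    n_steps: int = 4000
    n_burn: int = 1000
    seed: int = 0
    rhat_max: float = 1.05
    noise_sd: float | None = None
    noise_floor_frac: float = 1e-4
    target_accept: float = 0.44
    priors: IvimPriors = field(default_factory=IvimPriors)


def _ivim_model(b: np.ndarray, s0, d, f, dstar) -> np.ndarray:
    return s0[..., None] * (
        (1.0 - f[..., None]) * np.exp(-b * d[..., None])
        + f[..., None] * np.exp(-b * dstar[..., None])
    )


def _segmented_init(b: np.ndarray, y: np.ndarray, priors: IvimPriors):
    """Segmented least-squares initialisation, vectorised over voxels.

    High-b log-linear fit gives (S0_hi, D); the gap between the all-b
    extrapolated S(0) and S0_hi gives f; D* is picked from a log-spaced
    grid by analytically profiling S0 at each candidate.
    """
    n_vox = y.shape[0]
    hi = b >= min(200.0, np.median(b))
    if hi.sum() < 2:
        hi = b >= np.sort(b)[len(b) // 2]
    eps = 1e-12
    logy = np.log(np.maximum(y, eps))

    def lstsq_rate(bsub: np.ndarray, ysub: np.ndarray):
        # per-voxel OLS of log-signal on b: returns (intercept, slope)
        bm = bsub.mean()
        denom = ((bsub - bm) ** 2).sum()
        slope = ((bsub - bm) * (ysub - ysub.mean(axis=1, keepdims=True))).sum(axis=1) / denom
        intercept = ysub.mean(axis=1) - slope * bm
        return intercept, slope

    int_hi, slope_hi = lstsq_rate(b[hi], logy[:, hi])
    d0 = np.clip(-slope_hi, priors.d_bounds[0] * 1.01, priors.d_bounds[1] * 0.99)
    s0_hi = np.exp(int_hi)

    int_all, _ = lstsq_rate(b, logy)
    s0_all = np.exp(int_all)
    s0_ref = np.maximum(s0_all, s0_hi)
    f0 = np.clip(1.0 - s0_hi / np.maximum(s0_ref, eps), 1e-3, priors.f_bounds[1] - 1e-3)

    # grid over D*, profiling S0 analytically for each candidate
    dstar_grid = np.geomspace(priors.dstar_bounds[0] * 1.05, priors.dstar_bounds[1] * 0.95, 24)
    best_sse = np.full(n_vox, np.inf)
    dstar0 = np.full(n_vox, dstar_grid[0])
    s0_best = s0_ref.copy()
    for ds in dstar_grid:
        m = (1.0 - f0[:, None]) * np.exp(-b * d0[:, None]) + f0[:, None] * np.exp(-b * ds)
        s0_c = (y * m).sum(axis=1) / np.maximum((m * m).sum(axis=1), eps)
        sse = ((s0_c[:, None] * m - y) ** 2).sum(axis=1)
        better = sse < best_sse
        best_sse = np.where(better, sse, best_sse)
        dstar0 = np.where(better, ds, dstar0)
        s0_best = np.where(better, s0_c, s0_best)
    dstar0 = np.maximum(dstar0, d0 * 1.5)
    dstar0 = np.clip(dstar0, priors.dstar_bounds[0] * 1.01, priors.dstar_bounds[1] * 0.99)
    s0_best = np.maximum(s0_best, eps)
    return s0_best, d0, f0, dstar0, best_sse


def _polish_lsq(
    b: np.ndarray, y: np.ndarray, init: tuple, priors: IvimPriors
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel bounded least-squares refinement of the segmented init."""
    s0_0, d0, f0, ds0 = init
    n_vox = y.shape[0]
    out = np.empty((n_vox, 4))
    sse = np.empty(n_vox)
    lo = [1e-12, priors.d_bounds[0], priors.f_bounds[0], priors.dstar_bounds[0]]
    hi = [np.inf, priors.d_bounds[1], priors.f_bounds[1], priors.dstar_bounds[1]]

    def residuals(p: np.ndarray, yv: np.ndarray) -> np.ndarray:
        return p[0] * ((1 - p[2]) * np.exp(-b * p[1]) + p[2] * np.exp(-b * p[3])) - yv

    for i in range(n_vox):
        x0 = np.clip([s0_0[i], d0[i], f0[i], ds0[i]], lo, hi)
        try:
            res = optimize.least_squares(
                residuals, x0=x0, bounds=(lo, hi), args=(y[i],),
                x_scale=np.maximum(np.abs(x0), 1e-12), max_nfev=200,
            )
            out[i] = res.x
            sse[i] = float(2 * res.cost)
        except Exception:
            out[i] = x0
            sse[i] = float(np.sum(residuals(x0, y[i]) ** 2))
    return out[:, 0], out[:, 1], out[:, 2], out[:, 3], sse


def _split_rhat(samples: np.ndarray) -> np.ndarray:
    """Rank-normalised split R-hat, vectorised over axis 0.

    ``samples`` has shape (n_voxels, n_chains, n_draws); each chain is split
    in half, draws are rank-normalised per voxel, and the classic
    between/within variance ratio is computed on the normal scores.
    """
    v, c, n = samples.shape
    half = n // 2
    x = samples[:, :, : 2 * half].reshape(v, 2 * c, half)
    flat = x.reshape(v, -1)
    order = np.argsort(flat, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(v)[:, None]
    ranks[rows, order] = np.arange(flat.shape[1])[None, :]
    s = flat.shape[1]
    z = ndtri((ranks + 1.0 - 0.375) / (s + 0.25)).reshape(v, 2 * c, half)
    chain_mean = z.mean(axis=2)
    chain_var = z.var(axis=2, ddof=1)
    w = chain_var.mean(axis=1)
    bvar = half * chain_mean.var(axis=1, ddof=1)
    var_plus = (half - 1) / half * w + bvar / half
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    return np.where(w > 0, rhat, 1.0)


def fit_ivim_mcmc(
    series: AcquisitionSeries,
    mask: np.ndarray | None = None,
    config: IvimSamplerConfig | None = None,
) -> tuple[dict[str, ParameterMap], FitDiagnostics]:
    """Voxel-wise Bayesian IVIM fit by component-wise adaptive Metropolis.

    All masked voxels are sampled simultaneously (the chains are vectorised
    over voxels).  Each of ``n_chains`` chains random-walks the transformed
    coordinates (log S0, log D, logit f, log D*) with per-voxel,
    per-coordinate step sizes adapted during burn-in toward
    ``target_accept``.  Point estimates are posterior medians of the natural
    parameters pooled over chains; voxels whose rank-normalised split R-hat
    (worst case over D, f, D*) exceeds ``rhat_max`` are invalidated and
    counted as failures.
    """
    if config is None:
        config = IvimSamplerConfig()
    if series.kind != "dwi":
        raise ValueError("IVIM fitting needs a dwi series")
    b = series.encodings
    if len(np.unique(b)) < 4:
        raise ValueError("IVIM fitting needs at least four distinct b-values")
    pri = config.priors
    if not (pri.d_bounds[0] > 0 and pri.dstar_bounds[0] > 0):
        raise ValueError("diffusivity priors must be positive")

    shape = series.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask must be congruent with the series grid")

    idx = np.argwhere(mask)
    n_attempted = len(idx)
    y_all = series.volumes[mask]  # (V, B)
    fittable = np.any(y_all > 0, axis=1)
    y = y_all[fittable]
    v = y.shape[0]
    n_zero = int(n_attempted - v)

    maps: dict[str, ParameterMap] = {}
    if v == 0:
        for name in ("D", "f", "Dstar"):
            maps[name] = ParameterMap(
                values=np.zeros(shape), valid_mask=np.zeros(shape, bool), parameter=name
            )
        diag = FitDiagnostics(
            n_voxels_attempted=n_attempted,
            n_voxels_converged=0,
            n_voxels_failed=n_zero,
        )
        return maps, diag

    rng = np.random.default_rng(config.seed)
    s0_g, d_g, f_g, ds_g, _ = _segmented_init(b, y, pri)
    s0_0, d0, f0, ds0, sse0 = _polish_lsq(b, y, (s0_g, d_g, f_g, ds_g), pri)
    d0 = np.clip(d0, pri.d_bounds[0] * (1 + 1e-6), pri.d_bounds[1] * (1 - 1e-6))
    ds0 = np.clip(
        np.maximum(ds0, d0 * (1 + 1e-6)),
        pri.dstar_bounds[0] * (1 + 1e-6),
        pri.dstar_bounds[1] * (1 - 1e-6),
    )
    f0 = np.clip(f0, 1e-4, pri.f_bounds[1] - 1e-4)
    s0_0 = np.maximum(s0_0, 1e-12)

    if config.noise_sd is not None:
        sigma = np.full(v, float(config.noise_sd))
    else:
        sigma = np.sqrt(sse0 / max(len(b) - 4, 1))
    sigma = np.maximum(sigma, config.noise_floor_frac * y.max(axis=1))
    sigma = np.maximum(sigma, 1e-30)

    f_max = pri.f_bounds[1]
    log_d_lo, log_d_hi = np.log(pri.d_bounds[0]), np.log(pri.d_bounds[1])
    log_ds_lo, log_ds_hi = np.log(pri.dstar_bounds[0]), np.log(pri.dstar_bounds[1])

    def to_theta(s0, d, f, ds):
        f = np.clip(f, 1e-8, f_max - 1e-8)
        return np.stack(
            [np.log(s0), np.log(d), np.log(f / (f_max - f)), np.log(ds)], axis=-1
        )

    def natural(theta):
        s0 = np.exp(theta[..., 0])
        d = np.exp(theta[..., 1])
        f = f_max / (1.0 + np.exp(-theta[..., 2]))
        ds = np.exp(theta[..., 3])
        return s0, d, f, ds

    inv_two_sigma2 = 1.0 / (2.0 * sigma**2)  # (V,)

    def log_post(theta):
        s0, d, f, ds = natural(theta)
        model = _ivim_model(b, s0, d, f, ds)
        sse = ((model - y[:, None, :]) ** 2).sum(axis=2)
        ll = -sse * inv_two_sigma2[:, None]
        # log-Jacobian of the transform under flat natural-space priors
        jac = theta[..., 0] + theta[..., 1] + theta[..., 3]
        jac = jac + np.log(f) + np.log1p(-f / f_max)
        lp = ll + jac
        bad = (
            (theta[..., 1] < log_d_lo)
            | (theta[..., 1] > log_d_hi)
            | (theta[..., 3] < log_ds_lo)
            | (theta[..., 3] > log_ds_hi)
            | (ds <= d)
        )
        return np.where(bad, -np.inf, lp)

    c = config.n_chains
    theta0 = to_theta(s0_0, d0, f0, ds0)  # (V, 4)

    # curvature of the sum of squares at the mode sets per-voxel,
    # per-coordinate posterior scales for chain dispersal and step sizes
    def sse_of(theta):  # theta: (V, 4)
        s0, d, f, ds = natural(theta)
        model = _ivim_model(b, s0, d, f, ds)
        return ((model - y) ** 2).sum(axis=-1)

    h = 1e-3
    sse_c = sse_of(theta0)
    scales = np.empty((v, 4))
    for p in range(4):
        dp = np.zeros((v, 4))
        dp[:, p] = h
        d2 = (sse_of(theta0 + dp) + sse_of(theta0 - dp) - 2 * sse_c) / h**2
        with np.errstate(divide="ignore", invalid="ignore"):
            sd = sigma * np.sqrt(2.0 / d2)
        scales[:, p] = np.clip(np.where(np.isfinite(sd) & (d2 > 0), sd, 1.0), 1e-7, 1.0)

    theta = np.repeat(theta0[:, None, :], c, axis=1)  # (V, C, 4)
    jitter = scales[:, None, :] * rng.standard_normal(theta.shape)
    jitter[:, 0, :] = 0.0
    theta = theta + jitter
    lp = log_post(theta)
    # repair any chain jittered out of support
    bad = ~np.isfinite(lp)
    if bad.any():
        theta[bad] = np.repeat(theta0[:, None, :], c, axis=1)[bad]
        lp = log_post(theta)

    step = np.broadcast_to(2.4 * scales[:, None, :], (v, c, 4)).copy()
    n_keep = config.n_steps - config.n_burn
    if n_keep <= 0:
        raise ValueError("n_steps must exceed n_burn")
    kept = np.empty((v, c, n_keep, 4), dtype=np.float32)
    n_accept = 0
    n_prop = 0

    for t in range(config.n_steps):
        adapting = t < config.n_burn
        gamma = min(0.5, 5.0 / (t + 1.0) ** 0.6) if adapting else 0.0
        for p in range(4):
            prop = theta.copy()
            prop[..., p] = theta[..., p] + step[..., p] * rng.standard_normal((v, c))
            lp_prop = log_post(prop)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random((v, c))) < (lp_prop - lp)
            theta[..., p] = np.where(accept, prop[..., p], theta[..., p])
            lp = np.where(accept, lp_prop, lp)
            if adapting:
                step[..., p] *= np.exp(gamma * (accept.astype(float) - config.target_accept))
            else:
                n_accept += int(accept.sum())
                n_prop += accept.size
        if not adapting:
            kept[:, :, t - config.n_burn, :] = theta

    s0_s, d_s, f_s, ds_s = natural(kept.astype(np.float64))
    rhat = np.maximum.reduce(
        [
            _split_rhat(kept[..., 1].astype(np.float64)),
            _split_rhat(kept[..., 2].astype(np.float64)),
            _split_rhat(kept[..., 3].astype(np.float64)),
        ]
    )
    converged = rhat <= config.rhat_max

    med = lambda arr: np.median(arr.reshape(v, -1), axis=1)
    estimates = {"D": med(d_s), "f": med(f_s), "Dstar": med(ds_s)}

    valid_lin = np.zeros(n_attempted, dtype=bool)
    valid_lin[fittable] = converged
    rhat_full = np.full(shape, np.nan)
    rhat_full[tuple(idx[fittable].T)] = rhat

    for name, est in estimates.items():
        vol = np.zeros(shape)
        full = np.zeros(n_attempted)
        full[fittable] = est
        vol[tuple(idx.T)] = full
        vmask = np.zeros(shape, dtype=bool)
        vmask[tuple(idx.T)] = valid_lin
        maps[name] = ParameterMap(values=vol, valid_mask=vmask, parameter=name)

    diag = FitDiagnostics(
        n_voxels_attempted=n_attempted,
        n_voxels_converged=int(converged.sum()),
        n_voxels_failed=n_zero + int((~converged).sum()),
        mcmc_acceptance_rate=(n_accept / n_prop) if n_prop else None,
        mcmc_chain_length=config.n_steps,
        mcmc_rhat=rhat_full,
    )
    return maps, diag
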