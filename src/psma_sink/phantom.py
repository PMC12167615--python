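"""Digital phantoms: synthetic PET volumes, masks and cohorts.

No patient images are distributed with tumour-sink PET studies, so every
pipeline stage here is exercised on synthetic data with known ground truth:

* **Single-patient phantoms** — ellipsoidal organs at risk (kidneys and
  parotid glands as bilateral pairs) rasterized on a voxel grid, filled with
  per-organ baseline SUV over a low soft-tissue background, optional
  spherical lesions, optional Gaussian smoothing and multiplicative Gaussian
  voxel noise.  The SUV truth image is converted to activity concentration
  through the inverse SUV formula so the measurement pipeline's conversion
  round-trips.

* **Cohorts** — an image-free fast path drawing per-patient tumour burden
  (zero-inflated lognormal TLV, lognormal lesion SUV), lognormal
  inter-patient organ variability, body weight and injected activity, and an
  optional saturating "tumour sink" coupling that depresses expected organ
  uptake as the tumour burden grows:

  .. math:: \\mathrm{SUV}_o = B_o\\,(1 - \\beta\\,\\frac{TLU}{TLU+K})\\,
            \\varepsilon_o,\\qquad \\varepsilon_o \\sim
            \\mathrm{Lognormal}(0, \\sigma_o).

  With ``beta = 0`` organ uptake is independent of burden (null model); the
  half-saturation constant ``K`` (SUV*cm^3) controls how large a burden must
  be before the depression becomes visible.

Defaults emulate a staging/recurrence prostate-cancer cohort: organ SUVmean
medians (kidneys 13.1, liver 11.8, parotid glands 18.6, spleen 11.3) and
IQRs, a right-skewed TLV distribution (median 3.8 cm^3, tail to ~2000 cm^3)
with a 157/1086 zero mass, weight 87 +/- 14 kg and 4.0 +/- 0.2 MBq/kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy import ndimage

from .burden import LesionSet, compute_tlu, compute_tlv, pct_injected_activity
from .cohort_stats import DEFAULT_SCHEME, stratify
from .suvcore import PETVolume, ScanMeta, suv_scale_factor
from .voi_placement import ORGANS

#: Baseline organ SUVmean medians (B_o) for a typical cohort.
DEFAULT_ORGAN_MEDIANS = {
    "kidneys": 13.1,
    "liver": 11.8,
    "parotid_glands": 18.6,
    "spleen": 11.3,
}

#: Cohort IQRs of organ SUVmean, used to size inter-patient variability.
DEFAULT_ORGAN_IQRS = {
    "kidneys": 4.6,
    "liver": 4.4,
    "parotid_glands": 6.8,
    "spleen": 5.8,
}

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


def lognormal_sigma_from_iqr(median: float, iqr: float) -> float:
    """Log-scale sigma of a lognormal with the given median and IQR.

    For X ~ Lognormal(mu, sigma), IQR/median = 2 sinh(z75 * sigma).
    """
    return math.asinh(iqr / median / 2.0) / _Z75


@dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned ellipsoid: centre and semi-axes in world mm."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class LesionSpec:
    """Spherical lesion: centre (mm), radius (mm) and its SUV."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    suv: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be positive")


@dataclass
class PhantomConfig:
    """Geometry and intensity model for one synthetic patient."""

    shape: tuple[int, int, int] = (96, 96, 72)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    organs: dict[str, list[EllipsoidSpec]] = field(default_factory=dict)
    organ_suv: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_MEDIANS))
    background_suv: float = 0.5
    lesions: list[LesionSpec] = field(default_factory=list)
    noise_sd_frac: float = 0.0
    smoothing_fwhm_mm: float | None = None
    allow_lesion_in_organ: bool = False
    weight_kg: float = 87.0
    injected_mbq_per_kg: float = 4.0
    uptake_minutes: float = 120.0
    seed: int = 0


#: Standard four-organ layout on the default 192 x 192 x 144 mm grid.
DEFAULT_ORGAN_LAYOUT: dict[str, list[EllipsoidSpec]] = {
    "liver": [EllipsoidSpec((130.0, 70.0, 50.0), (30.0, 34.0, 30.0))],
    "spleen": [EllipsoidSpec((40.0, 70.0, 50.0), (20.0, 22.0, 20.0))],
    "kidneys": [EllipsoidSpec((60.0, 120.0, 95.0), (16.0, 16.0, 18.0)),
                EllipsoidSpec((130.0, 120.0, 95.0), (16.0, 16.0, 18.0))],
    "parotid_glands": [EllipsoidSpec((50.0, 30.0, 20.0), (15.0, 16.0, 15.0)),
                       EllipsoidSpec((140.0, 30.0, 20.0), (15.0, 16.0, 15.0))],
}

#: Two background lesions giving a TLV near the cohort median.
DEFAULT_LESIONS = [LesionSpec((95.0, 160.0, 50.0), 8.0, 25.0),
                   LesionSpec((95.0, 30.0, 110.0), 5.0, 15.0)]


def default_phantom_config(seed: int = 0, noise_sd_frac: float = 0.0,
                           with_lesions: bool = True,
                           **overrides) -> PhantomConfig:
    """The standard four-organ phantom used throughout the test-bench."""
    cfg = PhantomConfig(
        organs={k: list(v) for k, v in DEFAULT_ORGAN_LAYOUT.items()},
        lesions=list(DEFAULT_LESIONS) if with_lesions else [],
        noise_sd_frac=noise_sd_frac, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class PatientPhantom:
    """Generated patient: activity image, masks, metadata and ground truth."""

    pet: PETVolume                      # activity concentration, kBq/mL
    suv_truth: np.ndarray               # noise-free SUV image
    organ_masks: dict[str, np.ndarray]
    lesions: LesionSet
    meta: ScanMeta
    truth: dict


def _world_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def rasterize_ellipsoid(shape, spacing, ell: EllipsoidSpec) -> np.ndarray:
    """Binary mask of voxel centres inside the ellipsoid."""
    gx, gy, gz = _world_grids(shape, spacing)
    cx, cy, cz = ell.center_mm
    ax, ay, az = ell.semi_axes_mm
    return (((gx - cx) / ax) ** 2 + ((gy - cy) / ay) ** 2
            + ((gz - cz) / az) ** 2) <= 1.0


def rasterize_sphere(shape, spacing, center_mm, radius_mm) -> np.ndarray:
    return rasterize_ellipsoid(shape, spacing,
                               EllipsoidSpec(tuple(center_mm),
                                             (radius_mm,) * 3))


def _make_meta(cfg: PhantomConfig) -> ScanMeta:
    t0 = datetime(2025, 1, 1, 10, 0, 0)
    return ScanMeta(cfg.weight_kg * cfg.injected_mbq_per_kg, t0,
                    t0 + timedelta(minutes=cfg.uptake_minutes), cfg.weight_kg)


def generate_patient(cfg: PhantomConfig) -> PatientPhantom:
    """Rasterize organs and lesions, fill SUV, add noise, emit activity.

    Organs must be disjoint from each other; lesions may only overlap organs
    when ``allow_lesion_in_organ`` is set (used for the lesion-avoidance
    fixtures).  The noise-free SUV image and exact organ/burden metrics are
    recorded as ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    suv = np.full(cfg.shape, float(cfg.background_suv))
    organ_masks: dict[str, np.ndarray] = {}
    occupied = np.zeros(cfg.shape, dtype=bool)
    for name, parts in cfg.organs.items():
        mask = np.zeros(cfg.shape, dtype=bool)
        for ell in parts:
            mask |= rasterize_ellipsoid(cfg.shape, cfg.spacing, ell)
        if np.any(mask & occupied):
            raise ValueError(f"organ {name!r} overlaps another organ")
        occupied |= mask
        organ_masks[name] = mask
        suv[mask] = cfg.organ_suv[name]

    lesion_masks = []
    for les in cfg.lesions:
        m = rasterize_sphere(cfg.shape, cfg.spacing, les.center_mm,
                             les.radius_mm)
        if np.any(m & occupied) and not cfg.allow_lesion_in_organ:
            raise ValueError("lesion overlaps an organ "
                             "(set allow_lesion_in_organ for this fixture)")
        suv[m] = les.suv
        lesion_masks.append(m)
    lesions = (LesionSet.from_masks(lesion_masks) if lesion_masks
               else LesionSet.empty(cfg.shape))

    if cfg.smoothing_fwhm_mm:
        sigma = cfg.smoothing_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        suv = ndimage.gaussian_filter(
            suv, sigma=[sigma / s for s in cfg.spacing])

    meta = _make_meta(cfg)
    suv_clean = suv.copy()
    if cfg.noise_sd_frac > 0:
        suv = suv + rng.normal(0.0, 1.0, cfg.shape) * (cfg.noise_sd_frac * suv)

    scale = suv_scale_factor(meta)          # kBq/mL per SUV unit
    pet = PETVolume(suv * scale, cfg.spacing, value_kind="activity")

    clean_vol = PETVolume(suv_clean, cfg.spacing, value_kind="suv")
    tlv = compute_tlv(lesions, cfg.spacing)
    tlu = compute_tlu(clean_vol, lesions)
    truth = {
        "seed": cfg.seed,
        "organ_suv_mean": {o: float(suv_clean[m].mean())
                           for o, m in organ_masks.items()},
        "organ_suv_target": dict(cfg.organ_suv),
        "tlv_cm3": tlv,
        "tlu": tlu,
        "pct_injected": pct_injected_activity(tlu, meta),
    }
    return PatientPhantom(pet, suv_clean, organ_masks, lesions, meta, truth)


@dataclass
class CohortConfig:
    """Distributional model for an image-free synthetic cohort.

    ``beta`` in [0, 1) and ``K`` (SUV*cm^3) parameterize the tumour-sink
    coupling; ``beta = 0`` is the null model.  TLV is zero with probability
    ``zero_mass`` and otherwise lognormal with the given median and
    log-scale sigma; TLU is TLV times a lognormal lesion SUVmean.
    """

    n: int = 500
    beta: float = 0.0
    K: float = 500.0
    tlv_median_cm3: float = 3.8
    tlv_sigma_log: float = 2.0
    zero_mass: float = 157.0 / 1086.0
    lesion_suv_median: float = 8.0
    lesion_suv_sigma_log: float = 0.4
    organ_medians: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_MEDIANS))
    organ_iqrs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_IQRS))
    weight_mean_kg: float = 87.0
    weight_sd_kg: float = 14.0
    weight_range_kg: tuple[float, float] = (48.0, 146.0)
    activity_mean_mbq_per_kg: float = 4.0
    activity_sd_mbq_per_kg: float = 0.2
    activity_range_mbq_per_kg: tuple[float, float] = (2.8, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta < 1.0):
            raise ValueError("beta must lie in [0, 1)")
        if self.K <= 0:
            raise ValueError("K must be positive")
        if not (0.0 <= self.zero_mass < 1.0):
            raise ValueError("zero_mass must lie in [0, 1)")


def sink_factor(tlu, beta: float, K: float):
    """Multiplicative uptake depression 1 - beta * TLU / (TLU + K)."""
    tlu = np.asarray(tlu, dtype=float)
    return 1.0 - beta * tlu / (tlu + K)


def generate_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort table plus its latent ground truth.

    Returns ``(cohort, truth)``: the cohort frame has one row per patient
    with the columns the measurement pipeline would produce (organ SUVmean,
    TLV, TLU, % injected, TLV stratum); the truth frame records the latents
    (lesion SUVmean, sink factor, expected noise-free organ uptake
    ``B_o * f(TLU)``) and the coupling parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    weight = np.clip(rng.normal(cfg.weight_mean_kg, cfg.weight_sd_kg, n),
                     *cfg.weight_range_kg)
    act_per_kg = np.clip(
        rng.normal(cfg.activity_mean_mbq_per_kg, cfg.activity_sd_mbq_per_kg, n),
        *cfg.activity_range_mbq_per_kg)

    has_tumour = rng.random(n) >= cfg.zero_mass
    tlv = np.where(
        has_tumour,
        rng.lognormal(math.log(cfg.tlv_median_cm3), cfg.tlv_sigma_log, n),
        0.0)
    lesion_suv = rng.lognormal(math.log(cfg.lesion_suv_median),
                               cfg.lesion_suv_sigma_log, n)
    tlu = tlv * lesion_suv
    factor = sink_factor(tlu, cfg.beta, cfg.K)

    cohort = {"patient_id": [f"P{i:04d}" for i in range(n)]}
    truth = {"patient_id": cohort["patient_id"]}
    for organ in ORGANS:
        b = cfg.organ_medians[organ]
        sigma = lognormal_sigma_from_iqr(b, cfg.organ_iqrs[organ])
        eps = rng.lognormal(0.0, sigma, n)
        expected = b * factor
        cohort[f"suv_{organ}"] = expected * eps
        truth[f"expected_suv_{organ}"] = expected
        truth[f"sigma_log_{organ}"] = np.full(n, sigma)
    cohort.update({
        "tlv_cm3": tlv,
        "tlu": tlu,
        "pct_injected": 100.0 * tlu / (weight * 1000.0),
        "tlv_group": [stratify(v, DEFAULT_SCHEME) for v in tlv],
        "weight_kg": weight,
        "injected_mbq": weight * act_per_kg,
    })
    truth.update({
        "tlv_cm3": tlv,
        "lesion_suv": lesion_suv,
        "tlu": tlu,
        "sink_factor": factor,
        "beta": np.full(n, cfg.beta),
        "K": np.full(n, cfg.K),
        "seed": np.full(n, cfg.seed),
    })
    return pd.DataFrame(cohort), pd.DataFrame(truth)
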