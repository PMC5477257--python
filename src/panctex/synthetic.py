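"""Synthetic CT phantoms and survival cohorts for end-to-end testing.

No imaging dataset accompanies the analysis this package implements, so the
generator renders desk-scale stand-ins that reproduce its statistical
structure: a darker tumor (mean ≈ 57 HU) embedded next to brighter normal
parenchyma (mean ≈ 71 HU), both textured with spatially correlated Gaussian
noise, plus survival times whose log-hazard is linear in the standardized
value of a chosen texture feature.

Texture is synthesized by moving-average smoothing of white noise: a
uniform filter of half-width ℓ pixels applied per slice, then rescaled to
the target standard deviation. ℓ = 0 gives raw white noise (rough texture,
high dissimilarity); larger ℓ gives smoother, more correlated texture.

Everything is deterministic given the seed; phantom rendering and survival
draws use separate child streams so features and outcomes can be regenerated
independently.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import EmptyROIError
from .image_io import CTVolume, HUFilter, ROIMask
from .texture import QuantizationConfig, extract_features

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "CohortSpec", "generate_phantom", "generate_cohort"]


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture parameters of one phantom.

    The grid defaults to 8 slices of 48×48 pixels at (5.0, 0.625, 0.625) mm
    spacing — a 5 mm reconstruction interval and sub-millimetre in-plane
    pixels, as in a pancreas-protocol CT. The tumor is an ellipsoid of
    roughly 2 cm² maximal cross-section; the normal-parenchyma ROI is a
    disjoint elliptical region on the same slices. Mean HU defaults follow
    the tumor/normal contrast of portal-venous-phase PDAC (57 vs 71 HU).
    """

    shape: tuple[int, int, int] = (8, 48, 48)
    spacing: tuple[float, float, float] = (5.0, 0.625, 0.625)
    tumor_mean_hu: float = 57.0
    normal_mean_hu: float = 71.0
    tumor_noise_sd: float = 12.0
    normal_noise_sd: float = 8.0
    corr_length: float = 1.5
    tumor_radii: tuple[float, float] = (15.0, 11.0)
    normal_radii: tuple[float, float] = (8.0, 14.0)
    background_hu: float = 30.0
    hu_clip: tuple[float, float] = (-10.0, 500.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.hu_clip
        for mean in (self.tumor_mean_hu, self.normal_mean_hu):
            if not lo <= mean <= hi:
                raise ValueError(f"mean HU {mean} outside clip bounds {self.hu_clip}")
        if self.corr_length < 0 or self.tumor_noise_sd < 0 or self.normal_noise_sd < 0:
            raise ValueError("noise SD and correlation length must be non-negative")


def _correlated_noise(rng: np.random.Generator, shape, sd: float, ell: float) -> np.ndarray:
    """Per-slice moving-average-smoothed white noise rescaled to SD ``sd``."""
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    if ell <= 0:
        return sd * white
    size = 2 * int(round(ell)) + 1
    smooth = np.stack([ndimage.uniform_filter(s, size=size, mode="reflect") for s in white])
    scale = smooth.std()
    if scale == 0:
        return np.zeros(shape)
    return sd * smooth / scale


def _ellipse_mask(shape, center_yx, radii_yx, slice_scales) -> np.ndarray:
    """Stack of per-slice ellipses; radii shrink with the slice scale."""
    nz, ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    mask = np.zeros(shape, dtype=bool)
    cy, cx = center_yx
    ry, rx = radii_yx
    for k, s in enumerate(slice_scales):
        if s <= 0:
            continue
        mask[k] = ((yy - cy) / (ry * s)) ** 2 + ((xx - cx) / (rx * s)) ** 2 <= 1.0
    return mask


def generate_phantom(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[CTVolume, ROIMask, ROIMask]:
    """Render one phantom volume with its tumor and normal-pancreas masks.

    The tumor occupies the left half of the grid, the normal region the
    right half; per-slice ellipse radii follow an ellipsoidal profile so
    the mid-slice is the largest cross-section. HU values are clipped into
    the admissibility band and the clipped-voxel count logged.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape

    # Ellipsoidal through-slice profile, peaking at the volume mid-slice.
    kk = np.arange(nz)
    kc = (nz - 1) / 2.0
    half = max(nz / 2.0, 1.0)
    scales = np.sqrt(np.clip(1.0 - ((kk - kc) / half) ** 2, 0.0, None))

    tumor = _ellipse_mask(spec.shape, (ny * 0.5, nx * 0.30), spec.tumor_radii, scales)
    normal = _ellipse_mask(spec.shape, (ny * 0.5, nx * 0.72), spec.normal_radii, scales)
    normal &= ~tumor
    if not tumor.any():
        raise EmptyROIError("tumor region empty for the given phantom geometry")

    vol = np.full(spec.shape, spec.background_hu, dtype=float)
    vol += _correlated_noise(rng, spec.shape, 5.0, spec.corr_length)  # background texture
    vol[tumor] = (
        spec.tumor_mean_hu
        + _correlated_noise(rng, spec.shape, spec.tumor_noise_sd, spec.corr_length)[tumor]
    )
    vol[normal] = (
        spec.normal_mean_hu
        + _correlated_noise(rng, spec.shape, spec.normal_noise_sd, spec.corr_length)[normal]
    )

    lo, hi = spec.hu_clip
    n_clipped = int(((vol < lo) | (vol > hi)).sum())
    if n_clipped:
        logger.info("clipped %d voxels into HU band [%g, %g]", n_clipped, lo, hi)
    vol = np.clip(vol, lo, hi)

    volume = CTVolume(voxels=vol, spacing=spec.spacing)
    return volume, ROIMask(mask=tumor, role="tumor"), ROIMask(mask=normal, role="normal")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Statistical design of a synthetic cohort.

    effect_beta is the log-hazard ratio per standard deviation of the
    driven texture feature; survival times are Exponential with rate
    baseline_hazard · exp(effect_beta · z) and administratively censored
    at a Uniform(0, censoring_window) time. Defaults: 30 subjects, a mean
    uncensored survival of 31 months (baseline hazard 1/31 per month) and
    a 120-month censoring window (≈25% censoring).
    """

    n: int = 30
    effect_beta: float = 0.8
    baseline_hazard: float = 1.0 / 31.0
    censoring_window: float = 120.0
    driven_feature: str = "dissimilarity"
    noise_sd_range: tuple[float, float] = (4.0, 24.0)
    radius_scale_range: tuple[float, float] = (0.6, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")


def generate_cohort(
    pspec: PhantomSpec,
    cspec: CohortSpec,
    hu_filter: HUFilter = HUFilter(),
    quantization: QuantizationConfig | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Render a cohort of phantoms and attach feature-driven survival.

    Per subject: draw a tumor noise SD (the between-subject heterogeneity
    axis) and a tumor radius scale (the size axis), render a phantom,
    extract tumor and normal features, then draw
    the survival time from the proportional-hazards model on the cohort-
    standardized driven feature. Returns one row per subject with columns
    ``tumor_<feature>``, ``normal_<feature>``, ``time_months``, ``event``.

    When ``out_dir`` is given, volumes and masks are written as NIfTI with
    a manifest and survival CSV in the formats the pipeline reads.
    """
    from . import image_io  # local import to keep module load light

    master = np.random.SeedSequence(cspec.seed)
    phantom_seeds, survival_seed = master.spawn(2)
    subject_streams = [np.random.default_rng(s) for s in phantom_seeds.spawn(cspec.n)]
    rng_surv = np.random.default_rng(survival_seed)

    rows = []
    paths = []
    for i, rng in enumerate(subject_streams):
        sid = f"S{i + 1:03d}"
        lo_sd, hi_sd = cspec.noise_sd_range
        noise_sd = float(rng.uniform(lo_sd, hi_sd))
        lo_r, hi_r = cspec.radius_scale_range
        rscale = float(rng.uniform(lo_r, hi_r))
        ry, rx = pspec.tumor_radii
        spec_i = dataclasses.replace(
            pspec, tumor_noise_sd=noise_sd, tumor_radii=(ry * rscale, rx * rscale)
        )
        volume, tmask, nmask = generate_phantom(spec_i, rng=rng)
        row = {"subject_id": sid, "tumor_noise_sd": noise_sd}
        for mask in (tmask, nmask):
            fv = extract_features(
                volume, mask, hu_filter=hu_filter, config=quantization, subject=sid
            )
            for key, val in fv.as_dict().items():
                row[f"{mask.role}_{key}"] = val
        rows.append(row)
        if out_dir is not None:
            from pathlib import Path

            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            vol_p = out / f"{sid}_ct.nii.gz"
            tum_p = out / f"{sid}_tumor.nii.gz"
            nor_p = out / f"{sid}_normal.nii.gz"
            image_io.write_volume(volume, vol_p)
            image_io.write_mask(tmask, volume, tum_p)
            image_io.write_mask(nmask, volume, nor_p)
            paths.append(
                {
                    "subject_id": sid,
                    "volume": vol_p.name,
                    "tumor_mask": tum_p.name,
                    "normal_mask": nor_p.name,
                }
            )

    table = pd.DataFrame(rows)

    driven = table[f"tumor_{cspec.driven_feature}"].to_numpy(dtype=float)
    sd = driven.std()
    z = (driven - driven.mean()) / sd if sd > 0 else np.zeros_like(driven)
    rate = cspec.baseline_hazard * np.exp(cspec.effect_beta * z)
    t_event = rng_surv.exponential(1.0, cspec.n) / rate
    if np.isfinite(cspec.censoring_window):
        t_cens = rng_surv.uniform(0.0, cspec.censoring_window, cspec.n)
    else:
        t_cens = np.full(cspec.n, np.inf)
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-6)  # survival times must stay positive
    table["time_months"] = time
    table["event"] = event

    if event.sum() < 2:
        raise ValueError(
            "fewer than 2 events generated; widen the censoring window or "
            "regenerate with another seed"
        )

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        pd.DataFrame(paths).to_csv(out / "manifest.csv", index=False)
        table[["subject_id", "time_months", "event"]].to_csv(
            out / "survival.csv", index=False
        )
        table.to_csv(out / "cohort.csv", index=False)
    return table
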