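"""Masked grey-level co-occurrence matrices and the five texture statistics.

The analysis is strictly 2D and per-slice: features are reported for the
largest cross-section of the ROI, with the ROI's bounding box as the kernel
and every pixel outside the ROI excluded. A pixel pair contributes to the
co-occurrence counts only if *both* pixels are in-mask and HU-admissible.

The five statistics are computed exactly as defined on the normalized
matrix C (entries C_ij, grey levels 1..G indexed here 0..G-1):

    uniformity      = Σ C_ij²
    entropy         = Σ C_ij ln C_ij            (non-positive by construction)
    dissimilarity   = Σ C_ij |i−j|
    IDN             = Σ C_ij / (1 + |i−j|²/G²)
    correlation     = Σ (i−μx)(j−μy) C_ij / (σx σy)

Note the entropy carries the sign of the defining sum (no negation), and
the "inverse difference normalized" denominator uses the squared level
difference — the expression usually called inverse difference *moment*
normalized in the texture literature; the naming follows the source
feature set, the formula is implemented as written above.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .exceptions import DegenerateGLCMError, EmptyROIError, ExtractionError
from .image_io import CTVolume, HUFilter, ROIMask, apply_hu_filter, largest_cross_section

logger = logging.getLogger(__name__)

__all__ = [
    "QuantizationConfig",
    "GLCM",
    "FeatureVector",
    "SENTINEL",
    "ORIENTATION_OFFSETS",
    "TEXTURE_FEATURES",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "extract_features",
]

#: Level value carried by out-of-mask pixels after quantization.
SENTINEL: int = -1

#: The four 2D orientations, as (drow, dcol) unit offsets. 0° is the
#: horizontal neighbour; angles increase counter-clockwise in image terms.
ORIENTATION_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

TEXTURE_FEATURES = (
    "uniformity",
    "entropy",
    "dissimilarity",
    "correlation",
    "inverse_difference_normalized",
)


@dataclasses.dataclass(frozen=True)
class QuantizationConfig:
    """Equal-width quantization of HU into G grey levels.

    The mapped range defaults to the HU admissibility band [-10, 500], so
    quantization and filtering share one scale. G = 64 keeps the G×G
    matrix well-populated at typical ROI cross-sections of 10²–10³ pixels.
    """

    n_levels: int = 64
    lo: float = -10.0
    hi: float = 500.0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError(f"need at least 2 grey levels, got {self.n_levels}")
        if not self.lo < self.hi:
            raise ValueError(f"quantization range requires lo < hi, got ({self.lo}, {self.hi})")


def quantize(slice_hu: np.ndarray, mask2d: np.ndarray, config: QuantizationConfig) -> np.ndarray:
    """Map in-mask HU to integer levels 0..G-1; out-of-mask pixels get -1.

    level = floor(G · (HU − lo)/(hi − lo)), with HU = hi clamped to G−1.
    In-mask values are assumed pre-filtered into [lo, hi].
    """
    hu = np.asarray(slice_hu, dtype=float)
    m = np.asarray(mask2d, dtype=bool)
    if hu.shape != m.shape:
        raise ValueError(f"slice shape {hu.shape} != mask shape {m.shape}")
    if not m.any():
        raise EmptyROIError("cannot quantize an empty ROI slice")
    g = config.n_levels
    scaled = np.floor(g * (hu - config.lo) / (config.hi - config.lo)).astype(int)
    levels = np.clip(scaled, 0, g - 1)
    levels[~m] = SENTINEL
    return levels


@dataclasses.dataclass(frozen=True)
class GLCM:
    """Normalized grey-level co-occurrence matrix with its raw pair counts.

    counts : G×G raw pair counts P_ij, pooled over the requested orientations
             (each pair counted in both (i,j) and (j,i) when symmetric).
    delta  : interpixel distance in pixels.
    thetas : orientations pooled, degrees.
    """

    counts: np.ndarray
    delta: int
    thetas: tuple[int, ...]
    symmetric: bool

    @property
    def n_levels(self) -> int:
        return self.counts.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """C = P / ΣP, the co-occurrence probability matrix."""
        total = self.counts.sum()
        return self.counts / total

    # Marginal statistics of C (row marginal = x, column marginal = y).
    @property
    def marginal_x(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def marginal_y(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    def moments(self) -> tuple[float, float, float, float]:
        """(μx, μy, σx, σy) of the level indices under the marginals."""
        levels = np.arange(self.n_levels, dtype=float)
        px, py = self.marginal_x, self.marginal_y
        mu_x = float(levels @ px)
        mu_y = float(levels @ py)
        sigma_x = float(np.sqrt(((levels - mu_x) ** 2) @ px))
        sigma_y = float(np.sqrt(((levels - mu_y) ** 2) @ py))
        return mu_x, mu_y, sigma_x, sigma_y


def compute_glcm(
    levels: np.ndarray,
    n_levels: int,
    delta: int = 1,
    thetas: tuple[int, ...] = (0, 45, 90, 135),
    symmetric: bool = True,
) -> GLCM:
    """Accumulate co-occurrence counts over the requested orientations.

    ``levels`` is a 2D integer grid where out-of-mask pixels carry the
    sentinel −1; a pair is counted iff both its pixels are non-sentinel.
    Counts from all orientations are pooled into one matrix before
    normalization. Raises :class:`DegenerateGLCMError` when no admissible
    pair exists (callers must skip or fail loudly, never emit NaN).
    """
    lv = np.asarray(levels)
    if lv.ndim != 2:
        raise ValueError(f"levels grid must be 2D, got {lv.ndim}D")
    bad = set(np.unique(lv)) - set(range(n_levels)) - {SENTINEL}
    if bad:
        raise ValueError(f"levels outside [0, {n_levels - 1}] ∪ {{-1}}: {sorted(bad)}")
    for theta in thetas:
        if theta not in ORIENTATION_OFFSETS:
            raise ValueError(f"unsupported orientation {theta}; choose from {sorted(ORIENTATION_OFFSETS)}")

    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    nrow, ncol = lv.shape
    for theta in thetas:
        dr, dc = ORIENTATION_OFFSETS[theta]
        dr, dc = dr * delta, dc * delta
        # Overlap of the grid with itself shifted by (dr, dc).
        r0, r1 = max(0, -dr), min(nrow, nrow - dr)
        c0, c1 = max(0, -dc), min(ncol, ncol - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        src = lv[r0:r1, c0:c1]
        dst = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (src != SENTINEL) & (dst != SENTINEL)
        i, j = src[ok], dst[ok]
        flat = np.bincount(i * n_levels + j, minlength=n_levels * n_levels)
        counts += flat.reshape(n_levels, n_levels)
    if symmetric:
        counts = counts + counts.T
    if counts.sum() == 0:
        raise DegenerateGLCMError(
            f"no admissible pixel pair at delta={delta}, thetas={thetas}"
        )
    return GLCM(counts=counts, delta=delta, thetas=tuple(thetas), symmetric=symmetric)


def glcm_features(glcm: GLCM) -> dict[str, float]:
    """The five texture statistics of a normalized GLCM.

    Zero entries contribute nothing to the entropy sum. Correlation is
    undefined (NaN, with a logged warning) when either marginal has zero
    variance — e.g. for a constant image.
    """
    c = glcm.matrix
    g = glcm.n_levels
    levels = np.arange(g, dtype=float)
    absdiff = np.abs(levels[:, None] - levels[None, :])

    uniformity = float(np.sum(c * c))
    nz = c > 0
    entropy = float(np.sum(c[nz] * np.log(c[nz])))
    dissimilarity = float(np.sum(c * absdiff))
    idn = float(np.sum(c / (1.0 + absdiff**2 / g**2)))

    mu_x, mu_y, sigma_x, sigma_y = glcm.moments()
    if sigma_x * sigma_y == 0.0:
        logger.warning("GLCM correlation undefined: zero marginal variance")
        correlation = math.nan
    else:
        correlation = float(
            np.sum((levels[:, None] - mu_x) * (levels[None, :] - mu_y) * c)
            / (sigma_x * sigma_y)
        )
    return {
        "uniformity": uniformity,
        "entropy": entropy,
        "dissimilarity": dissimilarity,
        "correlation": correlation,
        "inverse_difference_normalized": idn,
    }


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """Texture statistics plus intensity and size for one ROI.

    mean_intensity is the mean HU of the filtered in-mask pixels on the
    analysed slice; size is the cross-sectional area of that slice in mm².
    """

    uniformity: float
    entropy: float
    dissimilarity: float
    correlation: float
    inverse_difference_normalized: float
    mean_intensity: float
    size_mm2: float
    slice_index: int

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def extract_features(
    volume: CTVolume,
    mask: ROIMask,
    hu_filter: HUFilter = HUFilter(),
    config: QuantizationConfig | None = None,
    delta: int = 1,
    thetas: tuple[int, ...] = (0, 45, 90, 135),
    symmetric: bool = True,
    subject: str | None = None,
) -> FeatureVector:
    """Full per-ROI pipeline: HU filter → largest cross-section → GLCM features.

    Features are computed on the single slice with the largest filtered
    cross-section, matching a report-one-value-per-feature design.
    """
    if config is None:
        config = QuantizationConfig(lo=hu_filter.lo, hi=hu_filter.hi)
    filtered = apply_hu_filter(volume, mask, hu_filter)
    try:
        idx, area = largest_cross_section(filtered, volume.pixel_spacing)
        slice_hu = volume.voxels[idx]
        slice_mask = filtered.mask[idx]
        levels = quantize(slice_hu, slice_mask, config)
        glcm = compute_glcm(
            levels, config.n_levels, delta=delta, thetas=thetas, symmetric=symmetric
        )
    except (EmptyROIError, DegenerateGLCMError) as exc:
        raise ExtractionError(str(exc), subject=subject, role=mask.role) from exc
    stats = glcm_features(glcm)
    return FeatureVector(
        mean_intensity=float(slice_hu[slice_mask].mean()),
        size_mm2=area,
        slice_index=idx,
        **stats,
    )
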