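"""Dense/dilute phase splitting of condensate images.

Operational definition: within a cell, the pixels with the highest YFP
(acceptor) fluorescence intensity form the "dense phase" (the
condensates) and the pixels with the lowest intensity form the "dilute
phase" (the surrounding nucleoplasm).  Those intensity-defined regions
are projected onto the ratio image so the crowding readout can be
compared between phases, and line profiles let intensity and ratio
trends be compared along a transect.

Phase membership is decided by exact rank selection (top-k / bottom-k
pixels, deterministic tie-break on flat index) rather than interpolated
quantiles, so a region whose area fraction matches the requested
quantile is recovered exactly and growing a quantile can only grow its
mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import filters, measure

from .errors import DegenerateSegmentationError, InsufficientPixelsError
from .ratiometric import RatioImage


@dataclass
class PhaseMasks:
    """Dense and dilute phase masks within a cell, with the quantiles used."""

    dense_mask: np.ndarray
    dilute_mask: np.ndarray
    cell_mask: np.ndarray
    dense_quantile: float
    dilute_quantile: float


@dataclass
class PhaseMeasurement:
    """Per-cell dense/dilute ratio and intensity means."""

    cell_id: str
    dense_mean_ratio: float
    dilute_mean_ratio: float
    dense_mean_intensity: float
    dilute_mean_intensity: float
    n_dense: int
    n_dilute: int


@dataclass
class LineProfilePair:
    """Paired intensity and ratio samples along a transect.

    ``intensity_scaled`` / ``ratio_scaled`` are min-max scaled copies
    for display; the raw profiles are retained and the Spearman rank
    correlation is computed on them.  ``correlation`` is None (with
    ``correlation_defined`` False) when either raw profile is constant.
    """

    positions_um: np.ndarray
    intensity_profile: np.ndarray
    ratio_profile: np.ndarray
    intensity_scaled: np.ndarray
    ratio_scaled: np.ndarray
    correlation: float | None
    correlation_defined: bool


def derive_cell_mask(acceptor_image: np.ndarray) -> np.ndarray:
    """Default cell mask: intensity threshold on YFP, hole filling, largest blob.

    A condensate-bearing cell has a three-mode histogram (image
    background, nucleoplasm, condensates), so the mask is everything
    above the lowest of two multi-Otsu thresholds; plain two-class Otsu
    is the fallback when the histogram cannot support three classes.
    """
    try:
        th = filters.threshold_multiotsu(acceptor_image, classes=3)[0]
    except ValueError:
        th = filters.threshold_otsu(acceptor_image)
    mask = acceptor_image > th
    mask = ndimage.binary_fill_holes(mask)
    labels = measure.label(mask)
    if labels.max() == 0:
        raise DegenerateSegmentationError("Otsu segmentation found no foreground")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == sizes.argmax()


def segment_phases(
    acceptor_image: np.ndarray,
    cell_mask: np.ndarray,
    dense_quantile: float = 0.10,
    dilute_quantile: float = 0.30,
    validity_mask: np.ndarray | None = None,
    smooth_sigma: float = 0.0,
) -> PhaseMasks:
    """Split in-cell pixels into dense and dilute phases by YFP intensity.

    The dense phase is the brightest ``dense_quantile`` fraction of
    eligible pixels, the dilute phase the dimmest ``dilute_quantile``
    fraction; eligible means inside ``cell_mask`` and, when provided,
    inside ``validity_mask`` (so dim pixels already excluded from the
    ratio stay out of both phases).  ``smooth_sigma > 0`` ranks pixels
    on a Gaussian-smoothed copy of the image — intensities are still
    measured on the raw data — which keeps phase membership from
    tracking per-pixel shot noise.
    """
    if not (0.0 < dense_quantile < 1.0 and 0.0 < dilute_quantile < 1.0):
        raise ValueError("quantiles must lie in (0, 1)")
    if dense_quantile + dilute_quantile > 1.0:
        raise ValueError("dense_quantile + dilute_quantile must be <= 1")
    pool = cell_mask if validity_mask is None else (cell_mask & validity_mask)
    if not pool.any():
        raise DegenerateSegmentationError("no eligible pixels inside the cell mask")

    rank_image = (ndimage.gaussian_filter(np.asarray(acceptor_image, float), smooth_sigma)
                  if smooth_sigma > 0 else np.asarray(acceptor_image, float))
    flat_idx = np.flatnonzero(pool)
    vals = rank_image.ravel()[flat_idx]
    if vals.max() == vals.min():
        raise DegenerateSegmentationError("image is constant within the mask; no contrast")

    n = flat_idx.size
    k_dense = int(round(dense_quantile * n))
    k_dilute = min(int(round(dilute_quantile * n)), n - k_dense)
    if k_dense < 1 or k_dilute < 1:
        raise DegenerateSegmentationError(
            f"quantiles ({dense_quantile}, {dilute_quantile}) select no pixels from n={n}")

    order = np.lexsort((flat_idx, vals))  # ascending value, ties by flat index
    dense_idx = flat_idx[order[-k_dense:]]
    dilute_idx = flat_idx[order[:k_dilute]]
    dense = np.zeros(acceptor_image.shape, dtype=bool)
    dilute = np.zeros(acceptor_image.shape, dtype=bool)
    dense.ravel()[dense_idx] = True
    dilute.ravel()[dilute_idx] = True
    return PhaseMasks(dense, dilute, cell_mask, dense_quantile, dilute_quantile)


def measure_phase_ratios(
    ratio: RatioImage,
    masks: PhaseMasks,
    acceptor_image: np.ndarray,
    min_pixels: int = 20,
    cell_id: str = "cell",
    weights: np.ndarray | None = None,
) -> PhaseMeasurement:
    """Mean ratio and mean YFP intensity per phase over valid pixels.

    By default each phase reports the mean of pixelwise ratios (robust
    to concentration gradients within the region); passing ``weights``
    — typically the background-subtracted donor image — gives the
    weighted mean, which equals the ratio of summed channel intensities.
    """
    out = {}
    for name, region in (("dense", masks.dense_mask), ("dilute", masks.dilute_mask)):
        sel = region & ratio.valid_mask
        n = int(sel.sum())
        if n < min_pixels:
            raise InsufficientPixelsError(
                f"{name} phase of {cell_id}: {n} valid pixels < floor {min_pixels}")
        r = ratio.ratio_map[sel]
        if weights is None:
            mean_ratio = float(r.mean())
        else:
            w = np.asarray(weights, float)[sel]
            mean_ratio = float(np.sum(r * w) / np.sum(w))
        out[name] = (mean_ratio, float(np.asarray(acceptor_image, float)[sel].mean()), n)
    return PhaseMeasurement(
        cell_id=cell_id,
        dense_mean_ratio=out["dense"][0], dilute_mean_ratio=out["dilute"][0],
        dense_mean_intensity=out["dense"][1], dilute_mean_intensity=out["dilute"][1],
        n_dense=out["dense"][2], n_dilute=out["dilute"][2],
    )


def extract_line_profiles(
    acceptor_image: np.ndarray,
    ratio: RatioImage,
    start: tuple[float, float],
    end: tuple[float, float],
    width: int = 1,
    pixel_size: float = 0.1,
) -> LineProfilePair:
    """Sample intensity and ratio along a segment (row, col coordinates).

    Nearest-pixel sampling, averaged across ``width`` pixels
    perpendicular to the segment.  Spearman correlation between the raw
    profiles is reported when both are non-constant; positions are in
    micrometres along the segment.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    img = np.asarray(acceptor_image, float)
    for pt in (start, end):
        if not (0 <= pt[0] <= img.shape[0] - 1 and 0 <= pt[1] <= img.shape[1] - 1):
            raise ValueError(f"endpoint {pt} outside the image")

    intensity = measure.profile_line(img, start, end, linewidth=width, order=0,
                                     mode="constant", reduce_func=np.mean)
    ratio_prof = measure.profile_line(ratio.ratio_map, start, end, linewidth=width,
                                      order=0, mode="constant", reduce_func=np.nanmean)
    if np.all(np.isnan(ratio_prof)):
        raise ValueError("segment lies entirely outside the valid ratio mask")

    length_px = float(np.hypot(end[0] - start[0], end[1] - start[1]))
    n = intensity.size
    step = length_px / (n - 1) if n > 1 else 0.0
    positions = np.arange(n) * step * pixel_size

    ok = np.isfinite(ratio_prof) & np.isfinite(intensity)
    i_ok, r_ok = intensity[ok], ratio_prof[ok]
    defined = (i_ok.size >= 3 and np.ptp(i_ok) > 0 and np.ptp(r_ok) > 0)
    corr = float(stats.spearmanr(i_ok, r_ok).statistic) if defined else None

    def _scale(v):
        rng = np.nanmax(v) - np.nanmin(v)
        return (v - np.nanmin(v)) / rng if rng > 0 else np.zeros_like(v)

    return LineProfilePair(
        positions_um=positions,
        intensity_profile=intensity,
        ratio_profile=ratio_prof,
        intensity_scaled=_scale(intensity),
        ratio_scaled=_scale(ratio_prof),
        correlation=corr,
        correlation_defined=defined,
    )
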