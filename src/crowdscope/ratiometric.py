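"""Pixelwise YFP/CFP emission-ratio images.

The crowding readout of the sensor is the acceptor/donor (YFP/CFP)
emission ratio: a higher ratio means more FRET, i.e. a more crowded
environment compressing the sensor linker.  This module turns a
two-channel image into a validity-masked ratio image, normalizes ratio
collections against a control group, and renders color-coded ratio
panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import matplotlib

from .errors import EmptyRatioError, NormalizationError
from .synthetic_scenes import ChannelPair

log = logging.getLogger(__name__)

#: default validity threshold on the background-subtracted donor, in counts
#: (3x the default read-noise sigma; dimmer pixels give unstable ratios)
DEFAULT_INTENSITY_THRESHOLD = 6.0


@dataclass
class RatioImage:
    """A YFP/CFP ratio map with its validity mask and provenance.

    ``ratio_map`` is NaN outside ``valid_mask``.  A pixel is valid when
    its background-subtracted donor exceeds ``intensity_threshold`` and
    its background-subtracted (bleedthrough-corrected) acceptor is
    positive.  ``normalization_factor`` is 1.0 until the image is
    normalized against a control group.
    """

    ratio_map: np.ndarray
    valid_mask: np.ndarray
    background_donor: float
    background_acceptor: float
    intensity_threshold: float
    normalization_factor: float = 1.0
    n_negative_acceptor: int = 0

    @property
    def valid_values(self) -> np.ndarray:
        return self.ratio_map[self.valid_mask]


def estimate_background(image: np.ndarray, cell_mask: np.ndarray | None = None) -> float:
    """Histogram-mode background estimate over pixels outside the cell mask.

    Counts are rounded to integers and the most frequent value returned
    (ties break toward the lower count), which is deterministic and
    robust to the bright in-cell tail.
    """
    outside = image if cell_mask is None else image[~cell_mask]
    if outside.size == 0:
        raise ValueError("no pixels outside the cell mask to estimate background from")
    counts = np.round(np.clip(outside, 0, None)).astype(np.int64).ravel()
    return float(np.bincount(counts).argmax())


def compute_ratio_image(
    channels: ChannelPair,
    background="auto",
    intensity_threshold: float = DEFAULT_INTENSITY_THRESHOLD,
    cell_mask: np.ndarray | None = None,
    donor_bleedthrough: float = 0.0,
) -> RatioImage:
    """Compute the acceptor/donor ratio image of a channel pair.

    Parameters
    ----------
    background:
        ``"auto"`` (histogram mode outside ``cell_mask``, per channel),
        a scalar used for both channels, or a ``(donor, acceptor)``
        pair of scalars.
    intensity_threshold:
        Pixels whose background-subtracted donor is <= this value are
        invalid (counts).
    donor_bleedthrough:
        Optional fraction of donor signal subtracted from the acceptor
        channel before the ratio (sensitized-emission bleedthrough
        correction); default 0, i.e. the raw emission ratio.
    """
    if intensity_threshold < 0:
        raise ValueError("intensity_threshold must be >= 0")
    donor, acceptor = channels.donor, channels.acceptor
    if background == "auto":
        bg_d = estimate_background(donor, cell_mask)
        bg_a = estimate_background(acceptor, cell_mask)
    elif np.isscalar(background):
        bg_d = bg_a = float(background)
    else:
        bg_d, bg_a = (float(b) for b in background)

    d_sub = donor - bg_d
    a_sub = acceptor - bg_a - donor_bleedthrough * d_sub
    valid = d_sub > intensity_threshold
    negative = valid & (a_sub <= 0)
    n_negative = int(negative.sum())
    if n_negative:
        log.info("ratio: %d pixels with non-positive corrected acceptor marked invalid",
                 n_negative)
    valid &= a_sub > 0
    if not valid.any():
        raise EmptyRatioError("no valid pixels after background subtraction and thresholding")

    ratio = np.full(donor.shape, np.nan)
    ratio[valid] = a_sub[valid] / d_sub[valid]
    return RatioImage(
        ratio_map=ratio,
        valid_mask=valid,
        background_donor=bg_d,
        background_acceptor=bg_a,
        intensity_threshold=intensity_threshold,
        n_negative_acceptor=n_negative,
    )


def normalize_ratios(values, control_values):
    """Divide ``values`` by the mean of ``control_values``.

    Returns ``(normalized_values, factor)``; by construction the mean of
    ``control_values / factor`` is exactly 1.  This is the
    per-experiment control-group normalization used for every reported
    ratio panel.
    """
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise NormalizationError("control group is empty")
    factor = float(control.mean())
    if factor <= 0:
        raise NormalizationError(f"control mean must be > 0, got {factor}")
    return np.asarray(values, dtype=float) / factor, factor


def normalize_ratio_image(ratio: RatioImage, control_values) -> RatioImage:
    """Return a copy of ``ratio`` normalized against a control collection."""
    normalized, factor = normalize_ratios(ratio.ratio_map, control_values)
    return replace(ratio, ratio_map=normalized,
                   normalization_factor=ratio.normalization_factor * factor)


def render_ratio_colormap(
    ratio: RatioImage,
    vrange: tuple[float, float],
    cmap: str = "viridis",
    neutral: tuple[int, int, int] = (80, 80, 80),
):
    """Render a ratio image as an 8-bit RGB panel.

    Valid pixels are mapped through a perceptually uniform colormap
    clipped to ``vrange``; invalid pixels get the neutral color.
    Returns ``(rgb, colorbar_meta)`` where the metadata records the
    colormap name and limits for a colorbar.
    """
    lo, hi = vrange
    if not lo < hi:
        raise ValueError("vrange must satisfy lo < hi")
    colormap = matplotlib.colormaps[cmap]
    scaled = np.clip((ratio.ratio_map - lo) / (hi - lo), 0.0, 1.0)
    scaled = np.nan_to_num(scaled, nan=0.0)
    rgb = (colormap(scaled)[..., :3] * 255).astype(np.uint8)
    rgb[~ratio.valid_mask] = np.asarray(neutral, dtype=np.uint8)
    return rgb, {"cmap": cmap, "vmin": lo, "vmax": hi}
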