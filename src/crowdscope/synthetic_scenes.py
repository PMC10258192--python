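"""Ground-truth-labeled synthetic inputs for the crowding-sensor pipeline.

Real condensate experiments give two-channel (CFP donor / YFP acceptor)
images of cells expressing a FRET crowding sensor, FRAP time traces, and
crowder-titration ratio series.  This module simulates all three with
known ground truth so that every downstream stage — ratio imaging, phase
splitting, assembly-mode classification, FRAP and titration fitting —
can be tested against the parameters that generated its input.

Two ground-truth assembly modes are supported, mirroring the two ways a
condensate can form:

* ``aggregation`` — small oligomers concentrate into the condensate and
  the local macromolecular crowding is *higher* inside than outside
  (heterochromatin / HP1a-like behaviour);
* ``consolidation`` — pre-formed large polymers join up without raising
  local crowding, so the dense phase is bright but *not* more crowded
  (nuclear-speckle / SRSF2-like behaviour).

All randomness flows from an explicit ``seed`` argument; there is no
module-level RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InsufficientDataError, InvalidGeometryError, PlacementError
from .frap_dynamics import FRAPTrace
from .calibration import TitrationSeries

AGGREGATION = "aggregation"
CONSOLIDATION = "consolidation"
MODES = (AGGREGATION, CONSOLIDATION)


# --------------------------------------------------------------------------- #
# sensor forward model
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SensorModel:
    """Crowding -> FRET response of a donor-linker-acceptor sensor.

    The FRET efficiency follows a hyperbolic saturation in the local
    crowding level ``c``::

        E(c) = E_min + (E_max - E_min) * c / (c + K_half)

    which is monotone, saturating and analytically invertible — the
    qualitative behaviour of linker-compression crowding sensors.

    Parameters
    ----------
    E_min, E_max:
        FRET efficiency at zero and saturating crowding, ``0 <= E_min <
        E_max <= 1``.
    K_half:
        Crowding level giving the half-maximal response, in the same
        units as the crowding field (volume-fraction-like in [0, 1] for
        imaging, g/L for in vitro titrations).
    gamma:
        Acceptor/donor detection-efficiency ratio (> 0).
    crosstalk:
        Donor bleedthrough fraction into the acceptor channel, in [0, 1).
    """

    E_min: float = 0.2
    E_max: float = 0.6
    K_half: float = 0.3
    gamma: float = 1.0
    crosstalk: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.E_min < self.E_max <= 1.0):
            raise ValueError(f"need 0 <= E_min < E_max <= 1, got ({self.E_min}, {self.E_max})")
        if self.K_half <= 0:
            raise ValueError("K_half must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not (0.0 <= self.crosstalk < 1.0):
            raise ValueError("crosstalk must be in [0, 1)")

    def efficiency(self, crowding):
        """FRET efficiency E(c) for a crowding level or array."""
        c = np.asarray(crowding, dtype=float)
        return self.E_min + (self.E_max - self.E_min) * c / (c + self.K_half)

    def expected_ratio(self, crowding):
        """Noiseless acceptor/donor ratio gamma*E/(1-E) + crosstalk."""
        E = self.efficiency(crowding)
        return self.gamma * E / (1.0 - E) + self.crosstalk


@dataclass(frozen=True)
class NoiseModel:
    """Camera/photon noise applied when rendering channels.

    counts = gain * Poisson((signal + background) / gain) + N(0, read_sigma)

    with the result clipped at zero.  ``gain`` is counts per photon.
    """

    gain: float = 1.0
    read_sigma: float = 2.0
    background_donor: float = 10.0
    background_acceptor: float = 10.0
    photon_noise: bool = True
    read_noise: bool = True

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")


DEFAULT_NOISE = NoiseModel()


# --------------------------------------------------------------------------- #
# scene ground truth
# --------------------------------------------------------------------------- #

@dataclass
class SceneGroundTruth:
    """Latent state of one simulated cell.

    Attributes
    ----------
    concentration_map:
        Per-pixel sensor concentration in photon-rate units (>= 0).
    crowding_map:
        Per-pixel crowding level in [0, 1].
    cell_mask, condensate_mask:
        Boolean masks; ``condensate_mask`` is a subset of ``cell_mask``.
    mode_label:
        ``"aggregation"`` or ``"consolidation"``.
    pixel_size:
        Physical pixel size in micrometres.
    """

    concentration_map: np.ndarray
    crowding_map: np.ndarray
    cell_mask: np.ndarray
    condensate_mask: np.ndarray
    mode_label: str
    pixel_size: float = 0.1
    params: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.concentration_map.shape


@dataclass
class ChannelPair:
    """Donor (CFP) and acceptor (YFP) intensity images plus provenance."""

    donor: np.ndarray
    acceptor: np.ndarray
    noise: NoiseModel | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.donor.shape != self.acceptor.shape:
            raise ValueError("donor and acceptor images must share a shape")
        if not (np.all(np.isfinite(self.donor)) and np.all(np.isfinite(self.acceptor))):
            raise ValueError("channel images must be finite")
        if self.donor.min() < 0 or self.acceptor.min() < 0:
            raise ValueError("channel counts must be >= 0")


def _elliptical_mask(height, width, rng):
    """Elliptical 'nucleus' mask with mildly randomized semi-axes."""
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    a = rng.uniform(0.36, 0.44) * width   # semi-axis along x
    b = rng.uniform(0.32, 0.40) * height  # semi-axis along y
    yy, xx = np.mgrid[0:height, 0:width]
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    return mask, (cy, cx, a, b)


def make_scene(
    width: int = 256,
    height: int = 256,
    n_condensates: int = 6,
    enrichment: float = 3.0,
    crowding_dense: float = 0.4,
    crowding_dilute: float = 0.3,
    mode_label: str = AGGREGATION,
    seed: int | None = None,
    *,
    base_concentration: float = 100.0,
    radius_range: tuple[float, float] = (3.0, 8.0),
    pixel_size: float = 0.1,
    texture_sigma: float = 0.0,
    texture_scale: float = 4.0,
    max_retries: int = 1000,
) -> SceneGroundTruth:
    """Simulate the latent state of one sensor-expressing cell.

    Builds an elliptical cell (nucleus) containing ``n_condensates``
    non-overlapping disc condensates.  Sensor concentration is
    ``base_concentration`` in the cell and ``enrichment`` times that in
    condensates; crowding is ``crowding_dilute`` in the cell and
    ``crowding_dense`` in condensates.

    ``texture_sigma`` optionally multiplies the in-cell concentration by
    a smooth random field ``1 + t`` (``t`` zero-mean with the given
    standard deviation, correlation length ``texture_scale`` px),
    emulating intracellular concentration heterogeneity.  It defaults to
    off, in which case concentrations are exactly two-level.

    Raises
    ------
    InvalidGeometryError
        If the cell mask would be empty.
    PlacementError
        If non-overlapping placement fails after ``max_retries`` draws
        per condensate.
    """
    if mode_label not in MODES:
        raise ValueError(f"mode_label must be one of {MODES}")
    if enrichment < 1.0:
        raise ValueError("enrichment must be >= 1")
    for name, c in (("crowding_dense", crowding_dense), ("crowding_dilute", crowding_dilute)):
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if n_condensates < 0:
        raise ValueError("n_condensates must be >= 0")
    if n_condensates > 0:
        if mode_label == AGGREGATION and not (crowding_dense > crowding_dilute):
            raise ValueError("aggregation scenes need crowding_dense > crowding_dilute")
        if mode_label == CONSOLIDATION and crowding_dense > crowding_dilute:
            raise ValueError("consolidation scenes need crowding_dense <= crowding_dilute")

    rng = np.random.default_rng(seed)
    if width < 4 or height < 4:
        raise InvalidGeometryError(f"image {width}x{height} too small for a cell")
    cell_mask, (cy, cx, a, b) = _elliptical_mask(height, width, rng)
    if not cell_mask.any():
        raise InvalidGeometryError("cell mask is empty")

    yy, xx = np.mgrid[0:height, 0:width]
    condensate_mask = np.zeros_like(cell_mask)
    placed: list[tuple[float, float, float]] = []
    r_lo, r_hi = radius_range
    for _ in range(n_condensates):
        for attempt in range(max_retries):
            r = rng.uniform(r_lo, r_hi)
            # keep the disc fully inside the ellipse: shrink the sampling ellipse
            u, v = rng.uniform(-1, 1), rng.uniform(-1, 1)
            if u * u + v * v > 1:
                continue
            x = cx + u * max(a - r - 1, 1.0)
            y = cy + v * max(b - r - 1, 1.0)
            if ((x - cx) / max(a - r, 1e-9)) ** 2 + ((y - cy) / max(b - r, 1e-9)) ** 2 > 1:
                continue
            if any((x - px) ** 2 + (y - py) ** 2 < (r + pr + 1.0) ** 2 for px, py, pr in placed):
                continue
            placed.append((x, y, r))
            condensate_mask |= (xx - x) ** 2 + (yy - y) ** 2 <= r * r
            break
        else:
            raise PlacementError(
                f"could not place condensate {len(placed) + 1}/{n_condensates} "
                f"after {max_retries} attempts"
            )
    condensate_mask &= cell_mask  # defensive; placement already guarantees it

    concentration = np.zeros((height, width), dtype=float)
    concentration[cell_mask] = base_concentration
    concentration[condensate_mask] = enrichment * base_concentration
    if texture_sigma > 0:
        raw = rng.standard_normal((height, width))
        smooth = ndimage.gaussian_filter(raw, sigma=texture_scale)
        smooth /= smooth.std()
        texture = np.clip(1.0 + texture_sigma * smooth, 0.1, None)
        concentration *= texture

    crowding = np.zeros((height, width), dtype=float)
    crowding[cell_mask] = crowding_dilute
    crowding[condensate_mask] = crowding_dense

    return SceneGroundTruth(
        concentration_map=concentration,
        crowding_map=crowding,
        cell_mask=cell_mask,
        condensate_mask=condensate_mask,
        mode_label=mode_label,
        pixel_size=pixel_size,
        params=dict(
            width=width, height=height, n_condensates=n_condensates,
            enrichment=enrichment, crowding_dense=crowding_dense,
            crowding_dilute=crowding_dilute, base_concentration=base_concentration,
            radius_range=radius_range, texture_sigma=texture_sigma,
            texture_scale=texture_scale, seed=seed, centers=placed,
        ),
    )


def render_fret_images(
    scene: SceneGroundTruth,
    sensor: SensorModel,
    noise: NoiseModel | None = DEFAULT_NOISE,
    seed: int | None = None,
) -> ChannelPair:
    """Render a scene through the sensor into donor/acceptor channels.

    Per pixel with concentration ``C`` and crowding ``c``::

        E        = E_min + (E_max - E_min) * c / (c + K_half)
        donor    = C * (1 - E)
        acceptor = gamma * C * E + crosstalk * donor

    With ``noise=None`` these closed forms hold exactly (zero
    background); otherwise the per-channel background offset is added
    and Poisson photon noise plus Gaussian read noise applied.
    """
    C = scene.concentration_map
    c = scene.crowding_map
    if not (np.all(np.isfinite(C)) and np.all(np.isfinite(c))):
        raise ValueError("scene contains non-finite concentration or crowding")
    E = sensor.efficiency(c)
    donor = C * (1.0 - E)
    acceptor = sensor.gamma * C * E + sensor.crosstalk * donor
    if noise is None:
        return ChannelPair(donor=donor, acceptor=acceptor, noise=None,
                           metadata={"seed": seed, "pixel_size": scene.pixel_size})

    rng = np.random.default_rng(seed)
    out = []
    for img, bg in ((donor, noise.background_donor), (acceptor, noise.background_acceptor)):
        mean = img + bg
        if noise.photon_noise:
            img_n = noise.gain * rng.poisson(mean / noise.gain).astype(float)
        else:
            img_n = mean.copy()
        if noise.read_noise and noise.read_sigma > 0:
            img_n += rng.normal(0.0, noise.read_sigma, size=img.shape)
        out.append(np.clip(img_n, 0.0, None))
    return ChannelPair(donor=out[0], acceptor=out[1], noise=noise,
                       metadata={"seed": seed, "pixel_size": scene.pixel_size})


# --------------------------------------------------------------------------- #
# FRAP and titration simulators
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class FRAPSimParams:
    """Parameters of a reaction-limited FRAP recovery simulation.

    The bleach happens at ``t_bleach`` (the paper-matching default is
    10 s); recovery is a single exponential toward the plateau set by
    the mobile fraction.
    """

    t_bleach: float = 10.0
    pre_level: float = 1.0
    post_level: float = 0.3
    mobile_fraction: float = 0.8
    tau: float = 20.0
    interval: float = 0.5
    duration: float = 120.0
    noise_sigma: float = 0.0

    def __post_init__(self):
        if not self.post_level < self.pre_level:
            raise ValueError("post_level must be < pre_level")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if not (0.0 <= self.mobile_fraction <= 1.0):
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if self.interval <= 0 or self.duration <= 0:
            raise ValueError("interval and duration must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def frap_model(t, t_bleach, pre_level, post_level, mobile_fraction, tau):
    """Noiseless reaction-limited recovery curve; vectorized in ``t``."""
    t = np.asarray(t, dtype=float)
    post = post_level + mobile_fraction * (pre_level - post_level) * (
        1.0 - np.exp(-(t - t_bleach) / tau)
    )
    return np.where(t < t_bleach, pre_level, post)


def simulate_frap_trace(params: FRAPSimParams, seed: int | None = None) -> FRAPTrace:
    """Simulate one FRAP time-intensity trace with Gaussian noise."""
    if params.duration <= params.t_bleach:
        raise InsufficientDataError("duration must exceed t_bleach (no post-bleach samples)")
    times = np.arange(0.0, params.duration + params.interval / 2, params.interval)
    clean = frap_model(times, params.t_bleach, params.pre_level,
                       params.post_level, params.mobile_fraction, params.tau)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, params.noise_sigma, size=times.shape)
    return FRAPTrace(times=times, intensities=clean, t_bleach=params.t_bleach)


@dataclass(frozen=True)
class TitrationSimParams:
    """Ficoll-like crowder titration of a purified sensor.

    The ratio response is the same hyperbolic saturation used for the
    imaging sensor, on a g/L concentration axis:
    ``R(c) = R0 + delta_R * c / (c + K_c)``.
    """

    crowder_concentrations: tuple = (0.0, 50.0, 100.0, 150.0, 200.0, 300.0)
    R0: float = 1.0
    delta_R: float = 0.4
    K_c: float = 75.0
    replicate_count: int = 3
    noise_sigma: float = 0.0

    def __post_init__(self):
        conc = np.asarray(self.crowder_concentrations, dtype=float)
        if conc.size == 0:
            raise ValueError("crowder_concentrations must be non-empty")
        if conc.min() < 0 or not np.all(np.diff(conc) > 0):
            raise ValueError("concentrations must be non-negative and strictly increasing")
        if self.delta_R < 0:
            raise ValueError("delta_R must be >= 0")
        if self.K_c <= 0:
            raise ValueError("K_c must be > 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


def titration_model(conc, R0, delta_R, K_c):
    """Hyperbolic saturation ratio response R(c)."""
    conc = np.asarray(conc, dtype=float)
    return R0 + delta_R * conc / (conc + K_c)


def simulate_titration(
    params: TitrationSimParams, seed: int | None = None, sensor_id: str = "sensor"
) -> TitrationSeries:
    """Simulate replicate FRET-ratio measurements along a crowder titration."""
    conc = np.asarray(params.crowder_concentrations, dtype=float)
    clean = titration_model(conc, params.R0, params.delta_R, params.K_c)
    ratios = np.tile(clean, (params.replicate_count, 1))
    if params.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        ratios = ratios + rng.normal(0.0, params.noise_sigma, size=ratios.shape)
    return TitrationSeries(concentrations=conc, ratios=ratios, sensor_id=sensor_id)
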