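"""End-to-end orchestration, file formats and fixture generation.

Ties the stages together: simulate (or read) two-channel images ->
ratio image -> dense/dilute phase split -> per-cell measurements ->
control-group normalization -> assembly-mode verdict.  Also owns the
on-disk formats (2-channel TIFF for images, CSV for traces, series and
measurement tables, YAML for configs/manifests) and the seeded fixture
generator used by the test-suite and the worked examples.

Simulated-experiment defaults (the study conditions)
----------------------------------------------------
Aggregation-truth ("HP1a-like") experiments use a dense-phase crowding
of 0.38 against a dilute 0.30, which through the default sensor gives a
normalized dense-vs-dilute ratio contrast of ~0.10; consolidation-truth
("SRSF2-like") experiments use equal crowding (zero contrast).  Scenes
carry a smooth ±20% concentration texture emulating intracellular
heterogeneity, and images get the default photon + read noise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import CrowdscopeError, PipelineStageError
from .synthetic_scenes import (
    AGGREGATION, CONSOLIDATION, ChannelPair, DEFAULT_NOISE, FRAPSimParams,
    NoiseModel, SceneGroundTruth, SensorModel, TitrationSimParams, make_scene,
    render_fret_images, simulate_frap_trace, simulate_titration,
)
from .ratiometric import compute_ratio_image, normalize_ratios
from .phase_split import (
    PhaseMeasurement, derive_cell_mask, measure_phase_ratios, segment_phases,
)
from .assembly_call import AssemblyCall, classify_assembly_mode
from .frap_dynamics import FRAPTrace

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = ["cell_id", "region", "mean_ratio", "mean_intensity",
                       "n_pixels", "normalized_ratio"]


# --------------------------------------------------------------------------- #
# configuration
# --------------------------------------------------------------------------- #

@dataclass
class RunConfig:
    """Resolved configuration of one analysis run.

    Every analysis output embeds the full config plus the software
    version, so thresholds and quantiles are always auditable.
    """

    input_dir: str | None = None
    out_dir: str | None = None
    background: object = "auto"          # "auto" | scalar | (donor, acceptor)
    intensity_threshold: float = 6.0
    donor_bleedthrough: float = 0.0
    dense_quantile: float = 0.10
    dilute_quantile: float = 0.30
    smooth_sigma: float = 1.5
    min_pixels: int = 20
    alpha: float = 0.05
    min_effect: float = 0.02
    bootstrap_n: int = 2000
    min_cells: int = 10
    seed: int = 0
    control: str = "dilute"              # control group for normalization

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["background"], tuple):
            d["background"] = list(d["background"])
        d["version"] = __version__
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a flat key: value config file; unknown keys are rejected."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.pop("version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CrowdscopeError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(data.get("background"), list):
            data["background"] = tuple(data["background"])
        return cls(**data)


# --------------------------------------------------------------------------- #
# file formats
# --------------------------------------------------------------------------- #

def write_channel_tiff(path, channels: ChannelPair) -> None:
    """Write donor/acceptor as a 2-channel 16-bit TIFF (donor first)."""
    stack = np.stack([channels.donor, channels.acceptor])
    data = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={"axes": "CYX",
                                           "channels": ["donor", "acceptor"]})


def read_channel_tiff(path) -> ChannelPair:
    data = tifffile.imread(path)
    if data.ndim != 3 or data.shape[0] != 2:
        raise CrowdscopeError(f"{path}: expected a 2-channel (CYX) TIFF, got {data.shape}")
    return ChannelPair(donor=data[0].astype(float), acceptor=data[1].astype(float))


def write_mask_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, mask.astype(np.uint8) * 255)


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_frap_csv(path, traces: dict[str, FRAPTrace]) -> None:
    """Trace table with columns time_s, intensity, cell_id, t_bleach_s."""
    rows = [pd.DataFrame({"cell_id": cid, "time_s": tr.times,
                          "intensity": tr.intensities, "t_bleach_s": tr.t_bleach})
            for cid, tr in traces.items()]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_frap_csv(path) -> dict[str, FRAPTrace]:
    df = pd.read_csv(path)
    out = {}
    for cid, grp in df.groupby("cell_id", sort=False):
        out[str(cid)] = FRAPTrace(times=grp["time_s"].to_numpy(),
                                  intensities=grp["intensity"].to_numpy(),
                                  t_bleach=float(grp["t_bleach_s"].iloc[0]))
    return out


def write_titration_csv(path, series) -> None:
    """Titration table with columns conc_gL, replicate, ratio, sensor_id."""
    n_rep, n_conc = series.ratios.shape
    df = pd.DataFrame({
        "conc_gL": np.tile(series.concentrations, n_rep),
        "replicate": np.repeat(np.arange(n_rep), n_conc),
        "ratio": series.ratios.ravel(),
        "sensor_id": series.sensor_id,
    })
    df.to_csv(path, index=False)


def read_titration_csv(path):
    from .calibration import TitrationSeries

    df = pd.read_csv(path)
    conc = np.sort(df["conc_gL"].unique())
    reps = np.sort(df["replicate"].unique())
    ratios = np.empty((reps.size, conc.size))
    for i, r in enumerate(reps):
        sub = df[df["replicate"] == r].sort_values("conc_gL")
        ratios[i] = sub["ratio"].to_numpy()
    sensor_id = str(df["sensor_id"].iloc[0]) if "sensor_id" in df else "sensor"
    return TitrationSeries(concentrations=conc, ratios=ratios, sensor_id=sensor_id)


def measurements_to_frame(measurements, normalized=None) -> pd.DataFrame:
    """Long-form measurement table (one row per cell x region)."""
    rows = []
    for i, m in enumerate(measurements):
        for region in ("dense", "dilute"):
            raw = getattr(m, f"{region}_mean_ratio")
            norm = getattr(normalized[i], f"{region}_mean_ratio") if normalized else np.nan
            rows.append({"cell_id": m.cell_id, "region": region, "mean_ratio": raw,
                         "mean_intensity": getattr(m, f"{region}_mean_intensity"),
                         "n_pixels": getattr(m, f"n_{region}"),
                         "normalized_ratio": norm})
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def frame_to_paired_measurements(df: pd.DataFrame, column: str = "normalized_ratio"):
    """Rebuild PhaseMeasurement pairs from a long-form measurement table."""
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise CrowdscopeError(f"measurement table missing columns: {sorted(missing)}")
    out = []
    for cid, grp in df.groupby("cell_id", sort=False):
        by_region = {r["region"]: r for _, r in grp.iterrows()}
        if not {"dense", "dilute"} <= set(by_region):
            raise CrowdscopeError(f"cell {cid}: need one dense and one dilute row")
        d, l = by_region["dense"], by_region["dilute"]
        out.append(PhaseMeasurement(
            cell_id=str(cid),
            dense_mean_ratio=float(d[column]), dilute_mean_ratio=float(l[column]),
            dense_mean_intensity=float(d["mean_intensity"]),
            dilute_mean_intensity=float(l["mean_intensity"]),
            n_dense=int(d["n_pixels"]), n_dilute=int(l["n_pixels"]),
        ))
    return out


# --------------------------------------------------------------------------- #
# per-cell analysis and simulated experiments
# --------------------------------------------------------------------------- #

def analyze_cell(channels: ChannelPair, config: RunConfig,
                 cell_mask: np.ndarray | None = None, cell_id: str = "cell"):
    """Run ratio -> split -> measure for one cell.

    Returns ``(PhaseMeasurement, RatioImage, PhaseMasks)``.  The cell
    mask is derived by Otsu segmentation of the acceptor channel when
    not supplied.
    """
    if cell_mask is None:
        cell_mask = derive_cell_mask(channels.acceptor)
    ratio = compute_ratio_image(
        channels, background=config.background,
        intensity_threshold=config.intensity_threshold,
        cell_mask=cell_mask, donor_bleedthrough=config.donor_bleedthrough,
    )
    masks = segment_phases(
        channels.acceptor, cell_mask,
        dense_quantile=config.dense_quantile, dilute_quantile=config.dilute_quantile,
        validity_mask=ratio.valid_mask, smooth_sigma=config.smooth_sigma,
    )
    measurement = measure_phase_ratios(ratio, masks, channels.acceptor,
                                       min_pixels=config.min_pixels, cell_id=cell_id)
    log.info("cell %s: dense %d px (ratio %.4f), dilute %d px (ratio %.4f), "
             "%d negative-acceptor px", cell_id, measurement.n_dense,
             measurement.dense_mean_ratio, measurement.n_dilute,
             measurement.dilute_mean_ratio, ratio.n_negative_acceptor)
    return measurement, ratio, masks


@dataclass(frozen=True)
class ExperimentConditions:
    """Ground-truth parameters of one simulated imaging experiment."""

    mode: str = AGGREGATION
    width: int = 128
    height: int = 128
    n_condensates: int = 8
    enrichment: float = 3.0
    crowding_dilute: float = 0.30
    crowding_dense: float = 0.38          # ~0.10 normalized ratio contrast
    base_concentration: float = 100.0
    radius_range: tuple = (4.0, 6.0)
    texture_sigma: float = 0.2
    texture_scale: float = 4.0
    sensor: SensorModel = field(default_factory=SensorModel)
    noise: NoiseModel | None = field(default_factory=NoiseModel)

    def with_mode(self, mode: str) -> "ExperimentConditions":
        """Conditions for the given truth; consolidation gets zero contrast."""
        dense = self.crowding_dense if mode == AGGREGATION else self.crowding_dilute
        return dataclasses.replace(self, mode=mode, crowding_dense=dense)


HP1A_LIKE = ExperimentConditions().with_mode(AGGREGATION)
SRSF2_LIKE = ExperimentConditions().with_mode(CONSOLIDATION)


def simulate_cell(conditions: ExperimentConditions, seed):
    """One scene + rendered channel pair under the given conditions."""
    scene = make_scene(
        width=conditions.width, height=conditions.height,
        n_condensates=conditions.n_condensates, enrichment=conditions.enrichment,
        crowding_dense=conditions.crowding_dense,
        crowding_dilute=conditions.crowding_dilute,
        mode_label=conditions.mode, seed=seed,
        base_concentration=conditions.base_concentration,
        radius_range=conditions.radius_range,
        texture_sigma=conditions.texture_sigma,
        texture_scale=conditions.texture_scale,
    )
    channels = render_fret_images(scene, conditions.sensor, conditions.noise,
                                  seed=None if seed is None else seed + 1_000_003)
    return scene, channels


def simulate_experiment_measurements(
    conditions: ExperimentConditions, n_cells: int, seed: int,
    config: RunConfig | None = None,
):
    """Simulate and analyze one experiment of ``n_cells`` cells.

    Returns normalized per-cell :class:`PhaseMeasurement`s (ratios
    divided by the mean dilute-phase ratio of the experiment, the
    control group) together with the raw measurements.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    raw = []
    for i in range(n_cells):
        cell_seed = int(rng.integers(0, 2**31 - 1))
        scene, channels = simulate_cell(conditions, cell_seed)
        m, _, _ = analyze_cell(channels, config, cell_mask=scene.cell_mask,
                               cell_id=f"cell_{i:03d}")
        raw.append(m)
    normalized = normalize_measurements(raw, control=config.control)
    return normalized, raw


def normalize_measurements(measurements, control: str = "dilute"):
    """Normalize all per-cell ratios by the control-group mean ratio."""
    if control != "dilute":
        raise CrowdscopeError(f"unknown control group {control!r}")
    control_values = [m.dilute_mean_ratio for m in measurements]
    out = []
    for m in measurements:
        (dense_n, dilute_n), _ = normalize_ratios(
            [m.dense_mean_ratio, m.dilute_mean_ratio], control_values)
        out.append(dataclasses.replace(m, dense_mean_ratio=float(dense_n),
                                       dilute_mean_ratio=float(dilute_n)))
    return out


# --------------------------------------------------------------------------- #
# end-to-end run
# --------------------------------------------------------------------------- #

@dataclass
class RunResult:
    call: AssemblyCall
    measurements: pd.DataFrame
    failures: list
    out_dir: Path | None


def run_end_to_end(config: RunConfig) -> RunResult:
    """Analyze every 2-channel TIFF under ``config.input_dir``.

    Per-cell failures are recorded (stage + cell id) in a failure
    manifest and do not abort the remaining cells; the verdict is
    computed on the cells that succeeded.  All intermediate tables, the
    resolved config and the verdict are written under
    ``config.out_dir`` when set.
    """
    in_dir = Path(config.input_dir)
    cell_paths = sorted(
        p for p in in_dir.glob("*.tif")
        if not p.stem.endswith(("_cellmask", "_condensates")))
    if not cell_paths:
        raise CrowdscopeError(f"no cell TIFFs found under {in_dir}")
    raw, failures = [], []
    for path in cell_paths:
        cell_id = path.stem
        mask_path = path.with_name(path.stem + "_cellmask.tif")
        try:
            channels = read_channel_tiff(path)
            cell_mask = read_mask_tiff(mask_path) if mask_path.exists() else None
            m, _, _ = analyze_cell(channels, config, cell_mask=cell_mask, cell_id=cell_id)
            raw.append(m)
        except CrowdscopeError as exc:
            err = PipelineStageError("analyze_cell", cell_id, exc)
            log.warning("%s", err)
            failures.append({"cell_id": cell_id, "stage": "analyze_cell", "error": str(exc)})

    normalized = normalize_measurements(raw, control=config.control)
    call = classify_assembly_mode(
        normalized, alpha=config.alpha, min_effect=config.min_effect,
        bootstrap_n=config.bootstrap_n, seed=config.seed, min_cells=config.min_cells,
    )
    table = measurements_to_frame(raw, normalized)

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "measurements.csv", index=False)
        (out_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        verdict = {"mode": call.mode, "effect_size": call.effect_size,
                   "ci_95": list(call.ci_95), "p_value": call.p_value,
                   "n_cells": call.n_cells, "degenerate": call.degenerate,
                   "params": call.params, "version": __version__}
        (out_dir / "verdict.json").write_text(json.dumps(verdict, indent=2, sort_keys=True))
        if failures:
            pd.DataFrame(failures).to_csv(out_dir / "failures.csv", index=False)
    return RunResult(call=call, measurements=table, failures=failures, out_dir=out_dir)


def hash_outputs(out_dir) -> dict:
    """SHA-256 of every file under a run directory (determinism checks)."""
    out = {}
    for p in sorted(Path(out_dir).rglob("*")):
        if p.is_file():
            out[str(p.relative_to(out_dir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


# --------------------------------------------------------------------------- #
# fixture suite
# --------------------------------------------------------------------------- #

FRAP_GROUND_TRUTH = {
    # low-mobility heterochromatin-like vs high-mobility speckle-like
    "hp1a_like": dict(mobile_fraction=0.5, tau=30.0),
    "srsf2_like": dict(mobile_fraction=0.9, tau=5.0),
}

TITRATION_GROUND_TRUTH = {
    # the optimized long-linker sensor has twice the dynamic range
    "crowding_sensor": dict(R0=1.0, delta_R=0.2, K_c=75.0),
    "cyr090": dict(R0=1.0, delta_R=0.4, K_c=75.0),
}


def generate_fixture_suite(out_dir, seed: int, n_cells: int = 6,
                           conditions: ExperimentConditions | None = None) -> Path:
    """Write a labeled synthetic experiment suite under ``out_dir``.

    Emits aggregation-truth and consolidation-truth image sets (with
    cell masks and ground-truth condensate masks), FRAP traces for a
    slow and a fast protein, titration series for a low- and a
    high-dynamic-range sensor, and a YAML manifest of every ground-truth
    parameter.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = conditions or ExperimentConditions()
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "n_cells": n_cells, "version": __version__,
                      "conditions": {}, "frap": FRAP_GROUND_TRUTH,
                      "titration": TITRATION_GROUND_TRUTH}

    for name, mode in (("hp1a_like", AGGREGATION), ("srsf2_like", CONSOLIDATION)):
        cond = base.with_mode(mode)
        cond_dir = out_dir / name
        cond_dir.mkdir(exist_ok=True)
        manifest["conditions"][name] = {
            "mode": mode, "crowding_dense": cond.crowding_dense,
            "crowding_dilute": cond.crowding_dilute, "enrichment": cond.enrichment,
            "expected_ratio_dense": float(cond.sensor.expected_ratio(cond.crowding_dense)),
            "expected_ratio_dilute": float(cond.sensor.expected_ratio(cond.crowding_dilute)),
        }
        for i in range(n_cells):
            cell_seed = int(rng.integers(0, 2**31 - 1))
            scene, channels = simulate_cell(cond, cell_seed)
            stem = cond_dir / f"cell_{i:03d}"
            write_channel_tiff(f"{stem}.tif", channels)
            write_mask_tiff(f"{stem}_cellmask.tif", scene.cell_mask)
            write_mask_tiff(f"{stem}_condensates.tif", scene.condensate_mask)

    traces = {}
    for name, truth in FRAP_GROUND_TRUTH.items():
        for i in range(12):
            params = FRAPSimParams(mobile_fraction=truth["mobile_fraction"],
                                   tau=truth["tau"], noise_sigma=0.02)
            traces[f"{name}_{i:02d}"] = simulate_frap_trace(
                params, seed=int(rng.integers(0, 2**31 - 1)))
    write_frap_csv(out_dir / "frap_traces.csv", traces)

    for name, truth in TITRATION_GROUND_TRUTH.items():
        # replicate noise: 1% of the sensor's dynamic range
        params = TitrationSimParams(R0=truth["R0"], delta_R=truth["delta_R"],
                                    K_c=truth["K_c"],
                                    noise_sigma=0.01 * truth["delta_R"])
        series = simulate_titration(params, seed=int(rng.integers(0, 2**31 - 1)),
                                    sensor_id=name)
        write_titration_csv(out_dir / f"titration_{name}.csv", series)

    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return out_dir
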