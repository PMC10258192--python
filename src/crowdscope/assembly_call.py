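"""Population-level statistics and the assembly-mode verdict.

Given per-cell paired dense/dilute crowding ratios, the classifier asks
whether the dense phase is demonstrably more crowded than the dilute
phase.  If it is (one-sided paired Wilcoxon signed-rank significant AND
the mean paired difference exceeds a minimal practical effect), the
condensate is called *aggregation* — oligomers concentrating and
crowding their surroundings.  Otherwise the verdict defaults to
*consolidation* — pre-formed polymers joining without elevated local
crowding.  Group summaries are reported as mean ± SEM, the convention
of the figures this pipeline emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

AGGREGATION = "aggregation"
CONSOLIDATION = "consolidation"


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SEM of a group, with the raw values retained."""

    n: int
    mean: float
    sd: float
    sem: float
    values: np.ndarray = field(repr=False)


def summarize_group(values) -> GroupSummary:
    """Mean, sample SD (ddof=1) and SEM = sd/sqrt(n) of a collection."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise InsufficientDataError("need n >= 2 for mean ± SEM")
    sd = float(v.std(ddof=1))
    return GroupSummary(n=v.size, mean=float(v.mean()), sd=sd,
                        sem=sd / np.sqrt(v.size), values=v)


@dataclass(frozen=True)
class AssemblyCall:
    """The pipeline's verdict on how a condensate system assembles."""

    mode: str                    # "aggregation" | "consolidation"
    effect_size: float           # mean paired dense - dilute normalized-ratio difference
    ci_95: tuple                 # bootstrap CI of the mean difference
    p_value: float               # one-sided paired Wilcoxon (dense > dilute)
    n_cells: int
    degenerate: bool = False     # all paired differences were exactly zero
    params: dict = field(default_factory=dict)


def _bootstrap_ci(diffs: np.ndarray, n_boot: int, seed, level: float = 0.95):
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, diffs.size, size=(n_boot, diffs.size))
    means = diffs[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    return (float(np.quantile(means, lo)), float(np.quantile(means, 1.0 - lo)))


def classify_assembly_mode(
    measurements,
    alpha: float = 0.05,
    min_effect: float = 0.02,
    bootstrap_n: int = 2000,
    seed: int | None = None,
    min_cells: int = 10,
) -> AssemblyCall:
    """Call the assembly mode from per-cell phase measurements.

    ``measurements`` is a collection of
    :class:`~crowdscope.phase_split.PhaseMeasurement` whose ratios are
    already consistently normalized (per-experiment control-group
    normalization), or a ``(dense, dilute)`` pair of equal-length
    arrays.  ``min_effect`` is in normalized-ratio units and guards
    against microscopically small but statistically significant
    contrasts; ``seed`` makes the bootstrap CI reproducible.
    """
    if isinstance(measurements, tuple) and len(measurements) == 2:
        dense = np.asarray(measurements[0], dtype=float)
        dilute = np.asarray(measurements[1], dtype=float)
    else:
        dense = np.array([m.dense_mean_ratio for m in measurements], dtype=float)
        dilute = np.array([m.dilute_mean_ratio for m in measurements], dtype=float)
    if dense.shape != dilute.shape:
        raise ValueError("dense and dilute collections must pair up")
    n = dense.size
    if n < min_cells:
        raise InsufficientDataError(f"need >= {min_cells} cells, got {n}")

    diffs = dense - dilute
    params = dict(alpha=alpha, min_effect=min_effect, bootstrap_n=bootstrap_n,
                  seed=seed, min_cells=min_cells)
    if np.all(diffs == 0):
        return AssemblyCall(mode=CONSOLIDATION, effect_size=0.0, ci_95=(0.0, 0.0),
                            p_value=1.0, n_cells=n, degenerate=True, params=params)

    res = stats.wilcoxon(diffs, alternative="greater")
    p = float(res.pvalue)
    effect = float(diffs.mean())
    ci = _bootstrap_ci(diffs, bootstrap_n, seed)
    mode = AGGREGATION if (p < alpha and effect > min_effect) else CONSOLIDATION
    return AssemblyCall(mode=mode, effect_size=effect, ci_95=ci, p_value=p,
                        n_cells=n, params=params)


@dataclass(frozen=True)
class ConditionComparison:
    """Two-sided Mann-Whitney contrast between two unpaired groups."""

    statistic: float
    p_value: float
    direction: str  # "A>B" | "B>A" | "none"
    n_a: int
    n_b: int


def compare_conditions(
    group_a: GroupSummary, group_b: GroupSummary,
    alpha: float = 0.05, min_n: int = 5,
) -> ConditionComparison:
    """Unpaired two-group contrast (e.g. interphase vs prometaphase).

    Mann-Whitney U, two-sided; the direction reports which group has the
    larger mean when the contrast is significant, else ``"none"``.
    """
    if group_a.n < min_n or group_b.n < min_n:
        raise InsufficientDataError(f"need >= {min_n} values per group")
    res = stats.mannwhitneyu(group_a.values, group_b.values, alternative="two-sided")
    p = float(res.pvalue)
    if p >= alpha or group_a.mean == group_b.mean:
        direction = "none"
    else:
        direction = "A>B" if group_a.mean > group_b.mean else "B>A"
    return ConditionComparison(statistic=float(res.statistic), p_value=p,
                               direction=direction, n_a=group_a.n, n_b=group_b.n)
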