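"""In vitro sensor calibration: spectra, crowder titrations, linker screens,
and polymer stoichiometry arithmetic.

A purified FRET crowding sensor is titrated with an inert crowder
(Ficoll-like); the donor-normalized acceptor emission rises with
crowder concentration.  The response is fitted with a hyperbolic
saturation ``R(c) = R0 + delta_R * c / (c + K_c)`` — the fewest-parameter
monotone saturating model — and sensors are compared by dynamic range
(``delta_R``) and initial slope (``delta_R / K_c``).

The stoichiometry helper converts an assembly molar mass (e.g. from
SEC-MALS) and a monomer mass into a copy number, rounded to one
significant figure to reflect the "approximately" precision with which
such masses are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import FitFailureError, InsufficientDataError, NormalizationError

DONOR_BAND = (460.0, 500.0)     # nm, CFP-like emission window
ACCEPTOR_BAND = (515.0, 560.0)  # nm, YFP-like emission window


@dataclass(frozen=True)
class EmissionSpectrum:
    """A fluorescence emission spectrum at one crowder concentration."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    crowder_concentration: float = 0.0
    donor_band: tuple = DONOR_BAND
    acceptor_band: tuple = ACCEPTOR_BAND

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)
        if wl.shape != inten.shape or wl.ndim != 1:
            raise ValueError("wavelengths and intensities must be equal-length 1-D arrays")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be >= 0")
        for lo, hi in (self.donor_band, self.acceptor_band):
            if not (wl[0] <= lo < hi <= wl[-1]):
                raise ValueError(f"band ({lo}, {hi}) outside wavelength range")
        d_lo, d_hi = self.donor_band
        a_lo, a_hi = self.acceptor_band
        if max(d_lo, a_lo) < min(d_hi, a_hi):
            raise ValueError("donor and acceptor bands must not overlap")


def _band_integral(wl, inten, lo, hi):
    """Trapezoidal integral over [lo, hi] with interpolated band edges."""
    inside = (wl > lo) & (wl < hi)
    xs = np.concatenate(([lo], wl[inside], [hi]))
    ys = np.concatenate(([np.interp(lo, wl, inten)], inten[inside], [np.interp(hi, wl, inten)]))
    return float(np.trapezoid(ys, xs))


def spectra_to_ratio(spectrum: EmissionSpectrum) -> float:
    """Donor-normalized acceptor band ratio of one spectrum.

    The spectrum is scaled so the integrated donor-band intensity is 1;
    the returned ratio is the integrated acceptor-band intensity after
    that scaling (equivalently acceptor/donor integral ratio), so it is
    invariant to any global intensity rescaling.
    """
    wl, inten = spectrum.wavelengths, spectrum.intensities
    donor = _band_integral(wl, inten, *spectrum.donor_band)
    if donor <= 0:
        raise NormalizationError("donor-band integral must be > 0")
    acceptor = _band_integral(wl, inten, *spectrum.acceptor_band)
    return acceptor / donor


@dataclass(frozen=True)
class TitrationSeries:
    """Replicate FRET-ratio measurements along a crowder titration.

    ``ratios`` has shape ``(n_replicates, n_concentrations)``.
    """

    concentrations: np.ndarray
    ratios: np.ndarray
    sensor_id: str = "sensor"

    def __post_init__(self):
        conc = np.atleast_1d(np.asarray(self.concentrations, dtype=float))
        ratios = np.atleast_2d(np.asarray(self.ratios, dtype=float))
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "ratios", ratios)
        if conc.size == 0:
            raise ValueError("concentrations must be non-empty")
        if ratios.shape[1] != conc.size:
            raise ValueError("ratios must have one column per concentration")
        if conc.min() < 0 or not np.all(np.diff(conc) > 0):
            raise ValueError("concentrations must be non-negative and strictly increasing")

    def mean_ratios(self):
        return self.ratios.mean(axis=0)

    def normalized_to_baseline(self) -> "TitrationSeries":
        """Divide every ratio by the mean zero/lowest-crowder ratio (control)."""
        baseline = float(self.ratios[:, 0].mean())
        if baseline <= 0:
            raise NormalizationError("baseline ratio must be > 0")
        return TitrationSeries(self.concentrations, self.ratios / baseline, self.sensor_id)


@dataclass(frozen=True)
class SensorResponseFit:
    """Hyperbolic-saturation fit of a titration series."""

    R0: float
    delta_R: float
    K_c: float                    # g/L; NaN when unidentifiable
    rmse: float
    unidentifiable: bool = False  # flat series or K_c beyond the probed range
    sensor_id: str = "sensor"

    @property
    def sensitivity(self) -> float:
        """Initial slope of the response, delta_R / K_c (per g/L)."""
        if self.unidentifiable or not np.isfinite(self.K_c):
            return math.nan
        return self.delta_R / self.K_c


def fit_titration(series: TitrationSeries) -> SensorResponseFit:
    """Least-squares hyperbolic fit of a titration series (all replicates).

    A flat series yields ``delta_R = 0`` with ``K_c`` flagged
    unidentifiable; a fit that pushes ``K_c`` far beyond the probed
    concentration range falls back to a linear model whose slope is
    reported as the fitted initial slope (``delta_R``/``K_c`` both NaN,
    unidentifiable flag set).
    """
    conc = series.concentrations
    if np.unique(conc).size < 4:
        raise InsufficientDataError("need >= 4 distinct concentrations")
    c_all = np.tile(conc, series.ratios.shape[0])
    y_all = series.ratios.ravel()
    means = series.mean_ratios()
    spread = float(means.max() - means.min())
    scale = max(abs(means).max(), 1.0)
    if spread <= 1e-12 * scale:
        return SensorResponseFit(R0=float(means.mean()), delta_R=0.0, K_c=math.nan,
                                 rmse=float(np.std(y_all)), unidentifiable=True,
                                 sensor_id=series.sensor_id)

    c_max = float(conc.max())

    def residuals(x):
        r0, dr, log_k = x
        return r0 + dr * c_all / (c_all + math.exp(log_k)) - y_all

    best = None
    for k0 in (c_max / 10, c_max / 3, c_max, 3 * c_max):
        x0 = np.array([float(means[0]), spread, math.log(k0)])
        try:
            sol = optimize.least_squares(
                residuals, x0,
                bounds=([-np.inf, 0.0, math.log(c_max / 1e4)],
                        [np.inf, np.inf, math.log(c_max * 1e3)]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # pragma: no cover
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailureError("titration fit failed for every start")
    r0, dr, log_k = best.x
    k = math.exp(log_k)
    rmse = math.sqrt(2.0 * best.cost / y_all.size)
    if k > 50.0 * c_max:
        # saturation never approached: only the initial slope is identified
        slope, intercept = np.polyfit(c_all, y_all, 1)
        resid = intercept + slope * c_all - y_all
        return SensorResponseFit(R0=float(intercept), delta_R=math.nan, K_c=math.nan,
                                 rmse=float(np.sqrt(np.mean(resid ** 2))),
                                 unidentifiable=True, sensor_id=series.sensor_id)
    return SensorResponseFit(R0=float(r0), delta_R=float(dr), K_c=float(k),
                             rmse=rmse, sensor_id=series.sensor_id)


@dataclass(frozen=True)
class SensitivityRanking:
    """Which of two sensors responds more strongly, on two criteria."""

    by_dynamic_range: str   # "A" | "B" | "tie"
    by_initial_slope: str
    agree: bool
    incomparable: bool = False


def _rank(a: float, b: float) -> str:
    if math.isclose(a, b, rel_tol=1e-12, abs_tol=1e-15):
        return "tie"
    return "A" if a > b else "B"


def compare_sensitivity(fit_a: SensorResponseFit, fit_b: SensorResponseFit) -> SensitivityRanking:
    """Rank two fitted sensors by dynamic range and by initial slope."""
    if fit_a.unidentifiable or fit_b.unidentifiable:
        return SensitivityRanking("tie", "tie", agree=True, incomparable=True)
    by_dr = _rank(fit_a.delta_R, fit_b.delta_R)
    by_slope = _rank(fit_a.sensitivity, fit_b.sensitivity)
    return SensitivityRanking(by_dr, by_slope, agree=by_dr == by_slope)


@dataclass(frozen=True)
class LinkerScreenResult:
    """Outcome of a linker-length screen.

    ``entries`` maps linker length (amino acids) to (response, sem),
    where response is the normalized condensed/relaxed ratio contrast.
    """

    entries: dict
    best_linker: int
    margin: float                 # best minus runner-up mean response
    sem_overlap: bool             # best - runner-up within their combined SEM


def select_best_linker(screen) -> LinkerScreenResult:
    """Pick the linker length with the maximal mean response.

    ``screen`` is a mapping ``{length: (response, sem)}`` or an iterable
    of ``(length, response, sem)`` rows.  Ties break toward the shorter
    linker (a shorter linker is cheaper to encode and fold).  When the
    margin over the runner-up is within the combined SEM, the result is
    flagged so callers know the selection is not resolved.
    """
    if hasattr(screen, "items"):
        rows = [(int(k), float(v[0]), float(v[1])) for k, v in screen.items()]
    else:
        rows = [(int(l), float(r), float(s)) for l, r, s in screen]
    if not rows:
        raise InsufficientDataError("linker screen is empty")
    rows.sort(key=lambda r: (-r[1], r[0]))  # best response first, shorter wins ties
    best_len, best_resp, best_sem = rows[0]
    if len(rows) == 1:
        margin, overlap = math.inf, False
    else:
        run_len, run_resp, run_sem = rows[1]
        margin = best_resp - run_resp
        overlap = margin <= math.hypot(best_sem, run_sem)
    return LinkerScreenResult(
        entries={l: (r, s) for l, r, s in rows},
        best_linker=best_len,
        margin=margin,
        sem_overlap=overlap,
    )


@dataclass(frozen=True)
class StoichiometryEstimate:
    """Copy number of monomers per assembly unit."""

    copy_number: float
    copy_number_rounded: float  # one significant figure


def estimate_stoichiometry(assembly_mass_kda: float, monomer_mass_kda: float) -> StoichiometryEstimate:
    """Copies per assembly = assembly mass / monomer mass.

    Reported raw and rounded to one significant figure, matching the
    precision at which light-scattering assembly masses are quoted.
    """
    if assembly_mass_kda <= 0 or monomer_mass_kda <= 0:
        raise ValueError("masses must be > 0")
    n = assembly_mass_kda / monomer_mass_kda
    exponent = math.floor(math.log10(n))
    rounded = round(n / 10 ** exponent) * 10 ** exponent
    return StoichiometryEstimate(copy_number=n, copy_number_rounded=float(rounded))
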