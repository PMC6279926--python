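"""Real-time amplification signal simulation and calling.

Two reporter channels are modelled phenomenologically:

* **Bioluminescent (BART).** Amplicon/pyrophosphate accumulation follows a
  logistic curve starting at the amplification onset. Instantaneous light is
  proportional to the pyrophosphate production rate attenuated by the
  remaining fraction of the sulphurylase substrate (APS), which depletes
  with cumulative pyrophosphate. Light therefore rises, peaks and
  collapses; the time of the peak (Tmax) is the assay readout and falls
  linearly in log10 of the starting copy number.

* **Fluorescent.** A normalised logistic sigmoid rising from baseline after
  onset; the readout is Ct, the first crossing of a fixed threshold (0.6 by
  default), interpolated linearly between samples. One nominal cycle equals
  one minute, so Ct is time in minutes.

Onset kinetics: onset = intercept − slope·log10(copies) + Gaussian noise,
truncated at zero; empty partitions never amplify. Melt analysis is a
phenomenological Gaussian −dF/dT peak, 85 °C for specific amplicon.

With logistic rate r, seed fraction p0 and APS pool a (as a fraction of the
total pyrophosphate ultimately produced), the noiseless light maximum sits
at onset + Δ where Δ = [ln((1−p0)/p0) + ln(P*/(1−P*))]/r and P* is the root
of P² − (1+2a)P + a = 0 in (0, ½) — used as the construction oracle in
tests and exposed as ``KineticParams.tmax_offset``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy import stats as sp_stats
from scipy.ndimage import uniform_filter1d

from .exceptions import InsufficientDataError, SingularFitError

ASSAY_DURATION_MIN = 100.0
DEFAULT_GRID_STEP_MIN = 0.5
CT_THRESHOLD = 0.6
MELT_TM_SPECIFIC = 85.0


def default_time_grid(
    duration_min: float = ASSAY_DURATION_MIN, step_min: float = DEFAULT_GRID_STEP_MIN
) -> np.ndarray:
    """Uniform assay time grid in minutes, endpoint included."""
    n = int(round(duration_min / step_min))
    return np.linspace(0.0, duration_min, n + 1)


class KineticParams(BaseModel):
    """Amplification kinetics and reporter parameters for one primer set.

    onset_intercept/onset_slope define the minutes-to-onset line against
    log10(copies); onset_noise_sd is partition-to-partition biochemical
    scatter. amp_rate is the logistic growth rate (1/min), initial_fraction
    the logistic seed, aps_pool the APS substrate pool as a fraction of
    total pyrophosphate production. light_gain/baseline/noise_sd are in RLU;
    fluor_* are normalised fluorescence units.
    """

    onset_intercept: float = Field(default=28.6, gt=0)
    onset_slope: float = Field(default=3.5, gt=0)
    onset_noise_sd: float = Field(default=3.0, ge=0)
    amp_rate: float = Field(default=1.5, gt=0)
    aps_pool: float = Field(default=0.5, gt=0)
    initial_fraction: float = Field(default=1e-4, gt=0, lt=0.5)
    light_gain: float = Field(default=1e4, gt=0)
    baseline: float = Field(default=50.0, ge=0)
    noise_sd: float = Field(default=5.0, ge=0)
    fluor_baseline: float = Field(default=0.05, ge=0, lt=1)
    fluor_noise_sd: float = Field(default=0.01, ge=0)

    @property
    def tmax_offset(self) -> float:
        """Minutes from onset to the noiseless light peak (closed form)."""
        a = self.aps_pool
        p_star = ((1 + 2 * a) - math.sqrt((1 + 2 * a) ** 2 - 4 * a)) / 2
        p0 = self.initial_fraction
        return (math.log((1 - p0) / p0) + math.log(p_star / (1 - p_star))) / self.amp_rate


@dataclass(frozen=True)
class LightTrace:
    """Bioluminescence (RLU) sampled on a uniform minute grid."""

    times: np.ndarray
    rlu: np.ndarray

    def __post_init__(self):
        _check_trace(self.times, self.rlu)


@dataclass(frozen=True)
class FluorTrace:
    """Normalised fluorescence; one nominal cycle = one minute."""

    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        _check_trace(self.times, self.fluorescence)


@dataclass(frozen=True)
class MeltCurve:
    temperatures: np.ndarray
    neg_derivative: np.ndarray

    def __post_init__(self):
        _check_trace(self.temperatures, self.neg_derivative)


def _check_trace(x: np.ndarray, y: np.ndarray) -> None:
    if len(x) != len(y):
        raise ValueError("axis and signal lengths differ")
    if len(x) >= 2 and not np.all(np.diff(x) > 0):
        raise ValueError("axis must be strictly increasing")


@dataclass(frozen=True)
class CallResult:
    positive: bool
    tmax_or_ct: Optional[float]
    peak_height: Optional[float]
    reason: str = ""

    def __post_init__(self):
        if self.positive and self.tmax_or_ct is None:
            raise ValueError("positive call requires a Tmax/Ct")


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of response time against log10(copies).

    ``pcr_efficiency`` = (10^(−1/slope) − 1) × 100, meaningful for
    Ct-vs-log10(copies) curves with negative slope (−3.3219 min per decade
    corresponds to perfect doubling, 100%).
    """

    slope: float
    intercept: float
    r_squared: float
    pcr_efficiency: Optional[float]
    x_min: float
    x_max: float


@dataclass(frozen=True)
class QuantResult:
    copies: float
    extrapolated: bool


def simulate_onset(
    copies: int, params: KineticParams, rng: np.random.Generator | int | None = None
) -> Optional[float]:
    """Minutes to amplification onset, or None for an empty partition.

    onset = intercept − slope·log10(copies) + N(0, onset_noise_sd),
    truncated at zero.
    """
    if copies < 0:
        raise ValueError("copies must be non-negative")
    if copies == 0:
        return None
    rng = np.random.default_rng(rng)
    onset = params.onset_intercept - params.onset_slope * math.log10(copies)
    if params.onset_noise_sd > 0:
        onset += rng.normal(0.0, params.onset_noise_sd)
    return max(onset, 0.0)


def _amplicon_fraction(times: np.ndarray, onset: float, params: KineticParams) -> np.ndarray:
    """Logistic amplicon/PPi fraction, seeded at p0 when t = onset."""
    p0 = params.initial_fraction
    z = np.exp(-params.amp_rate * (times - onset))
    return p0 / (p0 + (1 - p0) * z)


def bart_light_noiseless(
    times: np.ndarray, onset: float, params: KineticParams
) -> np.ndarray:
    """Deterministic BART light curve for a given onset.

    light = baseline + gain · (dPPi/dt) · exp(−PPi/aps_pool): logistic
    production attenuated by exponential APS depletion in cumulative PPi.
    """
    P = _amplicon_fraction(times, onset, params)
    production = params.amp_rate * P * (1.0 - P)
    aps_remaining = np.exp(-P / params.aps_pool)
    return params.baseline + params.light_gain * production * aps_remaining


def simulate_bart_trace(
    onset: Optional[float],
    params: KineticParams,
    rng: np.random.Generator | int | None = None,
    times: Optional[np.ndarray] = None,
) -> LightTrace:
    """BART light trace for one partition; flat baseline when onset is None."""
    if times is None:
        times = default_time_grid()
    rng = np.random.default_rng(rng)
    if onset is None:
        rlu = np.full_like(times, params.baseline, dtype=float)
    else:
        rlu = bart_light_noiseless(times, onset, params)
    if params.noise_sd > 0:
        rlu = rlu + rng.normal(0.0, params.noise_sd, size=times.shape)
    return LightTrace(times=times, rlu=rlu)


def fluor_noiseless(times: np.ndarray, onset: float, params: KineticParams) -> np.ndarray:
    """Deterministic normalised fluorescence sigmoid for a given onset."""
    P = _amplicon_fraction(times, onset, params)
    return params.fluor_baseline + (1.0 - params.fluor_baseline) * P


def simulate_fluor_trace(
    onset: Optional[float],
    params: KineticParams,
    rng: np.random.Generator | int | None = None,
    times: Optional[np.ndarray] = None,
) -> FluorTrace:
    """Fluorescent trace for one partition; NTCs stay at baseline."""
    if times is None:
        times = default_time_grid()
    rng = np.random.default_rng(rng)
    if onset is None:
        f = np.full_like(times, params.fluor_baseline, dtype=float)
    else:
        f = fluor_noiseless(times, onset, params)
    if params.fluor_noise_sd > 0:
        f = f + rng.normal(0.0, params.fluor_noise_sd, size=times.shape)
    return FluorTrace(times=times, fluorescence=f)


def _estimate_noise_sd(signal: np.ndarray, smoothed: np.ndarray) -> float:
    """Robust noise SD from smoothing residuals (MAD-scaled)."""
    resid = signal - smoothed
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def detect_tmax(
    trace: LightTrace,
    smoothing_window: int = 5,
    min_prominence: Optional[float] = None,
) -> CallResult:
    """Call a BART trace: Tmax is the time of the smoothed light maximum.

    The trace is smoothed with a centred moving average; a partition is
    positive iff the smoothed global maximum is an interior point standing
    at least ``min_prominence`` above the tail baseline (default 3× the
    noise SD estimated from smoothing residuals, with a small absolute
    floor). Traces still rising at assay end are negative ("no peak before
    assay end").
    """
    rlu = np.asarray(trace.rlu, dtype=float)
    if smoothing_window > 1:
        smoothed = uniform_filter1d(rlu, size=smoothing_window, mode="nearest")
    else:
        smoothed = rlu
    idx = int(np.argmax(smoothed))
    n = len(smoothed)
    if idx == n - 1:
        return CallResult(False, None, None, reason="no peak before assay end")
    if idx == 0:
        return CallResult(False, None, None, reason="no interior maximum")
    tail = smoothed[-max(5, n // 10):]
    prominence = smoothed[idx] - float(np.median(tail))
    if min_prominence is None:
        noise_sd = _estimate_noise_sd(rlu, smoothed)
        min_prominence = max(3.0 * noise_sd, 1e-9)
    if prominence < min_prominence:
        return CallResult(False, None, None, reason="peak below prominence threshold")
    return CallResult(True, float(trace.times[idx]), float(smoothed[idx]))


def detect_ct(trace: FluorTrace, threshold: float = CT_THRESHOLD) -> CallResult:
    """Call a fluorescent trace: Ct is the first threshold crossing.

    Linear interpolation between the bracketing samples. A trace that never
    reaches the threshold, or that starts above it, is negative.
    """
    f = np.asarray(trace.fluorescence, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    if f[0] >= threshold:
        return CallResult(False, None, None, reason="threshold below starting signal")
    above = np.nonzero(f >= threshold)[0]
    if len(above) == 0:
        return CallResult(False, None, None, reason="no threshold crossing")
    i = int(above[0])
    frac = (threshold - f[i - 1]) / (f[i] - f[i - 1])
    ct = t[i - 1] + frac * (t[i] - t[i - 1])
    return CallResult(True, float(ct), float(f.max()))


def default_melt_grid() -> np.ndarray:
    return np.arange(60.0, 92.0 + 0.25, 0.25)


def simulate_melt(
    amplicon_present: bool,
    tm: float = MELT_TM_SPECIFIC,
    peak_height: float = 1.0,
    peak_width: float = 1.5,
    noise_sd: float = 0.01,
    rng: np.random.Generator | int | None = None,
    temperatures: Optional[np.ndarray] = None,
) -> MeltCurve:
    """Phenomenological −dF/dT melt curve: Gaussian peak at the amplicon Tm."""
    if temperatures is None:
        temperatures = default_melt_grid()
    rng = np.random.default_rng(rng)
    if amplicon_present:
        y = peak_height * np.exp(-((temperatures - tm) ** 2) / (2 * peak_width**2))
    else:
        y = np.zeros_like(temperatures)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=temperatures.shape)
    return MeltCurve(temperatures=temperatures, neg_derivative=y)


def classify_melt(
    curve: MeltCurve,
    expected_tm: float = MELT_TM_SPECIFIC,
    window: float = 2.0,
    min_height: float = 0.2,
) -> bool:
    """Specific amplicon iff the melt peak sits within expected_tm ± window."""
    idx = int(np.argmax(curve.neg_derivative))
    height = float(curve.neg_derivative[idx])
    tm_obs = float(curve.temperatures[idx])
    return height >= min_height and abs(tm_obs - expected_tm) <= window


def fit_standard_curve(
    log10_copies: Sequence[float],
    response_min: Sequence[float],
) -> StandardCurve:
    """Least-squares line of response time against log10(copies).

    Requires at least three distinct copy levels. PCR efficiency is
    reported for negative-slope (Ct-style) curves only.
    """
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(response_min, dtype=float)
    if len(np.unique(x)) < 3:
        raise InsufficientDataError("need >= 3 distinct copy levels")
    if np.ptp(x) == 0:
        raise SingularFitError("zero variance in log10(copies)")
    fit = sp_stats.linregress(x, y)
    eff = pcr_efficiency_from_slope(fit.slope) if fit.slope < 0 else None
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        pcr_efficiency=eff,
        x_min=float(x.min()),
        x_max=float(x.max()),
    )


def pcr_efficiency_from_slope(slope: float) -> float:
    """Percent PCR efficiency from a Ct-curve slope: (10^(−1/slope) − 1)·100."""
    if slope == 0:
        raise ZeroDivisionError("slope must be non-zero")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def quantify_from_curve(curve: StandardCurve, response_min: float) -> QuantResult:
    """Invert a fitted curve: copies = 10^((response − intercept)/slope).

    Responses mapping outside the calibrated log10(copies) range are
    returned with the ``extrapolated`` flag set.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("cannot invert a zero-slope curve")
    x = (response_min - curve.intercept) / curve.slope
    return QuantResult(copies=10.0**x, extrapolated=not (curve.x_min <= x <= curve.x_max))
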