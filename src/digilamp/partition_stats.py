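"""Poisson partition-occupancy statistics for digital-style assays.

Under Poisson seeding with mean λ target molecules per partition and
per-molecule initiation probability η, the probability a partition amplifies
is p = 1 − e^(−ηλ). Observed positive fractions invert to occupancy
estimates λ̂ = −ln(1 − p̂), with confidence intervals obtained by applying
the same monotone transform to a binomial interval for p̂ (Wilson score by
default). At λ = 0.8 and ideal efficiency the expected positive fraction is
55% — the benchmark for single-copy limiting-dilution plates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .exceptions import (
    ContaminationWarning,
    EmptyPlateError,
    SaturationError,
)

CiMethod = Literal["wilson", "clopper-pearson"]
_STATSMODELS_METHOD = {"wilson": "wilson", "clopper-pearson": "beta"}


def format_percent(fraction: float) -> str:
    """Format a fraction as percent to one decimal, rounding half up.

    7/64 formats as ``'10.9'``, matching conventional plate reporting.
    """
    pct = Decimal(repr(fraction * 100.0)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return str(pct)


@dataclass(frozen=True)
class PlateCount:
    """Positive/total counts for test partitions and no-template controls."""

    n_positive: int
    n_total: int
    ntc_positive: int = 0
    ntc_total: int = 0

    def __post_init__(self):
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("need 0 <= n_positive <= n_total")
        if not 0 <= self.ntc_positive <= max(self.ntc_total, 0):
            raise ValueError("need 0 <= ntc_positive <= ntc_total")


@dataclass(frozen=True)
class FrequencyEstimate:
    frequency: float
    ci_low: float
    ci_high: float
    ci_method: str
    percent: str  # one-decimal display form

    def __post_init__(self):
        assert self.ci_low <= self.frequency <= self.ci_high + 1e-12


@dataclass(frozen=True)
class OccupancyEstimate:
    """Mean copies per partition inferred from a positive fraction."""

    lambda_hat: float
    ci_low: float
    ci_high: float
    frequency: float
    ci_method: str


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Effective-to-nominal occupancy ratio η."""

    eta: float
    nominal_lambda: float
    effective_lambda: float


def _binomial_interval(k: int, n: int, ci_method: CiMethod, alpha: float) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=alpha, method=_STATSMODELS_METHOD[ci_method])
    return float(lo), float(hi)


def observed_frequency(
    counts: PlateCount,
    ci_method: CiMethod = "wilson",
    alpha: float = 0.05,
) -> FrequencyEstimate:
    """Positive fraction of test partitions with a binomial interval."""
    if counts.n_total == 0:
        raise EmptyPlateError("plate has no test partitions")
    p = counts.n_positive / counts.n_total
    lo, hi = _binomial_interval(counts.n_positive, counts.n_total, ci_method, alpha)
    return FrequencyEstimate(
        frequency=p, ci_low=lo, ci_high=hi, ci_method=ci_method, percent=format_percent(p)
    )


def expected_positive_fraction(lam: float, eta: float = 1.0) -> float:
    """Poisson occupancy: P(partition positive) = 1 − exp(−ηλ)."""
    if lam < 0 or eta < 0:
        raise ValueError("lambda and eta must be non-negative")
    return -math.expm1(-eta * lam)


def frequency_curve(
    lambda_grid: Iterable[float], eta: float = 1.0
) -> list[tuple[float, float]]:
    """Predicted positive fraction over a grid of mean copy numbers."""
    out = []
    for lam in lambda_grid:
        out.append((float(lam), expected_positive_fraction(float(lam), eta)))
    return out


def estimate_lambda(
    counts: PlateCount,
    ci_method: CiMethod = "wilson",
    alpha: float = 0.05,
    ntc_tolerance: int = 0,
    subtract_ntc_rate: bool = False,
) -> OccupancyEstimate:
    """Invert a plate's positive fraction to mean copies per partition.

    λ̂ = −ln(1 − p̂); interval endpoints are the same transform applied to
    the binomial interval for p̂. Saturated plates (every partition
    positive) are rejected with a censored lower bound instead of an
    unbounded point estimate. NTC positives beyond ``ntc_tolerance`` emit a
    :class:`ContaminationWarning`; with ``subtract_ntc_rate`` the NTC
    positive rate is subtracted from p̂ before inversion.
    """
    if counts.n_total == 0:
        raise EmptyPlateError("plate has no test partitions")
    if counts.ntc_total and counts.ntc_positive > ntc_tolerance:
        warnings.warn(
            f"{counts.ntc_positive}/{counts.ntc_total} NTC partitions positive "
            f"(tolerance {ntc_tolerance}): possible contamination",
            ContaminationWarning,
            stacklevel=2,
        )
    p = counts.n_positive / counts.n_total
    if subtract_ntc_rate and counts.ntc_total:
        p = max(0.0, p - counts.ntc_positive / counts.ntc_total)
    if p >= 1.0:
        lo, _ = _binomial_interval(counts.n_positive, counts.n_total, ci_method, alpha)
        raise SaturationError(
            "all partitions positive: lambda unbounded above; "
            f"censored bound lambda >= {-math.log1p(-lo):.4g}",
            lambda_min=-math.log1p(-lo),
        )
    lo, hi = _binomial_interval(counts.n_positive, counts.n_total, ci_method, alpha)
    hi = min(hi, 1.0 - 1e-15)
    return OccupancyEstimate(
        lambda_hat=-math.log1p(-p),
        ci_low=-math.log1p(-lo),
        ci_high=-math.log1p(-hi),
        frequency=counts.n_positive / counts.n_total,
        ci_method=ci_method,
    )


def efficiency_from_nominal(
    observed: float,
    nominal_lambda: float,
    mode: Literal["inversion", "proportional"] = "inversion",
) -> EfficiencyEstimate:
    """Back-calculate amplification efficiency from an observed fraction.

    ``inversion`` (default): effective λ = −ln(1 − observed), η =
    effective/nominal. ``proportional``: η = observed fraction divided by
    the ideal fraction 1 − e^(−λ), i.e. frequencies scaled directly; the
    effective λ reported is η·λ. Observed fractions of 6–30% at nominal
    λ = 0.8 invert to effective occupancies of roughly 0.06–0.36.
    """
    if not 0.0 <= observed < 1.0:
        raise SaturationError("observed fraction must lie in [0, 1)")
    if nominal_lambda <= 0:
        raise ValueError("nominal lambda must be positive")
    if mode == "inversion":
        eff = -math.log1p(-observed)
        eta = eff / nominal_lambda
    elif mode == "proportional":
        eta = observed / expected_positive_fraction(nominal_lambda)
        eff = eta * nominal_lambda
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return EfficiencyEstimate(eta=eta, nominal_lambda=nominal_lambda, effective_lambda=eff)


@dataclass(frozen=True)
class ReplicateSummary:
    mean_percent: float
    sd_percent: float
    n_sets: int
    single_set: bool


def replicate_summary(frequencies: Sequence[float]) -> ReplicateSummary:
    """Mean and sample SD (percent) across replicate plate frequencies.

    Input fractions in [0, 1]; a single replicate set reports SD 0 with the
    ``single_set`` flag raised.
    """
    if len(frequencies) == 0:
        raise EmptyPlateError("no replicate sets supplied")
    arr = np.asarray(frequencies, dtype=float) * 100.0
    if len(arr) == 1:
        return ReplicateSummary(float(arr[0]), 0.0, 1, True)
    return ReplicateSummary(float(arr.mean()), float(arr.std(ddof=1)), len(arr), False)


@dataclass(frozen=True)
class QuantComparison:
    mean: float
    deviations: Mapping[str, float]
    nearest_method: str
    tie: bool


def compare_quantifications(method_values: Mapping[str, float]) -> QuantComparison:
    """Compare concentration estimates across quantification methods.

    Reports the cross-method mean, each method's absolute deviation from it,
    and the method nearest the mean (ties broken by method-name order and
    flagged). Mirrors the practice of adopting, among fluorimetry,
    tape-based electrophoresis, qPCR and digital PCR, the value closest to
    their average.
    """
    if len(method_values) < 2:
        raise ValueError("need at least two methods to compare")
    mean = sum(method_values.values()) / len(method_values)
    devs = {name: abs(v - mean) for name, v in method_values.items()}
    best = min(sorted(devs), key=lambda name: devs[name])
    tie = sum(1 for d in devs.values() if math.isclose(d, devs[best], abs_tol=1e-12)) > 1
    return QuantComparison(mean=mean, deviations=devs, nearest_method=best, tie=tie)
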