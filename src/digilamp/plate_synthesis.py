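"""Synthetic plate generator with known ground truth.

Builds whole plates of reaction partitions emulating limiting-dilution
layouts: 64 tests + 8 NTCs, 96- or 48-replicate single-copy runs, and
dilution ladders from 1 to 10⁴ copies. Per-partition template copies are
Poisson(λ); an efficiency parameter η thins copies molecule-by-molecule
(Bernoulli), modelling per-molecule initiation failure, so the called
positive fraction tends to 1 − e^(−ηλ). NTC partitions never receive
template. Traces come from :mod:`digilamp.signal_models`; everything is
deterministic under the design seed.

Primer-profile presets encode only qualitative kinetic differences between
the published primer sets (the NOSt assay is faster with lower scatter; the
original K set is slower and more variable than Z; K+ is the optimised 35S
set whose single-copy mean Tmax sits near 33.6 min). They are declared
parameter choices, not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .signal_models import (
    ASSAY_DURATION_MIN,
    DEFAULT_GRID_STEP_MIN,
    KineticParams,
    bart_light_noiseless,
    default_time_grid,
    fluor_noiseless,
    simulate_onset,
)

PRIMER_PROFILES: dict[str, KineticParams] = {
    # optimised 35S set: single-copy mean Tmax ~33.6 min
    "K_plus": KineticParams(onset_intercept=28.6, onset_slope=3.5, onset_noise_sd=3.0),
    # original 35S set: slower, more variable
    "K": KineticParams(onset_intercept=31.5, onset_slope=3.6, onset_noise_sd=4.0),
    "Z": KineticParams(onset_intercept=30.0, onset_slope=3.5, onset_noise_sd=3.5),
    # NOS terminator set: faster average Tmax, lower replicate variation
    "NOSt": KineticParams(onset_intercept=25.5, onset_slope=3.3, onset_noise_sd=1.5),
    # plasmid qPCR calibration scenario: slope set to the assay's reported
    # ~101% PCR efficiency (-1/log10(2.013) min per decade), tight replicates
    "qPCR_35Sp": KineticParams(
        onset_intercept=36.0, onset_slope=3.2913, onset_noise_sd=0.15
    ),
}


class PlateDesign(BaseModel):
    """Layout and conditions of one synthetic plate.

    ``lam`` is the mean independently distributing target molecules per
    test partition (already including any denaturation doubling computed by
    the copy-accounting layer; ``denatured`` is carried as metadata).
    ``efficiency`` is the per-molecule initiation probability η.
    ``fixed_copies`` replaces Poisson sampling with a constant copy number,
    for deterministic fixtures and noiseless ladders.
    """

    n_test: int = Field(default=64, ge=1)
    n_ntc: int = Field(default=8, ge=0)
    lam: float = Field(default=0.8, ge=0.0)
    detection: Literal["bart", "fluor"] = "bart"
    primer_profile: str = "K_plus"
    denatured: bool = False
    efficiency: float = Field(default=1.0, ge=0.0, le=1.0)
    seed: int = 0
    fixed_copies: Optional[int] = Field(default=None, ge=0)
    grid_step_min: float = Field(default=DEFAULT_GRID_STEP_MIN, gt=0)
    duration_min: float = Field(default=ASSAY_DURATION_MIN, gt=0)
    ntc_nonspecific_rate: float = Field(default=0.0, ge=0.0, le=1.0)

    def params(self) -> KineticParams:
        if self.primer_profile not in PRIMER_PROFILES:
            raise KeyError(
                f"unknown primer profile {self.primer_profile!r}; "
                f"known: {sorted(PRIMER_PROFILES)}"
            )
        return PRIMER_PROFILES[self.primer_profile]


@dataclass
class SyntheticPlate:
    """Ground truth plus the signal matrix for one simulated plate."""

    design: PlateDesign
    truth: pd.DataFrame  # partition_id, well_role, copies, effective_copies, onset_min
    times: np.ndarray
    signals: np.ndarray  # (n_partitions, n_times)
    channel: str

    def to_trace_table(self) -> pd.DataFrame:
        """Long-format trace table: partition_id, time_min, signal, channel."""
        n, t = self.signals.shape
        return pd.DataFrame(
            {
                "partition_id": np.repeat(self.truth["partition_id"].to_numpy(), t),
                "time_min": np.tile(self.times, n),
                "signal": self.signals.ravel(),
                "channel": self.channel,
            }
        )

    @property
    def n_partitions(self) -> int:
        return len(self.truth)


def generate_plate(design: PlateDesign) -> SyntheticPlate:
    """Simulate one plate: Poisson copies, kinetics, traces, NTCs.

    Test partitions draw copies ~ Poisson(λ) (or ``fixed_copies``), thinned
    by η; NTCs carry zero copies and flat traces, except for an optional
    late non-specific amplification rate (default 0). Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    params = design.params()
    times = default_time_grid(design.duration_min, design.grid_step_min)

    n_total = design.n_test + design.n_ntc
    roles = ["test"] * design.n_test + ["ntc"] * design.n_ntc
    if design.fixed_copies is not None:
        copies = np.full(design.n_test, design.fixed_copies, dtype=np.int64)
    else:
        copies = rng.poisson(design.lam, size=design.n_test)
    copies = np.concatenate([copies, np.zeros(design.n_ntc, dtype=np.int64)])

    if design.efficiency < 1.0:
        effective = rng.binomial(copies, design.efficiency)
    else:
        effective = copies.copy()

    # late non-specific NTC events, if enabled
    if design.n_ntc and design.ntc_nonspecific_rate > 0:
        nonspecific = rng.random(design.n_ntc) < design.ntc_nonspecific_rate
    else:
        nonspecific = np.zeros(design.n_ntc, dtype=bool)

    onsets = np.full(n_total, np.nan)
    signals = np.empty((n_total, len(times)))
    for i in range(n_total):
        if roles[i] == "ntc" and nonspecific[i - design.n_test]:
            onset = float(rng.uniform(0.7, 1.0) * design.duration_min)
        else:
            onset = simulate_onset(int(effective[i]), params, rng)
        if onset is not None:
            onsets[i] = onset
        if design.detection == "bart":
            base = (
                bart_light_noiseless(times, onset, params)
                if onset is not None
                else np.full_like(times, params.baseline)
            )
            noise_sd = params.noise_sd
        else:
            base = (
                fluor_noiseless(times, onset, params)
                if onset is not None
                else np.full_like(times, params.fluor_baseline)
            )
            noise_sd = params.fluor_noise_sd
        if noise_sd > 0:
            base = base + rng.normal(0.0, noise_sd, size=times.shape)
        signals[i] = base

    truth = pd.DataFrame(
        {
            "partition_id": [f"P{i + 1:04d}" for i in range(n_total)],
            "well_role": roles,
            "copies": copies,
            "effective_copies": effective,
            "onset_min": onsets,
            "truth_positive": effective > 0,
        }
    )
    return SyntheticPlate(
        design=design,
        truth=truth,
        times=times,
        signals=signals,
        channel=design.detection,
    )


def generate_dilution_series(
    copy_levels: list[float],
    replicates_per_level: int,
    profile: str = "K_plus",
    seed: int = 0,
    detection: Literal["bart", "fluor"] = "bart",
    fixed_copies: bool = False,
    efficiency: float = 1.0,
    n_ntc: int = 0,
) -> list[SyntheticPlate]:
    """One plate per copy level, λ = level (or exact copies when fixed).

    Suitable for fitting Tmax/Ct standard curves and validating the
    predicted amplification-frequency curve over 1–10⁴ copies.
    """
    if any(level < 1 for level in copy_levels):
        raise ValueError("copy levels must be >= 1 nominal copy")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(copy_levels))
    plates = []
    for level, s in zip(copy_levels, child_seeds):
        design = PlateDesign(
            n_test=replicates_per_level,
            n_ntc=n_ntc,
            lam=float(level),
            detection=detection,
            primer_profile=profile,
            efficiency=efficiency,
            seed=int(s % (2**31)),
            fixed_copies=int(round(level)) if fixed_copies else None,
        )
        plates.append(generate_plate(design))
    return plates


def generate_replicate_sets(design: PlateDesign, n_sets: int) -> list[SyntheticPlate]:
    """Independent replicate plates with seeds derived from the master seed."""
    if n_sets < 1:
        raise ValueError("need at least one replicate set")
    child_seeds = np.random.SeedSequence(design.seed).generate_state(n_sets)
    return [
        generate_plate(design.model_copy(update={"seed": int(s % (2**31))}))
        for s in child_seeds
    ]
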