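"""End-to-end orchestration: simulate/ingest → call → quantify → report.

All numerics delegate to the other modules; this layer moves tables,
validates formats and writes the report bundle (plate table, call table,
occupancy JSON, Tmax histogram, provenance). Tables are UTF-8 CSV with a
header row; reports are JSON. Runs are deterministic under the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .exceptions import SaturationError, TableFormatError
from .partition_stats import (
    PlateCount,
    estimate_lambda,
    observed_frequency,
)
from .plate_synthesis import PlateDesign, SyntheticPlate, generate_plate
from .signal_models import (
    CT_THRESHOLD,
    CallResult,
    FluorTrace,
    LightTrace,
    detect_ct,
    detect_tmax,
)

logger = logging.getLogger("digilamp")

PLATE_COLUMNS = ["partition_id", "well_role", "call", "tmax_or_ct_min"]
TRACE_COLUMNS = ["partition_id", "time_min", "signal", "channel"]


def call_signal(
    times: np.ndarray,
    signal: np.ndarray,
    channel: str,
    ct_threshold: float = CT_THRESHOLD,
    smoothing_window: int = 5,
    min_prominence: Optional[float] = None,
) -> CallResult:
    """Dispatch one partition's trace to the channel-appropriate caller."""
    if channel == "bart":
        return detect_tmax(
            LightTrace(times=times, rlu=signal),
            smoothing_window=smoothing_window,
            min_prominence=min_prominence,
        )
    if channel == "fluor":
        return detect_ct(FluorTrace(times=times, fluorescence=signal), threshold=ct_threshold)
    raise TableFormatError(f"unknown channel {channel!r}")


def call_plate(plate: SyntheticPlate, **caller_kwargs) -> pd.DataFrame:
    """Call every partition of a synthetic plate.

    Returns the plate result table: partition_id, well_role, call
    (positive|negative), tmax_or_ct_min, reason.
    """
    rows = []
    for i, rec in enumerate(plate.truth.itertuples(index=False)):
        res = call_signal(plate.times, plate.signals[i], plate.channel, **caller_kwargs)
        rows.append(
            {
                "partition_id": rec.partition_id,
                "well_role": rec.well_role,
                "call": "positive" if res.positive else "negative",
                "tmax_or_ct_min": res.tmax_or_ct,
                "reason": res.reason,
            }
        )
    return pd.DataFrame(rows)


def call_trace_table(traces: pd.DataFrame, roles: Optional[pd.DataFrame] = None, **kw) -> pd.DataFrame:
    """Call partitions from a long-format trace table.

    ``roles``, when given, maps partition_id → well_role; otherwise every
    partition is treated as a test well.
    """
    missing = [c for c in TRACE_COLUMNS if c not in traces.columns]
    if missing:
        raise TableFormatError(f"trace table missing column(s): {missing}")
    role_map = {}
    if roles is not None:
        role_map = dict(zip(roles["partition_id"], roles["well_role"]))
    rows = []
    for pid, grp in traces.groupby("partition_id", sort=False):
        grp = grp.sort_values("time_min")
        channels = grp["channel"].unique()
        if len(channels) != 1:
            raise TableFormatError(f"partition {pid!r} mixes channels {channels}")
        res = call_signal(
            grp["time_min"].to_numpy(float), grp["signal"].to_numpy(float), channels[0], **kw
        )
        rows.append(
            {
                "partition_id": pid,
                "well_role": role_map.get(pid, "test"),
                "call": "positive" if res.positive else "negative",
                "tmax_or_ct_min": res.tmax_or_ct,
                "reason": res.reason,
            }
        )
    return pd.DataFrame(rows)


def plate_counts(calls: pd.DataFrame) -> PlateCount:
    """Collapse a call table to test/NTC positive counts."""
    test = calls[calls["well_role"] == "test"]
    ntc = calls[calls["well_role"] == "ntc"]
    return PlateCount(
        n_positive=int((test["call"] == "positive").sum()),
        n_total=len(test),
        ntc_positive=int((ntc["call"] == "positive").sum()),
        ntc_total=len(ntc),
    )


def write_plate_table(calls: pd.DataFrame, path: Union[str, Path]) -> None:
    calls.to_csv(path, index=False)


def read_plate_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a plate result table."""
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"plate table missing column(s): {missing}")
    dup = df["partition_id"][df["partition_id"].duplicated()]
    if len(dup):
        raise TableFormatError(f"duplicate partition ids: {sorted(set(dup))}")
    bad_roles = set(df["well_role"]) - {"test", "ntc"}
    if bad_roles:
        raise TableFormatError(f"unknown well roles: {sorted(bad_roles)}")
    return df


def write_trace_table(traces: pd.DataFrame, path: Union[str, Path]) -> None:
    traces.to_csv(path, index=False)


def read_trace_table(path: Union[str, Path]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise TableFormatError(f"malformed trace table {path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"trace table missing column(s): {missing}")
    return df


def response_histogram(calls: pd.DataFrame, bin_width_min: float = 2.0) -> pd.DataFrame:
    """Histogram of positive-partition Tmax/Ct times (default 2-min bins)."""
    pos = calls[(calls["call"] == "positive") & calls["tmax_or_ct_min"].notna()]
    if len(pos) == 0:
        return pd.DataFrame({"bin_left_min": [], "bin_right_min": [], "count": []})
    t = pos["tmax_or_ct_min"].to_numpy(float)
    lo = np.floor(t.min() / bin_width_min) * bin_width_min
    hi = np.ceil(t.max() / bin_width_min) * bin_width_min
    edges = np.arange(lo, hi + bin_width_min, bin_width_min)
    counts, edges = np.histogram(t, bins=edges)
    return pd.DataFrame(
        {"bin_left_min": edges[:-1], "bin_right_min": edges[1:], "count": counts}
    )


class RunConfig(BaseModel):
    """Configuration for one simulate→call→quantify run."""

    design: PlateDesign = Field(default_factory=PlateDesign)
    output_dir: str = "results/run"
    histogram_bin_min: float = Field(default=2.0, gt=0)
    ct_threshold: float = CT_THRESHOLD
    verbosity: int = 1

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a plate, call it, quantify occupancy, write the bundle.

    Writes plate_table.csv, trace_table.csv, histogram.csv, occupancy.json
    and provenance.json under ``config.output_dir`` and returns the report
    dict. Byte-identical report bodies on rerun with the same config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("stage=simulate seed=%d hash=%s", config.design.seed, config.config_hash())
    plate = generate_plate(config.design)
    logger.info("stage=call n_partitions=%d channel=%s", plate.n_partitions, plate.channel)
    calls = call_plate(plate, ct_threshold=config.ct_threshold)
    counts = plate_counts(calls)
    freq = observed_frequency(counts)
    report: dict = {
        "n_positive": counts.n_positive,
        "n_total": counts.n_total,
        "ntc_positive": counts.ntc_positive,
        "ntc_total": counts.ntc_total,
        "frequency": freq.frequency,
        "frequency_percent": freq.percent,
        "frequency_ci95": [freq.ci_low, freq.ci_high],
    }
    try:
        occ = estimate_lambda(counts)
        report["lambda_hat"] = occ.lambda_hat
        report["lambda_ci95"] = [occ.ci_low, occ.ci_high]
    except SaturationError as exc:
        report["lambda_hat"] = None
        report["lambda_censored_min"] = exc.lambda_min
    logger.info("stage=quantify frequency=%s", freq.percent)

    write_plate_table(calls, out / "plate_table.csv")
    write_trace_table(plate.to_trace_table(), out / "trace_table.csv")
    response_histogram(calls, config.histogram_bin_min).to_csv(
        out / "histogram.csv", index=False
    )
    (out / "occupancy.json").write_text(json.dumps(report, indent=2) + "\n")
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.design.seed,
        "package_version": __version__,
        "config": config.model_dump(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    logger.info("stage=report dir=%s", out)
    return report
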