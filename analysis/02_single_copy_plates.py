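#!/usr/bin/env python
"""Single-copy limiting-dilution plates: simulate, call, quantify.

Three replicate BART plates of 64 tests + 8 NTCs at 0.8 copies/partition
for each primer profile, at ideal per-molecule efficiency (eta = 1, where
the expected positive fraction is 55%) and at a reduced eta = 0.25
illustrating the sub-ideal frequencies real primer sets produce. Reports
replicate mean/SD frequencies and the inverted occupancy estimate.

Writes results/single_copy_frequencies.csv.
"""

import warnings
from pathlib import Path

import pandas as pd

from digilamp.exceptions import ContaminationWarning
from digilamp.partition_stats import (
    estimate_lambda,
    expected_positive_fraction,
    replicate_summary,
)
from digilamp.pipeline import call_plate, plate_counts
from digilamp.plate_synthesis import PlateDesign, generate_replicate_sets

OUT = Path("results")
OUT.mkdir(exist_ok=True)

rows = []
for i, profile in enumerate(("K_plus", "Z", "NOSt")):
    for eta in (1.0, 0.25):
        design = PlateDesign(
            n_test=64, n_ntc=8, lam=0.8, primer_profile=profile,
            efficiency=eta, denatured=True, seed=42 + i,
        )
        freqs, lam_hats, tmaxes = [], [], []
        for plate in generate_replicate_sets(design, 3):
            calls = call_plate(plate)
            counts = plate_counts(calls)
            freqs.append(counts.n_positive / counts.n_total)
            pos = calls[(calls.call == "positive") & (calls.well_role == "test")]
            tmaxes.extend(pos.tmax_or_ct_min.tolist())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ContaminationWarning)
                lam_hats.append(estimate_lambda(counts).lambda_hat)
        summary = replicate_summary(freqs)
        rows.append(
            {
                "profile": profile,
                "eta": eta,
                "expected_pct": 100 * expected_positive_fraction(0.8, eta),
                "mean_pct": summary.mean_percent,
                "sd_pct": summary.sd_percent,
                "mean_lambda_hat": sum(lam_hats) / len(lam_hats),
                "mean_tmax_min": sum(tmaxes) / len(tmaxes),
            }
        )

table = pd.DataFrame(rows)
table.to_csv(OUT / "single_copy_frequencies.csv", index=False)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(
    "\nAt eta=1 the three replicate sets scatter around the 55% Poisson "
    "expectation; thinning to eta=0.25 drops the frequency to ~18%, the "
    "regime real single-copy assays occupy."
)
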