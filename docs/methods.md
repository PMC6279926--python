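# Methods

## Copy-number accounting

A nanogram of DNA from an organism with haploid genome size G base pairs
contains

    copies/ng = 1 ng × 10⁻⁹ × N_A / (G × M_bp)

haploid genome equivalents, with N_A Avogadro's number and M_bp the mean
molar mass per base pair (default 650 g/mol). Equivalently, copies/ng =
1000 / m_pg with m_pg the haploid mass in picograms. For maize the two
routes are consistent to ~0.4% (2.4 Gbp × 650 g/mol / N_A ≈ 2.59 pg
against the conventional 2.6 pg); the pg route with 2.6 pg gives the
conventional 384.6 ≈ 385 copies/ng and is the default. Copy quantities are
carried as reals throughout; `round_copies` rounds to the nearest integer
only for presentation.

**Transgene dosage.** Hybrid GM seed is hemizygous, with the transgene from
the male parent. Seed DNA is a mixture of diploid embryo (1 paternal genome
of 2) and triploid endosperm (1 paternal of 3), so the transgene-bearing
fraction of genome copies is

    d = Σ_tissues f_tissue × (bearing genomes / ploidy)

With the default 0.5/0.5 DNA-mass split this gives d = 5/12 ≈ 0.4167 and
160.3 copies/ng. The published simulation of this quantity reports
160.4 copies/ng and an adjustment factor of 160/385 ≈ 0.4156; the small
discrepancies reflect an unstated tissue weighting in that source. The
package therefore has two modes: `mechanistic` (the formula above; default
mass split 0.5/0.5, a documented assumption) and `literal`, which uses the
published per-ng constants (385.0 homozygous, 160.4 hemizygous) so that
printed arithmetic — e.g. Bt11's two 35S copies giving 2 × 160.4 =
320.8 copies/ng — is reproduced exactly. `transgene_dosage(mode="literal")`
returns exactly 160/385.

**Occupancy.** Expected independently distributing target molecules per
partition:

    λ = c × w × (copies/ng per unit target) × m_eff × V / D × (2 if denatured)

with c the DNA concentration (ng/µL), w the GM mass fraction, V the
template volume (µL), D the dilution factor. Denaturation doubles λ only —
each strand of a denatured duplex can seed amplification — never mass.
Duplicated targets on one locus co-segregate unless the DNA is fragmented
between them, so multiplicity m contributes m_eff = 1 + (m−1)·ℓ independent
units, with ℓ ∈ [0,1] the linkage-independence fraction (default 1, the
fully-independent working assumption; ℓ = 0 models an unfragmented locus).
Mass back-conversion (`copies_to_ng`) uses the true multiplicity and no
denaturation factor, since those affect partition occupancy, not mass.

## Partition statistics

With Poisson(λ) copies per partition and independent per-molecule
initiation probability η, the initiated count is Poisson(ηλ) (Bernoulli
thinning), so P(positive) = 1 − e^(−ηλ); at λ = 0.8 and η = 1 this is the
55% single-copy benchmark. Inversion: λ̂ = −ln(1 − p̂). Confidence
intervals come from a binomial interval for p̂ — Wilson score by default
(93–97% coverage at the plate sizes used here), Clopper–Pearson as a
conservative alternative — mapped through −ln(1−·), which is monotone, so
coverage is inherited. Saturated plates (p̂ = 1) raise an error carrying a
censored bound λ ≥ −ln(1 − p̂_lower) instead of returning infinity. NTC
positives beyond a tolerance (default 0) raise a contamination warning and
do not enter the estimate unless NTC-rate subtraction is enabled.

Efficiency back-calculation offers two modes: `inversion`
(λ_eff = −ln(1 − p_obs), η = λ_eff/λ_nom) and `proportional`
(η = p_obs / (1 − e^(−λ_nom))). Observed single-copy frequencies of 6–30%
at nominal λ = 0.8 invert to effective occupancies of 0.06–0.36; published
projections for the same data quote up to 0.5, which plain inversion cannot
produce — neither mode claims to reproduce that figure.

Percent displays are one decimal, round-half-up (7/64 → "10.9").

## Signal models

**BART.** Amplicon/pyrophosphate follows a logistic fraction
P(t) = p₀ / (p₀ + (1−p₀)e^(−r(t−t₀))) seeded at p₀ (default 10⁻⁴) at onset
t₀. Instantaneous light is

    L(t) = baseline + gain × r·P(1−P) × e^(−P/a)

— production rate attenuated by APS depletion, with a the APS pool as a
fraction of total pyrophosphate production (default 0.5). L rises and
collapses with a single interior maximum at P* = ((1+2a) − √((1+2a)²−4a))/2,
giving a closed-form peak time t₀ + Δ,
Δ = [ln((1−p₀)/p₀) + ln(P*/(1−P*))]/r — the construction oracle used by the
tests. This model is phenomenological: no rate equations for LAMP
strand-displacement chemistry or luciferase kinetics are published for
these assays, and none are attempted.

**Onset kinetics.** t₀ = intercept − slope·log₁₀(copies) + N(0, σ), truncated
at 0; empty partitions never amplify. Gaussian onset noise is an
assumption; the biochemical distribution is unknown.

**Calling.** Tmax = time of the smoothed global maximum (5-point centred
moving average), positive iff interior and ≥ min_prominence above the tail
median (default 3× the noise SD estimated from MAD of smoothing residuals,
with a 10⁻⁹ absolute floor so noiseless flat traces stay negative). Traces
still rising at assay end are negative. On the default 0.5-min grid the
noiseless caller recovers constructed peaks within one grid step.
Ct = first crossing of normalised fluorescence 0.6, linearly interpolated;
exactly translation-equivariant in onset at zero noise. Melt curves are
Gaussian −dF/dT peaks; specific iff the peak lies within ±2 °C of 85 °C
(window a declared default; only the mode is published) and above a height
threshold.

**Standard curves.** Ordinary least squares of response time on
log₁₀(copies), ≥ 3 distinct levels; PCR efficiency (10^(−1/slope) − 1)×100
for negative-slope (Ct) curves — slope −3.3219 min/decade is exact
doubling, 100%. Quantification inverts the fitted line and flags
extrapolation outside the calibrated range.

**Calibration of defaults.** The K+ profile (intercept 28.6 min, slope
3.5 min/decade, onset SD 3.0; r = 1.5/min, a = 0.5, p₀ = 10⁻⁴ ⇒
Δ = 5.55 min) was set analytically so that a Poisson single-copy plate
(λ = 1) has mean positive-partition Tmax ≈ 28.6 − 3.5·E[log₁₀C | C≥1] +
5.55 ≈ 33.6 min, the published working value for optimised 35S primers.
Other presets encode only reported qualitative orderings: NOSt faster
(25.5 min) with lower scatter (SD 1.5), K slower (31.5 min) and more
variable than Z (30.0 min). The `qPCR_35Sp` preset models the plasmid
calibration assay: slope 3.2913 min/decade (the slope corresponding to the
assay's reported ~101% PCR efficiency), onset SD 0.15 matching tight
triplicate calibrations. These are scenario presets, not fitted values.

## Synthetic plates

`generate_plate` draws copies ~ Poisson(λ) per test partition (or a fixed
count for deterministic fixtures), thins them per-molecule with η, draws
onsets and traces, and leaves NTCs template-free (an optional late
non-specific rate exists, default 0). Seeds propagate through
`numpy.random.SeedSequence`, so plates, replicate sets and dilution series
are reproducible and mutually independent. The generator emulates: Poisson
seeding, log-linear onset kinetics with Gaussian noise, BART peak shapes,
fluorescent sigmoids, 85 °C melt peaks, NTC wells, and the standard
layouts. It does **not** emulate primer-dimer artifacts, cross-
contamination, template fragmentation (linkage is handled upstream as a
deterministic λ scaling), instrument drift, or the true biochemical
distribution of onset times — so passing tests show the statistical
pipeline is correct under the declared model, not that any particular
primer set achieves a given wet-lab frequency. η deliberately conflates
per-molecule initiation failure with copy-number overestimation; the two
are not distinguishable from positive fractions alone.

## Numerical choices and problem sizes

Time grid 0.5 min over 100 min (configurable); melt grid 0.25 °C over
60–92 °C. Occupancy uses `expm1`/`log1p` for small-λ accuracy. Ties in
`compare_quantifications` break by method-name order with a flag.
Validation tests use 10⁴-partition plates for frequency/bias checks
(binomial SE ≈ 0.5%), 500 plates of 64 for interval coverage, 100 random
parameter draws for the noiseless caller, and 200 simulated ladders
(4 levels × 8 replicates) for slope recovery — sizes chosen to put Monte
Carlo error well below the tolerances being asserted.

## Limitations

* The BART light model is a two-parameter phenomenology; peak heights and
  widths are not calibrated to any instrument, only peak *times* are
  meaningful.
* Mechanistic dosage assumes a 0.5/0.5 embryo/endosperm DNA-mass split;
  real seed varies, which is why the literal mode exists.
* Single-λ plates only: no joint most-probable-number fit across a
  dilution ladder, and no Bayesian posterior for λ.
* CRM certified-value uncertainty is not propagated.
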