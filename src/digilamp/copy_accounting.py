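"""Copy-number accounting for single-copy transgene detection assays.

Converts DNA mass into expected target molecules per reaction partition and
back. The chain is:

    ng of total DNA
      -> genome copies          (Avogadro / molar-mass route, or pg route)
      -> transgene copies       (zygosity/seed-tissue dosage)
      -> target copies          (per-locus target multiplicity)
      -> copies per partition   (GM mass fraction, template volume, dilution,
                                 denaturation doubling)

Hybrid GM maize seed carries a hemizygous transgene locus from the male
parent; seed tissue is a mixture of diploid embryo (one paternal genome of
two) and triploid endosperm (one paternal genome of three), so one nanogram
of transgenic seed DNA carries fewer transgene copies than the homozygous
385 copies/ng. The mechanistic dosage mode computes that weighting; the
literal mode uses the published per-nanogram constants (385 homozygous,
160.4 hemizygous) so that hand calculations with the printed factors are
reproduced digit for digit.

Denaturation doubles the number of *independently distributing* amplifiable
molecules (each strand of a denatured duplex can seed amplification), so the
``denatured`` flag doubles the expected copies per partition only — never
mass or concentration.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .exceptions import InfeasibleDilutionError, InvalidSpecError

AVOGADRO = 6.02214076e23
DEFAULT_MOLAR_MASS_PER_BP = 650.0  # g/mol per base pair of double-stranded DNA

#: Published copies of a single-copy locus per nanogram of maize DNA.
HOMOZYGOUS_COPIES_PER_NG = 385.0
HEMIZYGOUS_COPIES_PER_NG = 160.4
#: The adjustment factor applied to homozygous copy numbers for hybrid seed.
LITERAL_HEMIZYGOUS_FACTOR = 160.0 / 385.0

DosageMode = Literal["mechanistic", "literal"]


class GenomeSpec(BaseModel):
    """Haploid genome size/mass of the host organism.

    ``haploid_mass_pg`` may be given directly (e.g. the conventional 2.6 pg
    for maize) or derived from ``haploid_size_bp`` via the molar mass per
    base pair. For a consistent spec the two routes agree within ~1%.
    """

    name: str
    haploid_size_bp: int = Field(gt=0)
    haploid_mass_pg: Optional[float] = Field(default=None, gt=0)
    molar_mass_per_bp: float = Field(default=DEFAULT_MOLAR_MASS_PER_BP, gt=0)

    def derived_mass_pg(self) -> float:
        """Haploid mass in pg implied by size and molar mass per bp."""
        return self.haploid_size_bp * self.molar_mass_per_bp / AVOGADRO * 1e12

    @property
    def mass_pg(self) -> float:
        """Haploid mass in pg: the stated value, else the derived one."""
        if self.haploid_mass_pg is not None:
            return self.haploid_mass_pg
        return self.derived_mass_pg()


class TransgeneEventSpec(BaseModel):
    """A GM event: zygosity, parental origin, and per-locus target counts.

    ``target_multiplicity`` maps target name (e.g. ``"35Sp"``) to copies per
    transgene locus; zero is legal (a target lost from the event).
    ``linkage_independence`` is the probability that duplicated targets on
    one locus distribute independently across partitions (1 = fully
    independent, 0 = fully linked on one fragment).
    """

    event_name: str
    zygosity: Literal["homozygous", "hemizygous"]
    transgenic_parent: Literal["male", "female", "not_applicable"]
    target_multiplicity: dict[str, int]
    linkage_independence: float = Field(default=1.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_multiplicities(self) -> "TransgeneEventSpec":
        for target, m in self.target_multiplicity.items():
            if m < 0:
                raise ValueError(f"negative multiplicity for target {target!r}")
        return self


class TissueSpec(BaseModel):
    ploidy: int = Field(gt=0)
    paternal_genomes: int = Field(ge=0)
    dna_mass_fraction: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _paternal_within_ploidy(self) -> "TissueSpec":
        if self.paternal_genomes > self.ploidy:
            raise ValueError("paternal_genomes cannot exceed ploidy")
        return self


class SeedTissueModel(BaseModel):
    """DNA mass contributions of seed tissues with their ploidy makeup.

    For maize seed: diploid embryo (1 paternal of 2 genomes) plus triploid
    endosperm (1 paternal of 3). Mass fractions must sum to 1.
    """

    tissues: dict[str, TissueSpec]

    @model_validator(mode="after")
    def _fractions_sum_to_one(self) -> "SeedTissueModel":
        total = sum(t.dna_mass_fraction for t in self.tissues.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tissue DNA mass fractions sum to {total}, not 1")
        return self


class SampleSpec(BaseModel):
    """A DNA extract as loaded into partitions."""

    dna_conc_ng_per_ul: float = Field(ge=0.0)
    gm_mass_fraction: float = Field(ge=0.0, le=1.0)
    denatured: bool = False
    dilution_factor: float = Field(default=1.0, gt=0.0)
    template_volume_ul: float = Field(gt=0.0)


def mass_to_copies(
    mass_ng: float,
    genome: GenomeSpec,
    route: Literal["bp", "pg"] = "pg",
) -> float:
    """Convert a DNA mass in nanograms to haploid genome copies.

    The ``bp`` route uses Avogadro's number and the molar mass per base
    pair; the ``pg`` route divides by the haploid mass in picograms. For
    maize (2.6 pg) the pg route gives 384.6 copies/ng, i.e. the published
    385 copies per nanogram after rounding.
    """
    if mass_ng < 0:
        raise InvalidSpecError("DNA mass must be non-negative")
    if route == "bp":
        return mass_ng * 1e-9 * AVOGADRO / (genome.haploid_size_bp * genome.molar_mass_per_bp)
    if route == "pg":
        return mass_ng / genome.mass_pg * 1000.0
    raise ValueError(f"unknown route {route!r}")


def transgene_dosage(
    event: TransgeneEventSpec,
    tissue: SeedTissueModel,
    mode: DosageMode = "mechanistic",
) -> float:
    """Fraction of haploid genome copies that carry the transgene locus.

    Homozygous events contribute a full dose (1.0). Hemizygous events are
    weighted across seed tissues by DNA mass fraction times the fraction of
    genomes carrying the locus: paternal genomes / ploidy when the
    transgenic parent is male, maternal / ploidy when female. ``literal``
    mode returns exactly 160/385, the published adjustment.
    """
    if event.zygosity == "homozygous":
        return 1.0
    if event.transgenic_parent == "not_applicable":
        raise InvalidSpecError(
            "hemizygous event requires a transgenic parent (male or female)"
        )
    if mode == "literal":
        return LITERAL_HEMIZYGOUS_FACTOR
    dose = 0.0
    for tspec in tissue.tissues.values():
        if event.transgenic_parent == "male":
            bearing = tspec.paternal_genomes
        else:
            bearing = tspec.ploidy - tspec.paternal_genomes
        dose += tspec.dna_mass_fraction * bearing / tspec.ploidy
    if not 0.0 < dose <= 1.0:
        raise InvalidSpecError(f"computed dosage {dose} outside (0, 1]")
    return dose


def _copies_per_ng_single_target(
    event: TransgeneEventSpec,
    genome: GenomeSpec,
    tissue: SeedTissueModel,
    dosage_mode: DosageMode,
    route: Literal["bp", "pg"],
) -> float:
    """Copies/ng of transgenic DNA for a multiplicity-1 target."""
    if dosage_mode == "literal":
        # published per-ng constants; reproduces printed arithmetic exactly
        if event.zygosity == "homozygous":
            return HOMOZYGOUS_COPIES_PER_NG
        if event.transgenic_parent == "not_applicable":
            raise InvalidSpecError(
                "hemizygous event requires a transgenic parent (male or female)"
            )
        return HEMIZYGOUS_COPIES_PER_NG
    return mass_to_copies(1.0, genome, route) * transgene_dosage(event, tissue, "mechanistic")


def target_copies_per_ng(
    target: str,
    event: TransgeneEventSpec,
    genome: GenomeSpec,
    tissue: SeedTissueModel,
    dosage_mode: DosageMode = "mechanistic",
    route: Literal["bp", "pg"] = "pg",
) -> float:
    """Target copies per nanogram of *transgenic* DNA.

    Product of genome copies per ng, the zygosity/tissue dosage, and the
    target's multiplicity per transgene locus.
    """
    if target not in event.target_multiplicity:
        raise KeyError(f"target {target!r} not defined for event {event.event_name!r}")
    m = event.target_multiplicity[target]
    return _copies_per_ng_single_target(event, genome, tissue, dosage_mode, route) * m


def effective_multiplicity(event: TransgeneEventSpec, target: str) -> float:
    """Independently distributing units contributed by a duplicated target.

    Two targets on one unfragmented locus co-segregate into the same
    partition; multiplicity m counts as 1 + (m-1) * linkage_independence
    independent units. Zero multiplicity contributes zero units.
    """
    m = event.target_multiplicity[target]
    if m == 0:
        return 0.0
    return 1.0 + (m - 1) * event.linkage_independence


def expected_copies_per_partition(
    sample: SampleSpec,
    target: str,
    event: TransgeneEventSpec,
    genome: GenomeSpec,
    tissue: SeedTissueModel,
    dosage_mode: DosageMode = "mechanistic",
    route: Literal["bp", "pg"] = "pg",
    linkage_mode: bool = True,
) -> float:
    """Mean independently distributing target molecules per partition (λ).

    λ = conc × GM fraction × copies/ng × volume / dilution, doubled when the
    template was heat denatured (each strand then distributes and initiates
    independently). With ``linkage_mode`` the target multiplicity is
    replaced by its effective number of independent units.
    """
    if target not in event.target_multiplicity:
        raise KeyError(f"target {target!r} not defined for event {event.event_name!r}")
    per_ng_unit = _copies_per_ng_single_target(event, genome, tissue, dosage_mode, route)
    if linkage_mode:
        mult = effective_multiplicity(event, target)
    else:
        mult = float(event.target_multiplicity[target])
    lam = (
        sample.dna_conc_ng_per_ul
        * sample.gm_mass_fraction
        * per_ng_unit
        * mult
        * sample.template_volume_ul
        / sample.dilution_factor
    )
    if sample.denatured:
        lam *= 2.0
    return lam


def plan_dilution(
    target_lambda: float,
    sample: SampleSpec,
    target: str,
    event: TransgeneEventSpec,
    genome: GenomeSpec,
    tissue: SeedTissueModel,
    **kwargs,
) -> float:
    """Dilution factor that brings the stock to a desired mean occupancy.

    Raises :class:`InfeasibleDilutionError` when the undiluted stock is
    already weaker than the requested λ (a dilution cannot concentrate).
    """
    if target_lambda <= 0:
        raise InvalidSpecError("target lambda must be positive")
    stock = sample.model_copy(update={"dilution_factor": 1.0})
    lam_undiluted = expected_copies_per_partition(
        stock, target, event, genome, tissue, **kwargs
    )
    if lam_undiluted < target_lambda:
        raise InfeasibleDilutionError(
            f"undiluted stock yields lambda={lam_undiluted:.4g} < target {target_lambda:.4g}"
        )
    return lam_undiluted / target_lambda


def copies_to_ng(
    target_conc_copies_per_ul: float,
    target: str,
    event: TransgeneEventSpec,
    genome: GenomeSpec,
    tissue: SeedTissueModel,
    gm_mass_fraction: float,
    dosage_mode: DosageMode = "mechanistic",
    route: Literal["bp", "pg"] = "pg",
) -> float:
    """Invert a measured target concentration to total DNA ng/µL.

    Exact inverse of the mass→copies chain: divides by target copies/ng of
    transgenic DNA and by the GM mass fraction. Uses the true target
    multiplicity (mass accounting ignores linkage and denaturation, which
    affect only partition occupancy).
    """
    if target_conc_copies_per_ul < 0:
        raise InvalidSpecError("concentration must be non-negative")
    per_ng = target_copies_per_ng(target, event, genome, tissue, dosage_mode, route)
    if per_ng == 0:
        raise InvalidSpecError(
            f"target {target!r} has zero copies/ng; conversion undefined"
        )
    if gm_mass_fraction <= 0:
        raise InvalidSpecError("gm_mass_fraction must be positive for inversion")
    return target_conc_copies_per_ul / (per_ng * gm_mass_fraction)


def round_copies(copies: float) -> int:
    """Presentation-layer rounding of a real copy number to nearest int."""
    return int(math.floor(copies + 0.5))
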