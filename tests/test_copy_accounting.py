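"""Copy-number accounting: mass -> copies -> partition occupancy and back."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from digilamp.copy_accounting import (
    GenomeSpec,
    SampleSpec,
    SeedTissueModel,
    TransgeneEventSpec,
    copies_to_ng,
    effective_multiplicity,
    expected_copies_per_partition,
    mass_to_copies,
    plan_dilution,
    round_copies,
    target_copies_per_ng,
    transgene_dosage,
)
from digilamp.exceptions import InfeasibleDilutionError, InvalidSpecError


class TestMassToCopies:
    @pytest.mark.parametrize(
        "mass_ng, route, expected",
        [
            # 1 ng of 2.6 pg haploid genome: the canonical 385 copies/ng
            (1.0, "pg", 384.6153846),
            (0.0, "pg", 0.0),
            # Avogadro route on 2.4 Gbp at 650 g/mol/bp
            (1.0, "bp", 386.0346641),
        ],
    )
    def test_known_conversions(self, maize, mass_ng, route, expected):
        assert mass_to_copies(mass_ng, maize, route=route) == pytest.approx(expected)

    def test_rounds_to_published_385(self, maize):
        assert round_copies(mass_to_copies(1.0, maize)) == 385

    def test_routes_agree_within_one_percent(self, maize):
        bp = mass_to_copies(1.0, maize, route="bp")
        pg = mass_to_copies(1.0, maize, route="pg")
        assert abs(bp - pg) / pg < 0.01

    def test_derived_mass_consistent_with_size(self):
        g = GenomeSpec(name="x", haploid_size_bp=2_400_000_000)
        assert g.mass_pg == pytest.approx(2.592, rel=1e-3)
        assert g.derived_mass_pg() == pytest.approx(
            g.haploid_size_bp * g.molar_mass_per_bp / 6.02214076e23 * 1e12, rel=1e-9
        )

    @given(
        a=st.floats(min_value=0, max_value=1e4),
        b=st.floats(min_value=0, max_value=1e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, maize, a, b):
        f = lambda m: mass_to_copies(m, maize)
        assert f(a + b) == pytest.approx(f(a) + f(b), rel=1e-9, abs=1e-9)

    def test_negative_mass_rejected(self, maize):
        with pytest.raises(InvalidSpecError):
            mass_to_copies(-1.0, maize)

    def test_invalid_genome_rejected(self):
        with pytest.raises(ValidationError):
            GenomeSpec(name="bad", haploid_size_bp=0)


class TestDosage:
    def test_homozygous_is_full_dose(self, seed_tissue):
        ev = TransgeneEventSpec(
            event_name="homo", zygosity="homozygous",
            transgenic_parent="not_applicable", target_multiplicity={"t": 1},
        )
        assert transgene_dosage(ev, seed_tissue) == 1.0

    def test_literal_factor_is_160_over_385(self, bt11, seed_tissue):
        assert transgene_dosage(bt11, seed_tissue, mode="literal") == 160.0 / 385.0

    def test_mechanistic_embryo_endosperm_weighting(self, bt11, seed_tissue):
        # 0.5*(1/2) + 0.5*(1/3) = 5/12 for a male transgenic parent
        assert transgene_dosage(bt11, seed_tissue) == pytest.approx(5.0 / 12.0)

    def test_female_parent_complements_male(self, seed_tissue):
        male = TransgeneEventSpec(
            event_name="m", zygosity="hemizygous", transgenic_parent="male",
            target_multiplicity={"t": 1},
        )
        female = male.model_copy(update={"transgenic_parent": "female"})
        d_m = transgene_dosage(male, seed_tissue)
        d_f = transgene_dosage(female, seed_tissue)
        assert d_m + d_f == pytest.approx(1.0)

    def test_hemizygous_without_parent_rejected(self, seed_tissue):
        ev = TransgeneEventSpec(
            event_name="bad", zygosity="hemizygous",
            transgenic_parent="not_applicable", target_multiplicity={"t": 1},
        )
        with pytest.raises(InvalidSpecError):
            transgene_dosage(ev, seed_tissue)

    def test_tissue_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            SeedTissueModel(
                tissues={
                    "embryo": dict(ploidy=2, paternal_genomes=1, dna_mass_fraction=0.3),
                    "endosperm": dict(ploidy=3, paternal_genomes=1, dna_mass_fraction=0.3),
                }
            )


class TestTargetCopiesPerNg:
    def test_homozygous_single_target(self, maize, seed_tissue):
        ev = TransgeneEventSpec(
            event_name="homo", zygosity="homozygous",
            transgenic_parent="not_applicable", target_multiplicity={"t": 1},
        )
        assert target_copies_per_ng("t", ev, maize, seed_tissue) == pytest.approx(384.615, abs=0.01)

    def test_bt11_35sp_literal_reproduces_printed_arithmetic(self, bt11, maize, seed_tissue):
        # two 35S copies per locus at 160.4 copies/ng -> 320.8
        val = target_copies_per_ng("35Sp", bt11, maize, seed_tissue, dosage_mode="literal")
        assert val == pytest.approx(320.8)

    def test_lost_target_gives_zero(self, mon810, maize, seed_tissue):
        assert target_copies_per_ng("NOSt", mon810, maize, seed_tissue) == 0.0

    def test_unknown_target_keyerror(self, bt11, maize, seed_tissue):
        with pytest.raises(KeyError):
            target_copies_per_ng("nope", bt11, maize, seed_tissue)


class TestPartitionOccupancy:
    def _sample(self, **kw):
        base = dict(
            dna_conc_ng_per_ul=12.3, gm_mass_fraction=0.001,
            denatured=False, dilution_factor=1.0, template_volume_ul=5.0,
        )
        base.update(kw)
        return SampleSpec(**base)

    def test_denaturation_exactly_doubles_lambda(self, bt11, maize, seed_tissue):
        native = expected_copies_per_partition(
            self._sample(), "35Sp", bt11, maize, seed_tissue
        )
        denat = expected_copies_per_partition(
            self._sample(denatured=True), "35Sp", bt11, maize, seed_tissue
        )
        assert denat == 2.0 * native

    def test_zero_gm_fraction_gives_zero(self, bt11, maize, seed_tissue):
        lam = expected_copies_per_partition(
            self._sample(gm_mass_fraction=0.0), "35Sp", bt11, maize, seed_tissue
        )
        assert lam == 0.0

    def test_bt11_dilution_to_single_copy(self, bt11, maize, seed_tissue):
        # 12.3 ng/uL of 0.1% Bt11 at 320.8 copies/ng and 5 uL diluted to 0.8
        dil = plan_dilution(
            0.8, self._sample(), "35Sp", bt11, maize, seed_tissue, dosage_mode="literal"
        )
        assert dil == pytest.approx(24.66, abs=0.01)
        lam = expected_copies_per_partition(
            self._sample(dilution_factor=dil), "35Sp", bt11, maize, seed_tissue,
            dosage_mode="literal",
        )
        assert lam == pytest.approx(0.8, rel=1e-9)

    def test_fully_linked_duplicate_halves_independent_units(self, bt11, maize, seed_tissue):
        linked = bt11.model_copy(update={"linkage_independence": 0.0})
        lam_free = expected_copies_per_partition(
            self._sample(), "35Sp", bt11, maize, seed_tissue
        )
        lam_linked = expected_copies_per_partition(
            self._sample(), "35Sp", linked, maize, seed_tissue
        )
        assert lam_linked == pytest.approx(lam_free / 2.0)
        assert effective_multiplicity(linked, "35Sp") == 1.0

    def test_plan_dilution_trivial_cases(self, bt11, maize, seed_tissue):
        lam1 = expected_copies_per_partition(
            self._sample(), "35Sp", bt11, maize, seed_tissue
        )
        assert plan_dilution(lam1, self._sample(), "35Sp", bt11, maize, seed_tissue) == pytest.approx(1.0)
        assert plan_dilution(lam1 / 2, self._sample(), "35Sp", bt11, maize, seed_tissue) == pytest.approx(2.0)

    def test_plan_dilution_infeasible_stock(self, bt11, maize, seed_tissue):
        with pytest.raises(InfeasibleDilutionError):
            plan_dilution(1e9, self._sample(), "35Sp", bt11, maize, seed_tissue)

    @given(
        conc=st.floats(min_value=0.1, max_value=100),
        frac=st.floats(min_value=1e-4, max_value=1.0),
        vol=st.floats(min_value=0.5, max_value=20),
        target_lam=st.floats(min_value=1e-3, max_value=0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_dilution_roundtrip(self, bt11, maize, seed_tissue, conc, frac, vol, target_lam):
        sample = self._sample(
            dna_conc_ng_per_ul=conc, gm_mass_fraction=frac, template_volume_ul=vol
        )
        lam1 = expected_copies_per_partition(sample, "35Sp", bt11, maize, seed_tissue)
        if lam1 < target_lam:
            return
        dil = plan_dilution(target_lam, sample, "35Sp", bt11, maize, seed_tissue)
        lam = expected_copies_per_partition(
            sample.model_copy(update={"dilution_factor": dil}),
            "35Sp", bt11, maize, seed_tissue,
        )
        assert lam == pytest.approx(target_lam, rel=1e-9)


class TestCopiesToNg:
    def test_published_qpcr_backconversion(self, bt11, maize, seed_tissue):
        # 2.26 copies/uL of 35Sp in a 0.1% extract -> ~7.04 ng/uL total DNA
        ng = copies_to_ng(2.26, "35Sp", bt11, maize, seed_tissue, 0.001, dosage_mode="literal")
        assert ng == pytest.approx(7.04, abs=0.01)

    def test_zero_concentration(self, bt11, maize, seed_tissue):
        assert copies_to_ng(0.0, "35Sp", bt11, maize, seed_tissue, 0.001) == 0.0

    def test_lost_target_conversion_undefined(self, mon810, maize, seed_tissue):
        with pytest.raises(InvalidSpecError):
            copies_to_ng(1.0, "NOSt", mon810, maize, seed_tissue, 0.001)

    @given(
        ng=st.floats(min_value=1e-3, max_value=100),
        frac=st.floats(min_value=1e-4, max_value=1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_forward_then_inverse_is_identity(self, bt11, maize, seed_tissue, ng, frac):
        per_ng = target_copies_per_ng("35Sp", bt11, maize, seed_tissue)
        copies_per_ul = ng * frac * per_ng
        back = copies_to_ng(copies_per_ul, "35Sp", bt11, maize, seed_tissue, frac)
        assert back == pytest.approx(ng, rel=1e-9)
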