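"""Restraint generation, trimming, protonation variants and CIF round trips."""

import numpy as np
import pytest

from conftest import TRP_CHI2, TRP_CHI2_CONFORMERS
from ligrest.components import ComponentIntegrityError, parse_component_cif, write_component_cif
from ligrest.fixtures import make_fixture, make_reference_table
from ligrest.geometry import bond_angle, bond_length, dihedral
from ligrest.minimize import torsion_deviation
from ligrest.restraints import (
    EsdDefaults,
    GeometryRestraints,
    TorsionRestraint,
    enumerate_protonation_variants,
    generate_restraints,
    read_restraints_cif,
    restraints_equal,
    trim_polymer_termini,
    write_restraints_cif,
)
from ligrest.validation import ReferenceEntry, ReferenceTable, TypingContext


def _measured(component, restraint):
    pos = [component.atom(n).coordinates for n in restraint.atoms]
    if len(pos) == 2:
        return bond_length(*pos)
    if len(pos) == 3:
        return bond_angle(*pos)
    return dihedral(*pos)


class TestGeneration:
    def test_ideals_are_measured_values(self, any_component):
        rs = generate_restraints(any_component)
        for r in rs.bonds + rs.angles:
            assert _measured(any_component, r) == pytest.approx(r.ideal, abs=1e-9)

    def test_zero_residual_at_source_geometry(self, any_component):
        rs = generate_restraints(any_component)
        for r in rs.torsions:
            obs = _measured(any_component, r)
            assert torsion_deviation(obs, r) == pytest.approx(0.0, abs=1e-8)
        for r in rs.chirals:
            pc = any_component.atom(r.centre).coordinates
            vs = [any_component.atom(n).coordinates - pc
                  for n in (r.neighbour_1, r.neighbour_2, r.neighbour_3)]
            assert float(np.dot(vs[0], np.cross(vs[1], vs[2]))) == pytest.approx(
                r.volume_ideal, abs=1e-9
            )

    def test_ethane_hcch_torsion_period_three(self, ethane):
        rs = generate_restraints(ethane)
        central = [t for t in rs.torsions
                   if {t.atom_2, t.atom_3} == {"C1", "C2"}]
        assert central
        assert all(t.mode == "periodic" and t.period == 3 for t in central)

    def test_benzene_ring_torsion_period_two(self, benzene):
        rs = generate_restraints(benzene)
        assert all(t.period == 2 for t in rs.torsions if t.mode == "periodic")

    def test_reference_esd_is_twice_sd(self, acetate):
        typing = TypingContext(acetate)
        key = typing.bond_key("C1", "O2")  # the C–O single bond
        table = ReferenceTable([ReferenceEntry("bond", key, 1.27, 0.011)])
        rs = generate_restraints(acetate, reference=table)
        matched = [r for r in rs.bonds if set(r.atoms) == {"C1", "O2"}]
        assert matched[0].esd == pytest.approx(0.022)
        # unmatched bonds fall back to the default
        others = [r for r in rs.bonds if set(r.atoms) != {"C1", "O2"}]
        assert all(r.esd == pytest.approx(EsdDefaults().bond) for r in others)

    def test_zero_sd_reference_falls_back_to_default(self, acetate):
        typing = TypingContext(acetate)
        key = typing.bond_key("C1", "O2")
        table = ReferenceTable([ReferenceEntry("bond", key, 1.27, 0.0)])
        rs = generate_restraints(acetate, reference=table)
        matched = [r for r in rs.bonds if set(r.atoms) == {"C1", "O2"}]
        assert matched[0].esd == pytest.approx(EsdDefaults().bond)

    def test_caller_supplied_discrete_chi2(self, trp_sidechain):
        rs = generate_restraints(
            trp_sidechain, discrete_torsions={TRP_CHI2: TRP_CHI2_CONFORMERS}
        )
        chi2 = [t for t in rs.torsions if t.atoms in (TRP_CHI2, TRP_CHI2[::-1])]
        assert len(chi2) == 1
        assert chi2[0].mode == "discrete"
        assert chi2[0].ideal_list == TRP_CHI2_CONFORMERS

    def test_hydrogen_completeness(self, any_component):
        rs = generate_restraints(any_component)
        in_bond = {a for r in rs.bonds for a in r.atoms}
        in_angle = {a for r in rs.angles for a in r.atoms}
        in_tor = {a for r in rs.torsions for a in r.atoms}
        hydrogens = {a.name for a in any_component.atoms if a.is_hydrogen}
        assert hydrogens <= in_bond
        assert hydrogens <= in_angle
        assert hydrogens <= in_tor  # every fixture H has a 4-atom path

    def test_all_esds_positive(self, any_component):
        rs = generate_restraints(any_component)
        assert all(r.esd > 0 for r in rs.all_restraints())

    def test_missing_coordinates_rejected(self, acetate):
        from dataclasses import replace
        bare = replace(
            acetate, atoms=[replace(a, coordinates=None) for a in acetate.atoms]
        )
        with pytest.raises(ComponentIntegrityError):
            generate_restraints(bare)


class TestTrimming:
    def test_removes_exactly_terminus_restraints(self, dipeptide_like):
        rs = generate_restraints(dipeptide_like)
        trimmed = trim_polymer_termini(rs, dipeptide_like)
        drop = {"H2", "OXT", "HXT"}
        for kind in ("bonds", "angles", "torsions", "chirals"):
            before = {tuple(r.atoms) for r in getattr(rs, kind)}
            after = {tuple(r.atoms) for r in getattr(trimmed, kind)}
            # exactly the terminus-touching restraints disappear
            assert before - after == {a for a in before if set(a) & drop}
            assert all(not (set(a) & drop) for a in after)
        for r in trimmed.planes:
            assert not (set(r.atoms) & drop)
        assert any(set(r.atoms) & drop for r in rs.all_restraints())
        assert not ({n for n, _ in trimmed.atoms} & drop)

    def test_bond_count_drops_by_terminus_degree(self, dipeptide_like):
        rs = generate_restraints(dipeptide_like)
        trimmed = trim_polymer_termini(rs, dipeptide_like)
        degree = sum(
            1 for r in rs.bonds if set(r.atoms) & {"H2", "OXT", "HXT"}
        )
        assert len(rs.bonds) - len(trimmed.bonds) == degree

    def test_idempotent(self, dipeptide_like):
        rs = generate_restraints(dipeptide_like)
        once = trim_polymer_termini(rs, dipeptide_like)
        twice = trim_polymer_termini(once, dipeptide_like)
        assert restraints_equal(once, twice)

    def test_non_polymer_untouched(self, acetate):
        rs = generate_restraints(acetate)
        assert trim_polymer_termini(rs, acetate) is rs


class TestProtonationVariants:
    def test_acetate_yields_acid_variant(self, acetate):
        variants = enumerate_protonation_variants(acetate)
        assert len(variants) == 2
        neutral, acid = variants
        assert neutral is acetate
        assert acid.variant == "protonated"
        assert len(acid.atoms) == len(acetate.atoms) + 1
        assert acid.net_charge() == 0
        new_h = acid.atom("HO2")
        # O–H 0.98 Å and in the carboxyl plane, anti to C=O
        assert bond_length(new_h.coordinates, acid.atom("O2").coordinates) == pytest.approx(0.98)
        assert bond_angle(
            acid.atom("C1").coordinates, acid.atom("O2").coordinates, new_h.coordinates
        ) == pytest.approx(106.0)
        tor = dihedral(
            new_h.coordinates, acid.atom("O2").coordinates,
            acid.atom("C1").coordinates, acid.atom("O1").coordinates,
        )
        assert abs(tor) == pytest.approx(180.0, abs=1e-6)

    def test_acid_variant_restraints_generate(self, acetate):
        acid = enumerate_protonation_variants(acetate)[1]
        rs = generate_restraints(acid)
        assert any(set(r.atoms) == {"O2", "HO2"} for r in rs.bonds)

    def test_ethane_has_no_variant(self, ethane):
        assert enumerate_protonation_variants(ethane) == [ethane]

    def test_dicarboxylate_policies(self, dicarboxylate):
        default = enumerate_protonation_variants(dicarboxylate)
        assert len(default) == 2
        assert default[1].net_charge() == 0  # both sites protonated
        combinatorial = enumerate_protonation_variants(dicarboxylate, combinatorial=True)
        assert len(combinatorial) == 4  # none, site A, site B, both


class TestRestraintsCif:
    def _restraints(self, component):
        dt = {TRP_CHI2: TRP_CHI2_CONFORMERS} if component.id == "TRPSC" else None
        return generate_restraints(component, discrete_torsions=dt)

    def test_round_trip_identity(self, any_component):
        rs = self._restraints(any_component)
        text = write_restraints_cif(rs)
        assert restraints_equal(rs, read_restraints_cif(text))

    def test_byte_stable_after_one_normalisation(self, any_component):
        rs = self._restraints(any_component)
        text = write_restraints_cif(rs)
        assert write_restraints_cif(read_restraints_cif(text)) == text

    def test_expected_loops_present(self, acetate):
        text = write_restraints_cif(generate_restraints(acetate))
        for cat in ("_chem_comp_bond", "_chem_comp_angle", "_chem_comp_tor",
                    "_chem_comp_plane_atom"):
            assert cat in text

    def test_discrete_rows_share_base_id(self, trp_sidechain):
        rs = self._restraints(trp_sidechain)
        text = write_restraints_cif(rs)
        alts = [l.split()[1] for l in text.splitlines() if "_alt" in l]
        assert len(alts) == 3
        bases = {a.rsplit("_alt", 1)[0] for a in alts}
        assert len(bases) == 1

    def test_five_character_id_round_trip(self, acetate):
        rs = generate_restraints(acetate)
        rs.component_id = "A1B2C"
        back = read_restraints_cif(write_restraints_cif(rs))
        assert back.component_id == "A1B2C"
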