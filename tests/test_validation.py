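"""Z-score validation: floors, classification tiers, side-chain restriction."""

import pytest
from hypothesis import given, strategies as st

from ligrest.fixtures import make_fixture, make_reference_table
from ligrest.validation import (
    ANGLE_SD_FLOOR,
    BOND_SD_FLOOR,
    DEFAULT_BACKBONE_ATOMS,
    ReferenceEntry,
    ReferenceTable,
    TypingContext,
    apply_sd_floor,
    classify,
    validate_geometry,
    zscore,
)


class TestZScore:
    @pytest.mark.parametrize(
        "observed,ideal,sd,expected",
        [(1.54, 1.52, 0.01, 2.0), (120.0, 120.0, 1.5, 0.0), (1.50, 1.52, 0.01, -2.0)],
    )
    def test_arithmetic(self, observed, ideal, sd, expected):
        assert zscore(observed, ideal, sd) == pytest.approx(expected)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            zscore(1.5, 1.5, 0.0)


class TestFloors:
    @pytest.mark.parametrize(
        "sd_raw,kind,expected_sd,expected_floored",
        [(0.0, "bond", BOND_SD_FLOOR, True),
         (0.5, "angle", ANGLE_SD_FLOOR, True),
         (0.02, "bond", 0.02, False),
         (2.0, "angle", 2.0, False)],
    )
    def test_floor_substitution(self, sd_raw, kind, expected_sd, expected_floored):
        sd_eff, floored = apply_sd_floor(sd_raw, kind)
        assert sd_eff == expected_sd
        assert floored == expected_floored

    def test_printed_floor_values(self):
        assert apply_sd_floor(0.0, "bond") == (0.005, True)
        assert apply_sd_floor(0.0, "angle") == (0.75, True)


class TestClassify:
    @pytest.mark.parametrize(
        "z,expected",
        [(0.0, "perfect"), (1.9, "perfect"), (2.0, "grand"), (3.99, "grand"),
         (4.0, "ok"), (5.99, "ok"), (6.0, "fail"), (10.0, "fail")],
    )
    def test_strict_tier_boundaries(self, z, expected):
        assert classify(z, False, False).classification == expected

    def test_reasonable_std_overrides_tier(self):
        result = classify(1.0, True, False)
        assert result.classification == "ok"
        assert result.reasonable_std
        assert result.designation == "ok (reasonable std)"

    def test_reasonable_std_cannot_rescue_fail(self):
        result = classify(6.5, True, False)
        assert result.classification == "fail"
        assert not result.reasonable_std

    def test_side_chain_suffix(self):
        assert classify(1.0, False, True).designation == "perfect (side chain)"
        assert classify(1.0, True, True).designation == "ok (reasonable std) (side chain)"

    @given(
        st.floats(0, 20, allow_nan=False), st.floats(0, 20, allow_nan=False),
        st.booleans(),
    )
    def test_monotone_in_max_abs_z(self, z1, z2, floored):
        order = {"perfect": 0, "grand": 1, "ok": 2, "fail": 3}
        lo, hi = sorted((z1, z2))
        assert (
            order[classify(lo, floored, False).classification]
            <= order[classify(hi, floored, False).classification]
        )


class TestValidateGeometry:
    def test_self_validation_is_perfect(self, any_component):
        table = make_reference_table([any_component])
        report = validate_geometry(any_component, table)
        assert report.classification.classification == "perfect"
        assert report.max_abs_z == pytest.approx(0.0, abs=1e-8)
        assert report.coverage == 1.0

    def test_rmsz_bounded_by_max(self, any_component):
        table = make_reference_table([any_component])
        report = validate_geometry(any_component, table)
        assert report.rms_z <= report.max_abs_z + 1e-12

    def test_shifted_ideal_gives_grand(self, acetate):
        table = make_reference_table([acetate], sd_bond=0.01, sd_angle=1.5)
        typing = TypingContext(acetate)
        key = typing.bond_key("C1", "C2")
        shifted = ReferenceTable(
            ReferenceEntry(e.kind, e.type_key,
                           e.ideal + (3 * e.sd if e.type_key == key else 0.0),
                           e.sd, e.n_obs)
            for e in table
        )
        report = validate_geometry(acetate, shifted)
        assert report.max_abs_z == pytest.approx(3.0)
        assert report.classification.classification == "grand"

    def test_zero_sd_entry_floored_and_reasonable_std(self, acetate):
        typing = TypingContext(acetate)
        key = typing.bond_key("C1", "C2")
        table = make_reference_table([acetate], zero_sd_keys={key})
        report = validate_geometry(acetate, table)
        floored = [r for r in report.records if r.floored]
        assert len(floored) == 1
        assert floored[0].sd_effective == BOND_SD_FLOOR
        assert report.classification.reasonable_std
        assert report.designation == "ok (reasonable std)"

    def test_side_chain_restriction(self, dipeptide_like):
        table = make_reference_table([dipeptide_like])
        side = {a.name for a in dipeptide_like.atoms} - set(DEFAULT_BACKBONE_ATOMS)
        report = validate_geometry(dipeptide_like, table, restrict_to=side)
        assert report.side_chain
        assert report.designation.endswith("(side chain)")
        for r in report.records:
            assert set(r.atoms) <= side
        full = validate_geometry(dipeptide_like, table)
        assert len(report.records) < len(full.records)

    def test_no_coverage_is_fail(self, acetate):
        table = ReferenceTable([ReferenceEntry("bond", "ZZ9~ZZ9:single", 1.0, 0.01)])
        report = validate_geometry(acetate, table)
        assert report.no_coverage
        assert report.classification.classification == "fail"

    def test_uncovered_metrics_counted_not_dropped(self, acetate):
        typing = TypingContext(acetate)
        key = typing.bond_key("C1", "C2")
        table = ReferenceTable([ReferenceEntry("bond", key, 1.52, 0.01)])
        report = validate_geometry(acetate, table)
        assert len(report.records) == 1
        assert report.n_skipped > 0
        assert 0 < report.coverage < 1

    def test_table_csv_round_trip(self, acetate, tmp_path):
        table = make_reference_table([acetate])
        path = tmp_path / "ref.csv"
        table.to_csv(path)
        again = ReferenceTable.from_csv(path)
        assert len(again) == len(table)
        report = validate_geometry(acetate, again)
        assert report.max_abs_z == pytest.approx(0.0, abs=1e-8)

    def test_shared_keys_accumulate_observations(self, ethane):
        other = make_fixture("ethane")
        table = make_reference_table([ethane, other])
        assert all(e.n_obs >= 2 for e in table)
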