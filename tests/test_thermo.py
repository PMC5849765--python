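"""Constants-table I/O, validation, and conditional stability constants."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from gdchelate.thermo import (
    Component,
    EquilibriumSpecies,
    ParseError,
    PhysiologicalMedium,
    ThermoTable,
    ValidationError,
    assemble_system,
    conditional_stability_constant,
    count_equilibria,
    load_constants,
    load_medium,
    parse_concentration,
    physiological_medium,
    write_constants,
)

from conftest import make_table

MINIMAL = """\
#! H\t+1\tproton
#! M\t+2\tmetal
#! L\t-2\tendogenous_ligand
label\tlog_beta\tH\tM\tL
ML\t6\t0\t1\t1
"""


def test_minimal_file_one_equilibrium(tmp_path):
    p = tmp_path / "min.tsv"
    p.write_text(MINIMAL)
    table = load_constants(p)
    assert len(table.species) == 1
    assert table.species[0].log_beta == 6.0
    assert table.species[0].stoichiometry == {"M": 1, "L": 1}


def test_packaged_table_holds_all_gd_chelate_entries(table):
    for chel in ("HOPO", "DTPA", "DOTA", "DTPA-BMA", "EDTA"):
        ml = [
            s for s in table.species
            if dict(s.stoichiometry) == {"Gd": 1, chel: 1}
        ]
        assert len(ml) == 1, f"missing Gd-{chel} 1:1 complex"
    assert set(table.chelators()) == {"HOPO", "DTPA", "DOTA", "DTPA-BMA", "EDTA"}


def test_undeclared_component_column_rejected(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(MINIMAL.replace("\tL\n", "\tL\tFe\n").replace(
        "ML\t6\t0\t1\t1", "ML\t6\t0\t1\t1\t1"))
    with pytest.raises(ParseError, match="Fe"):
        load_constants(p)


def test_malformed_row_names_line(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(MINIMAL + "M2L\tnot_a_number\t0\t2\t1\n")
    with pytest.raises(ParseError, match=r"bad\.tsv:6"):
        load_constants(p)


def test_duplicate_label_rejected(tmp_path):
    p = tmp_path / "dup.tsv"
    p.write_text(MINIMAL + "ML\t7\t0\t1\t1\n")
    with pytest.raises(ValidationError, match="duplicate"):
        load_constants(p)


def test_table_invariants():
    with pytest.raises(ValidationError, match="proton"):
        ThermoTable([Component("M", 2, "metal")], [])
    with pytest.raises(ValidationError, match="undeclared"):
        ThermoTable(
            [Component("H", 1, "proton")],
            [EquilibriumSpecies("X", 1.0, {"Q": 1})],
        )
    with pytest.raises(ValidationError, match="empty stoichiometry"):
        EquilibriumSpecies("X", 1.0, {"M": 0})


def test_round_trip_preserves_constants(table, tmp_path):
    p = tmp_path / "out.tsv"
    write_constants(table, p)
    back = load_constants(p)
    assert back.pKw == table.pKw
    assert len(back.species) == len(table.species)
    for a, b in zip(table.species, back.species):
        assert a.label == b.label
        assert a.log_beta == b.log_beta
        assert dict(a.stoichiometry) == dict(b.stoichiometry)
    assert [c.name for c in back.components] == [c.name for c in table.components]


class TestConditionalConstant:
    def test_no_protonation_equals_absolute(self, one_to_one_table):
        assert conditional_stability_constant(
            one_to_one_table, "M", "L", 7.4
        ) == pytest.approx(6.0)

    def test_monoprotic_ligand_alpha(self):
        # log beta(HL) = 10 at pH 7.4: alpha = 1 + 10^2.6
        t = make_table([
            ("ML", 12.0, {"M": 1, "L": 1}),
            ("HL", 10.0, {"H": 1, "L": 1}),
        ])
        expect = 12.0 - math.log10(1.0 + 10.0**2.6)
        assert conditional_stability_constant(t, "M", "L", 7.4) == pytest.approx(
            expect, abs=1e-12
        )
        assert 12.0 - expect == pytest.approx(2.601, abs=1e-3)

    def test_high_ph_limit_recovers_absolute(self):
        t = make_table([
            ("ML", 12.0, {"M": 1, "L": 1}),
            ("HL", 10.0, {"H": 1, "L": 1}),
        ])
        assert conditional_stability_constant(t, "M", "L", 13.9) == pytest.approx(
            12.0, abs=1e-3
        )

    def test_missing_complex_raises(self, one_to_one_table):
        with pytest.raises(LookupError):
            conditional_stability_constant(one_to_one_table, "M", "H", 7.4)

    @settings(deadline=None, max_examples=30)
    @given(
        bump=st.floats(0.0, 5.0),
        ph=st.floats(4.0, 10.0),
        log_hl=st.floats(2.0, 12.0),
    )
    def test_raising_basicity_never_raises_conditional(self, bump, ph, log_hl):
        base = make_table([
            ("ML", 15.0, {"M": 1, "L": 1}),
            ("HL", log_hl, {"H": 1, "L": 1}),
        ])
        more_basic = make_table([
            ("ML", 15.0, {"M": 1, "L": 1}),
            ("HL", log_hl + bump, {"H": 1, "L": 1}),
        ])
        assert (
            conditional_stability_constant(more_basic, "M", "L", ph)
            <= conditional_stability_constant(base, "M", "L", ph) + 1e-12
        )


class TestMediumAndAssembly:
    def test_concentration_units(self):
        assert parse_concentration("1.1 mM") == pytest.approx(1.1e-3)
        assert parse_concentration("15 uM") == pytest.approx(15e-6)
        assert parse_concentration("9.2 µM") == pytest.approx(9.2e-6)
        assert parse_concentration(0.025) == 0.025
        with pytest.raises(ParseError):
            parse_concentration("3 furlongs")

    def test_medium_validation(self):
        with pytest.raises(ValidationError):
            PhysiologicalMedium({"CO3": 0.0}, 7.4)
        with pytest.raises(ValidationError):
            PhysiologicalMedium({"CO3": 1e-3}, 15.0)

    def test_medium_config_round_trip(self, tmp_path):
        p = tmp_path / "medium.yaml"
        p.write_text(
            "pH: 7.4\ntotals:\n  PO4: 1.1 mM\n  CO3: 25 mM\n  Cit: 160 uM\n"
        )
        m = load_medium(p)
        assert m.pH == 7.4
        assert m.totals["PO4"] == pytest.approx(1.1e-3)
        assert m.totals["Cit"] == pytest.approx(160e-6)

    def test_medium_only_excludes_metal_and_chelator_species(self, table, medium):
        problem = assemble_system(table, medium)
        names = {n for s in problem.species for n in s.stoichiometry}
        assert names <= set(medium.totals) | {"H"}
        assert count_equilibria(problem) == 11  # ligand protonation ladders

    def test_minimal_toy_counts(self, one_to_one_table, neutral_medium):
        problem = assemble_system(
            one_to_one_table, neutral_medium({"M": 1e-3, "L": 1e-3})
        )
        assert count_equilibria(problem) == 1
        assert len(problem.components) == 2  # two mass balances
        empty = assemble_system(one_to_one_table, neutral_medium({"M": 1e-3}))
        assert count_equilibria(empty) == 0

    def test_full_physiological_system_size(self, table, medium):
        problem = assemble_system(
            table, medium, {"Gd": 1e-5, "DTPA": 1e-5, "Zn": 15e-6}
        )
        assert 40 <= count_equilibria(problem) <= 74

    def test_undeclared_total_rejected(self, table, medium):
        with pytest.raises(ValidationError, match="Fe"):
            assemble_system(table, medium, {"Fe": 1e-6})
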