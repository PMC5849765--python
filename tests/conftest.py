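import pytest

from gdchelate.thermo import (
    Component,
    EquilibriumSpecies,
    PhysiologicalMedium,
    ThermoTable,
    default_constants,
    physiological_medium,
)


@pytest.fixture(scope="session")
def table():
    """The packaged physiological constants table."""
    return default_constants()


@pytest.fixture(scope="session")
def medium():
    """Endogenous-ligand background at pH 7.4 (no Ca/Zn)."""
    return physiological_medium()


def make_table(species, components=None, pKw=13.997):
    """Tiny ad-hoc tables for toy systems.

    ``species``: list of (label, log_beta, stoichiometry-dict); components
    are inferred as M* = metal, L* = ligand unless given explicitly.
    """
    if components is None:
        names = sorted({n for _, _, st in species for n in st} - {"H"})
        components = [Component("H", +1, "proton")]
        for n in names:
            kind = "metal" if n.startswith("M") else "endogenous_ligand"
            charge = +2 if kind == "metal" else -2
            components.append(Component(n, charge, kind))
    return ThermoTable(
        components,
        [EquilibriumSpecies(lbl, lb, st) for lbl, lb, st in species],
        pKw=pKw,
    )


@pytest.fixture
def one_to_one_table():
    """M + L <=> ML with log beta = 6."""
    return make_table([("ML", 6.0, {"M": 1, "L": 1})])


@pytest.fixture
def neutral_medium():
    def _make(totals, pH=7.0):
        return PhysiologicalMedium(totals, pH)

    return _make
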