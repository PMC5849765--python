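"""Thermodynamic data model: components, formation equilibria, and media.

A :class:`ThermoTable` is the in-memory form of a HySS-style constants table:
a set of free *components* (metal ions, chelators, the proton) and a set of
*species*, each defined by a cumulative formation constant ``log beta`` and an
integer stoichiometry over the components.  Hydroxide-containing species are
encoded with negative proton stoichiometry (the ``log *beta`` convention), so
the only table-level water parameter is ``pKw``.

The delimited-text dialect read by :func:`load_constants` is:

* ``#`` starts a comment,
* ``#! name  charge  kind`` declares a component (kind is one of ``metal``,
  ``synthetic_chelator``, ``endogenous_ligand``, ``proton``),
* ``#@ pKw  value`` sets the water ionization constant,
* a header row ``label  log_beta  <component> ... [provenance]`` followed by
  one species per row with signed-integer stoichiometric coefficients.

Tabs or commas both work; decimal points only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .solver import SpeciationProblem

__all__ = [
    "Component",
    "EquilibriumSpecies",
    "ThermoTable",
    "PhysiologicalMedium",
    "ParseError",
    "ValidationError",
    "load_constants",
    "write_constants",
    "default_constants",
    "load_medium",
    "physiological_medium",
    "parse_concentration",
    "conditional_stability_constant",
    "assemble_system",
    "count_equilibria",
]

COMPONENT_KINDS = ("metal", "synthetic_chelator", "endogenous_ligand", "proton")

#: Total concentrations (mol/L) of the endogenous ligand pool used in the
#: physiological dilution simulations, and the fixed pH.
PHYSIOLOGICAL_TOTALS = {
    "PO4": 1.1e-3,   # phosphates
    "CO3": 25e-3,    # carbonates
    "Ox": 9.2e-6,    # oxalates
    "Lac": 1.5e-3,   # lactates
    "Cit": 160e-6,   # citrates
}
PHYSIOLOGICAL_PH = 7.4
CALCIUM_TOTAL = 1.1e-3
ZINC_TOTAL = 15e-6


class ParseError(ValueError):
    """Malformed constants or medium file."""


class ValidationError(ValueError):
    """Structurally valid file with inconsistent content."""


@dataclass(frozen=True)
class Component:
    name: str
    charge: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in COMPONENT_KINDS:
            raise ValidationError(
                f"component {self.name!r}: unknown kind {self.kind!r}"
            )


@dataclass(frozen=True)
class EquilibriumSpecies:
    """One formation equilibrium: ``sum_j nu_j * X_j <=> species``.

    ``stoichiometry`` maps component name to the signed integer coefficient
    nu; a negative proton count encodes hydroxide/deprotonation.
    """

    label: str
    log_beta: float
    stoichiometry: Mapping[str, int]

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_beta):
            raise ValidationError(f"species {self.label!r}: log_beta not finite")
        if not any(v != 0 for v in self.stoichiometry.values()):
            raise ValidationError(f"species {self.label!r}: empty stoichiometry")

    def coeff(self, component: str) -> int:
        return self.stoichiometry.get(component, 0)


@dataclass
class ThermoTable:
    components: list[Component]
    species: list[EquilibriumSpecies]
    pKw: float = 13.78
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate component names")
        protons = [c for c in self.components if c.kind == "proton"]
        if len(protons) != 1:
            raise ValidationError("exactly one component must have kind=proton")
        labels = [s.label for s in self.species]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValidationError(f"duplicate species labels: {sorted(dupes)}")
        known = set(names)
        for s in self.species:
            unknown = set(s.stoichiometry) - known
            if unknown:
                raise ValidationError(
                    f"species {s.label!r} references undeclared components "
                    f"{sorted(unknown)}"
                )

    @property
    def proton(self) -> str:
        return next(c.name for c in self.components if c.kind == "proton")

    def component(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise LookupError(f"no component named {name!r}")

    def species_by_label(self, label: str) -> EquilibriumSpecies:
        for s in self.species:
            if s.label == label:
                return s
        raise LookupError(f"no species labelled {label!r}")

    def chelators(self) -> list[str]:
        return [c.name for c in self.components if c.kind == "synthetic_chelator"]


def _split_row(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [f.strip() for f in line.split(sep)]


def load_constants(path: str | Path) -> ThermoTable:
    """Read a delimited constants table and return a validated ThermoTable."""
    path = Path(path)
    components: list[Component] = []
    pKw = 13.78
    header: list[str] | None = None
    species: list[EquilibriumSpecies] = []
    provenance: dict[str, str] = {}
    nu_cols: list[str] = []
    has_prov = False

    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#!"):
                fields = line[2:].split()
                if len(fields) != 3:
                    raise ParseError(
                        f"{path.name}:{lineno}: component directive needs "
                        "'name charge kind'"
                    )
                name, charge, kind = fields
                try:
                    components.append(Component(name, int(charge), kind))
                except ValueError as exc:
                    raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
                continue
            if line.startswith("#@"):
                fields = line[2:].split()
                if len(fields) != 2 or fields[0] != "pKw":
                    raise ParseError(f"{path.name}:{lineno}: bad table directive")
                pKw = float(fields[1])
                continue
            if line.startswith("#"):
                continue
            row = _split_row(line)
            if header is None:
                header = row
                if header[:2] != ["label", "log_beta"]:
                    raise ParseError(
                        f"{path.name}:{lineno}: header must start with "
                        "'label, log_beta'"
                    )
                nu_cols = header[2:]
                has_prov = bool(nu_cols) and nu_cols[-1] == "provenance"
                if has_prov:
                    nu_cols = nu_cols[:-1]
                declared = {c.name for c in components}
                undeclared = [n for n in nu_cols if n not in declared]
                if undeclared:
                    raise ParseError(
                        f"{path.name}:{lineno}: stoichiometry columns for "
                        f"undeclared components {undeclared}"
                    )
                continue
            expected = 2 + len(nu_cols) + (1 if has_prov else 0)
            if len(row) not in (expected, expected - 1 if has_prov else expected):
                raise ParseError(
                    f"{path.name}:{lineno}: expected {expected} fields, "
                    f"got {len(row)}"
                )
            label = row[0]
            try:
                log_beta = float(row[1])
                nus = [int(v) for v in row[2 : 2 + len(nu_cols)]]
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            stoich = {n: v for n, v in zip(nu_cols, nus) if v != 0}
            try:
                species.append(EquilibriumSpecies(label, log_beta, stoich))
            except ValidationError as exc:
                raise ParseError(f"{path.name}:{lineno}: {exc}") from exc
            if has_prov and len(row) == expected:
                provenance[label] = row[-1]

    if header is None:
        raise ParseError(f"{path.name}: no header row found")
    return ThermoTable(components, species, pKw=pKw, provenance=provenance)


def write_constants(table: ThermoTable, path: str | Path) -> None:
    """Write a ThermoTable in the dialect read back by :func:`load_constants`."""
    path = Path(path)
    names = [c.name for c in table.components]
    lines = []
    for c in table.components:
        lines.append(f"#! {c.name}\t{c.charge:+d}\t{c.kind}")
    lines.append(f"#@ pKw\t{table.pKw!r}")
    lines.append("\t".join(["label", "log_beta", *names, "provenance"]))
    for s in table.species:
        nus = [str(s.coeff(n)) for n in names]
        prov = table.provenance.get(s.label, "")
        lines.append("\t".join([s.label, repr(s.log_beta), *nus, prov]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def default_constants() -> ThermoTable:
    """The packaged Gd/Ca/Zn--chelator--endogenous-ligand constants table."""
    ref = resources.files("gdchelate").joinpath(
        "data/gd_physiological_constants.tsv"
    )
    with resources.as_file(ref) as p:
        return load_constants(p)


@dataclass(frozen=True)
class PhysiologicalMedium:
    """Fixed-pH background: total concentrations (mol/L) per component."""

    totals: Mapping[str, float]
    pH: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pH < 14.0:
            raise ValidationError(f"pH {self.pH} outside (0, 14)")
        for name, conc in self.totals.items():
            if not conc > 0:
                raise ValidationError(
                    f"total for {name!r} must be strictly positive, got {conc}"
                )

    def with_totals(self, extra: Mapping[str, float]) -> "PhysiologicalMedium":
        merged = dict(self.totals)
        merged.update({k: v for k, v in extra.items() if v > 0})
        return PhysiologicalMedium(merged, self.pH)


_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6,
               "μM": 1e-6, "nM": 1e-9}


def parse_concentration(text: str | float) -> float:
    """Parse '1.1 mM' / '15 uM' / plain mol/L numbers to mol/L."""
    if isinstance(text, (int, float)):
        return float(text)
    parts = str(text).split()
    if len(parts) == 1:
        return float(parts[0])
    if len(parts) == 2 and parts[1] in _UNIT_SCALE:
        return float(parts[0]) * _UNIT_SCALE[parts[1]]
    raise ParseError(f"cannot parse concentration {text!r}")


def load_medium(path: str | Path) -> PhysiologicalMedium:
    """Read a YAML medium config: ``pH`` plus ``totals: {name: '1.1 mM', ...}``."""
    import yaml

    with Path(path).open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "pH" not in doc or "totals" not in doc:
        raise ParseError(f"{path}: medium config needs 'pH' and 'totals' keys")
    totals = {k: parse_concentration(v) for k, v in doc["totals"].items()}
    return PhysiologicalMedium(totals, float(doc["pH"]))


def physiological_medium(calcium: bool = False, zinc: bool = False) -> PhysiologicalMedium:
    """The standard blood-plasma-like background at pH 7.4.

    Phosphates 1.1 mM, carbonates 25 mM, oxalates 9.2 uM, lactates 1.5 mM,
    citrates 160 uM; optionally calcium 1.1 mM and/or zinc 15 uM.
    """
    totals = dict(PHYSIOLOGICAL_TOTALS)
    if calcium:
        totals["Ca"] = CALCIUM_TOTAL
    if zinc:
        totals["Zn"] = ZINC_TOTAL
    return PhysiologicalMedium(totals, PHYSIOLOGICAL_PH)


def _side_reaction_coefficient(
    table: ThermoTable, component: str, pH: float, sign: int
) -> float:
    """alpha_X(H) = 1 + sum 10^(log beta(H_n X) - n*pH) over pure X/H species.

    ``sign=+1`` selects protonated species (ligand basicity), ``sign=-1``
    hydroxide species of a metal (negative proton stoichiometry).
    """
    proton = table.proton
    alpha = 1.0
    for s in table.species:
        st = dict(s.stoichiometry)
        n_h = st.pop(proton, 0)
        if st == {component: 1} and n_h * sign > 0:
            alpha += 10.0 ** (s.log_beta - n_h * pH)
    return alpha


def conditional_stability_constant(
    table: ThermoTable, metal: str, chelator: str, pH: float
) -> float:
    """log10 of the pH-conditional stability constant of the 1:1 complex.

    ``log K_cond = log beta(ML) - log alpha_L(H) - log alpha_M(OH)`` where the
    ligand side-reaction coefficient discounts protonation and the metal one
    discounts hydroxide species present in the table.
    """
    table.component(metal)
    table.component(chelator)
    ml = None
    for s in table.species:
        if dict(s.stoichiometry) == {metal: 1, chelator: 1}:
            ml = s
            break
    if ml is None:
        raise LookupError(f"no 1:1 {metal}-{chelator} species in table")
    alpha_l = _side_reaction_coefficient(table, chelator, pH, sign=+1)
    alpha_m = _side_reaction_coefficient(table, metal, pH, sign=-1)
    return ml.log_beta - math.log10(alpha_l) - math.log10(alpha_m)


def assemble_system(
    table: ThermoTable,
    medium: PhysiologicalMedium,
    extra_totals: Mapping[str, float] | None = None,
) -> SpeciationProblem:
    """Build the speciation problem for a medium plus optional extra totals.

    The proton is handled as a fixed free concentration (``10**-pH``); every
    other component with a strictly positive total becomes an unknown, and a
    species enters the problem only if all of its non-proton components are
    present (the equilibria "reachable" from the supplied totals).
    """
    totals: dict[str, float] = dict(medium.totals)
    for name, conc in (extra_totals or {}).items():
        totals[name] = totals.get(name, 0.0) + float(conc)
    proton = table.proton
    declared = {c.name for c in table.components}
    for name in totals:
        if name not in declared:
            raise ValidationError(f"total given for undeclared component {name!r}")
        if name == proton:
            raise ValidationError("proton total is set through pH, not totals")
    active = [n for n, t in totals.items() if t > 0]
    # preserve table declaration order for determinism
    active = [c.name for c in table.components if c.name in active]
    avail = set(active) | {proton}
    kept = [
        s
        for s in table.species
        if all(name in avail for name in s.stoichiometry)
    ]
    return SpeciationProblem(
        components=active,
        totals={n: totals[n] for n in active},
        fixed={proton: 10.0 ** (-medium.pH)},
        species=kept,
        table=table,
    )


def count_equilibria(problem: SpeciationProblem) -> int:
    """Number of formation equilibria in the assembled problem."""
    return len(problem.species)
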