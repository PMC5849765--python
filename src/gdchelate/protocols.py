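"""Simulation protocols: dilution scans, release thresholds, chelator ranking,
and transmetallation competition.

The central experiment is a co-dilution: total Gd and the synthetic chelator
are lowered together (1:1 mol/mol by default) at constant pH and constant
endogenous-ligand totals, mimicking progressive clearance of a contrast agent
from blood plasma.  Below some total-metal concentration the chelator can no
longer compete with the endogenous pool and the metal is released; the 50%
crossing of the bound-fraction curve is the *release threshold*, and the
thresholds of different chelators rank their effective in-vivo stability.
Transmetallation scans repeat the protocol with a constant pool of a
competing metal (Ca2+ or Zn2+) that can displace Gd3+ from the chelator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .solver import solve_equilibrium, bound_fraction
from .thermo import (
    CALCIUM_TOTAL,
    ZINC_TOTAL,
    PhysiologicalMedium,
    ThermoTable,
    assemble_system,
)

__all__ = [
    "GridSpec",
    "DilutionScan",
    "ReleaseThreshold",
    "ScanError",
    "dilution_scan",
    "transmetallation_scan",
    "release_threshold",
    "chelator_ranking",
    "format_ranking",
]

#: tie window (log10 units) inside which two release thresholds are reported
#: as indistinguishable ("=") in a ranking; ~ a factor of two.
TIE_LOG_WINDOW = 0.3


class ScanError(RuntimeError):
    """A scan point failed to converge; carries the failing concentration."""


@dataclass(frozen=True)
class GridSpec:
    """Descending log-spaced total-Gd grid (mol/L)."""

    start: float = 1e-3
    stop: float = 1e-15
    points_per_decade: int = 10

    def concentrations(self) -> np.ndarray:
        decades = math.log10(self.start) - math.log10(self.stop)
        n = int(round(decades * self.points_per_decade)) + 1
        grid = np.logspace(math.log10(self.start), math.log10(self.stop), n)
        if not np.all(np.diff(grid) < 0):
            raise ValueError("grid must be strictly decreasing")
        return grid


@dataclass
class DilutionScan:
    chelator: str
    grid: np.ndarray
    bound_fractions: np.ndarray
    medium: dict[str, float]
    pH: float
    ratio: float = 1.0
    competitor_totals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) < 0):
            raise ValueError("scan grid must be strictly decreasing")
        bf = self.bound_fractions
        if np.any(bf < -1e-12) or np.any(bf > 1 + 1e-9):
            raise ValueError("bound fractions must lie in [0, 1]")


@dataclass(frozen=True)
class ReleaseThreshold:
    chelator: str
    threshold: float
    crossing_found: bool
    medium: tuple = ()
    grid_range: tuple[float, float] = (0.0, 0.0)


def _medium_key(scan: DilutionScan) -> tuple:
    return (
        tuple(sorted(scan.medium.items())),
        scan.pH,
        tuple(sorted(scan.competitor_totals.items())),
        float(scan.grid[0]),
        float(scan.grid[-1]),
        len(scan.grid),
    )


def dilution_scan(
    table: ThermoTable,
    medium: PhysiologicalMedium,
    chelator: str,
    grid: GridSpec | Sequence[float] | None = None,
    metal: str = "Gd",
    ratio: float = 1.0,
    competitor_totals: Mapping[str, float] | None = None,
    tolerance: float = 1e-12,
) -> DilutionScan:
    """Co-dilute metal and chelator against the constant medium.

    One converged speciation solve per grid point, warm-started from the
    previous point (continuation); any non-converged point aborts the scan
    with the failing total concentration reported.
    """
    table.component(chelator)
    table.component(metal)
    conc = (grid.concentrations() if isinstance(grid, GridSpec)
            else GridSpec().concentrations() if grid is None
            else np.asarray(grid, dtype=float))
    competitor_totals = {k: float(v) for k, v in
                         (competitor_totals or {}).items() if v > 0}
    fractions = np.empty_like(conc)
    warm: Mapping[str, float] | None = None
    for k, total_metal in enumerate(conc):
        extra = {metal: total_metal, chelator: ratio * total_metal}
        extra.update(competitor_totals)
        problem = assemble_system(table, medium, extra)
        result = solve_equilibrium(problem, tolerance=tolerance,
                                   initial_free=warm)
        if not result.converged:
            raise ScanError(
                f"{chelator}: no convergence at total {metal} = "
                f"{total_metal:.3e} M (residual {result.residual:.2e})"
            )
        fractions[k] = bound_fraction(result, metal, chelator)
        warm = result.free
    return DilutionScan(
        chelator=chelator,
        grid=conc,
        bound_fractions=np.clip(fractions, 0.0, 1.0),
        medium=dict(medium.totals),
        pH=medium.pH,
        ratio=ratio,
        competitor_totals=competitor_totals,
    )


#: default competitor pools: physiological calcium and zinc totals (mol/L)
COMPETITOR_DEFAULTS = {"Ca": CALCIUM_TOTAL, "Zn": ZINC_TOTAL}


def transmetallation_scan(
    table: ThermoTable,
    medium: PhysiologicalMedium,
    chelator: str,
    competitor: str,
    competitor_total: float | None = None,
    grid: GridSpec | Sequence[float] | None = None,
    **kwargs,
) -> DilutionScan:
    """Dilution scan with a constant competing-metal pool (Ca2+ or Zn2+).

    Requires the competitor's complex with the chelator to be present in the
    table; a zero competitor total reduces bit-identically to the plain
    dilution scan.
    """
    table.component(competitor)
    if competitor_total is None:
        competitor_total = COMPETITOR_DEFAULTS.get(competitor)
        if competitor_total is None:
            raise ValueError(
                f"no default pool for competitor {competitor!r}; "
                "pass competitor_total"
            )
    if competitor_total > 0:
        has_complex = any(
            s.coeff(competitor) > 0 and s.coeff(chelator) > 0
            for s in table.species
        )
        if not has_complex:
            raise LookupError(
                f"table has no {competitor}-{chelator} species; "
                "transmetallation cannot be simulated"
            )
    return dilution_scan(
        table, medium, chelator, grid=grid,
        competitor_totals={competitor: competitor_total}, **kwargs,
    )


def _monotonized(bf: np.ndarray) -> np.ndarray:
    # tolerate sub-1e-9 numerical ripple; enforce non-increasing shape
    return np.minimum.accumulate(bf)


def release_threshold(scan: DilutionScan, level: float = 0.5) -> ReleaseThreshold:
    """Total-metal concentration at which the bound fraction crosses ``level``.

    Located by log-linear interpolation between the bracketing grid points of
    the (monotonized) scan.  Without a crossing, ``crossing_found`` is False
    and the threshold is reported at the grid bound the curve sits against.
    """
    bf = _monotonized(scan.bound_fractions)
    grid_range = (float(scan.grid[-1]), float(scan.grid[0]))
    key = _medium_key(scan)
    if bf[0] < level:
        return ReleaseThreshold(scan.chelator, float(scan.grid[0]), False,
                                key, grid_range)
    below = np.nonzero(bf < level)[0]
    if below.size == 0:
        return ReleaseThreshold(scan.chelator, float(scan.grid[-1]), False,
                                key, grid_range)
    i = int(below[0])
    f_hi, f_lo = bf[i - 1], bf[i]
    lg_hi, lg_lo = math.log10(scan.grid[i - 1]), math.log10(scan.grid[i])
    frac = (level - f_hi) / (f_lo - f_hi)
    return ReleaseThreshold(
        scan.chelator, 10.0 ** (lg_hi + frac * (lg_lo - lg_hi)), True,
        key, grid_range,
    )


def chelator_ranking(
    thresholds: Sequence[ReleaseThreshold],
    tie_log_window: float = TIE_LOG_WINDOW,
) -> list[list[str]]:
    """Order chelators weakest to strongest by release threshold.

    A higher threshold means the chelator lets go of the metal at a higher
    total concentration (weaker under dilution).  Thresholds within
    ``tie_log_window`` log units are grouped as ties.  All scans must come
    from the same medium and grid.
    """
    if not thresholds:
        raise ValueError("no thresholds given")
    keys = {t.medium for t in thresholds}
    if len(keys) > 1:
        raise ValueError("thresholds computed on different media/grids")
    ordered = sorted(thresholds, key=lambda t: -t.threshold)
    groups: list[list[str]] = [[ordered[0].chelator]]
    anchor = math.log10(ordered[0].threshold)
    for t in ordered[1:]:
        lg = math.log10(t.threshold)
        if anchor - lg <= tie_log_window:
            groups[-1].append(t.chelator)
        else:
            groups.append([t.chelator])
            anchor = lg
    return groups


def format_ranking(groups: Sequence[Sequence[str]]) -> str:
    """Render tie groups as e.g. ``EDTA = DTPA-BMA < DTPA = DOTA < HOPO``."""
    return " < ".join(" = ".join(g) for g in groups)
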