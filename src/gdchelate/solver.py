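"""Multi-component equilibrium speciation by damped Newton iteration.

Given total concentrations ``T_j`` for the free components and cumulative
formation constants ``beta_i`` for the species, the solver finds free
concentrations ``x_j`` satisfying the mass balances

    T_j = x_j + sum_i nu_ij * c_i,     c_i = 10**log_beta_i * prod_k x_k**nu_ik

with the proton held at a fixed free concentration (``10**-pH``).  The solve
runs in log space (variables ``ln x_j``) with an analytic Jacobian and damped
Newton steps, which keeps concentrations positive across the >12 decades
spanned by the dilution protocols.  A short fractional-correction warm-up
(the classical HALTAFALL-style update) precedes Newton so that cold starts
from ``x_j = T_j/2`` converge even for constants of order 10**24.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .thermo import EquilibriumSpecies, ThermoTable

__all__ = [
    "SpeciationProblem",
    "SpeciationResult",
    "NonConvergedError",
    "solve_equilibrium",
    "species_distribution",
    "bound_fraction",
]

_LN10 = np.log(10.0)
_EXP_CAP = 700.0  # exp argument cap; keeps intermediates finite


class NonConvergedError(RuntimeError):
    """Raised by consumers that require a converged result."""


@dataclass
class SpeciationProblem:
    """Totals plus fixed-free conditions against a thermodynamic table.

    ``components`` are the unknown free components (the proton and any other
    fixed component live in ``fixed``); every species must be expressible in
    ``components`` + ``fixed``.
    """

    components: Sequence[str]
    totals: Mapping[str, float]
    fixed: Mapping[str, float]
    species: Sequence["EquilibriumSpecies"]
    table: "ThermoTable | None" = None

    def __post_init__(self) -> None:
        if not self.components and not self.fixed:
            raise ValueError("problem needs at least one component")
        for name in self.components:
            t = self.totals.get(name)
            if t is None or not np.isfinite(t) or t < 0:
                raise ValueError(f"component {name!r} needs a finite total >= 0")


@dataclass
class SpeciationResult:
    free: dict[str, float]
    species_conc: dict[str, float]
    converged: bool
    residual: float
    iterations: int
    problem: SpeciationProblem = field(repr=False)

    def require_converged(self) -> "SpeciationResult":
        if not self.converged:
            raise NonConvergedError(
                f"speciation did not converge (residual {self.residual:.3e} "
                f"after {self.iterations} iterations)"
            )
        return self


def _build_matrices(problem: SpeciationProblem):
    comps = list(problem.components)
    idx = {n: j for j, n in enumerate(comps)}
    n_sp = len(problem.species)
    nu = np.zeros((n_sp, len(comps)))
    offset = np.empty(n_sp)
    for i, s in enumerate(problem.species):
        off = s.log_beta * _LN10
        for name, v in s.stoichiometry.items():
            if name in idx:
                nu[i, idx[name]] = v
            else:
                off += v * np.log(problem.fixed[name])
        offset[i] = off
    return comps, nu, offset


def _residual(t, nu, offset, totals):
    """Relative mass-balance residual vector and species concentrations."""
    logc = offset + nu @ t
    c = np.exp(np.minimum(logc, _EXP_CAP))
    recon = np.exp(t) + nu.T @ c
    return (recon - totals) / totals, c


def solve_equilibrium(
    problem: SpeciationProblem,
    tolerance: float = 1e-12,
    max_iter: int = 200,
    initial_free: Mapping[str, float] | None = None,
) -> SpeciationResult:
    """Solve the mass-action/mass-balance system.

    Returns a :class:`SpeciationResult`; non-convergence is reported through
    ``converged=False`` (never silently).  ``initial_free`` warm-starts the
    iteration, e.g. from the previous point of a dilution scan.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    comps, nu, offset = _build_matrices(problem)
    totals = np.array([problem.totals[n] for n in comps], dtype=float)

    if len(comps) == 0:
        # everything fixed; species follow directly
        c = np.exp(np.minimum(offset, _EXP_CAP))
        return SpeciationResult(
            free={}, species_conc={s.label: ci for s, ci in
                                   zip(problem.species, c)},
            converged=True, residual=0.0, iterations=0, problem=problem,
        )

    if initial_free:
        x0 = np.array([initial_free.get(n, problem.totals[n] / 2.0)
                       for n in comps])
        x0 = np.where(x0 > 0, x0, totals / 2.0)
    else:
        x0 = totals / 2.0
    t = np.log(x0)

    n_iter = 0
    with np.errstate(over="ignore", invalid="ignore"):
        f, _ = _residual(t, nu, offset, totals)

        # warm-up: multiplicative mass-balance corrections, robust far from
        # the root (and the fallback whenever a Newton step is rejected)
        def multiplicative(t, f, power=0.5):
            # half power keeps the update convergent for nu up to 2
            logc = offset + nu @ t
            c = np.exp(np.minimum(logc, _EXP_CAP))
            recon = np.exp(np.minimum(t, _EXP_CAP)) + nu.T @ c
            ratio = np.clip(totals / recon, 1e-6, 1e6)
            t = np.clip(t + power * np.log(ratio), -745.0, _EXP_CAP)
            return t, _residual(t, nu, offset, totals)[0]

        for _ in range(min(120, max_iter)):
            if np.max(np.abs(f)) < 1.0 or n_iter >= max_iter:
                break
            t, f = multiplicative(t, f)
            n_iter += 1

        norm2 = float(np.linalg.norm(f))
        while n_iter < max_iter and np.max(np.abs(f)) > tolerance:
            logc = offset + nu @ t
            c = np.exp(np.minimum(logc, _EXP_CAP))
            x = np.exp(t)
            jac = (np.diag(x) + nu.T @ (c[:, None] * nu)) / totals[:, None]
            try:
                step = np.linalg.solve(jac, -f)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(jac, -f, rcond=None)[0]
            accepted = False
            if np.all(np.isfinite(step)):
                # damped line search on the 2-norm of the residual
                alpha = 1.0
                for _ in range(30):
                    t_new = np.clip(t + alpha * step, -745.0, _EXP_CAP)
                    f_new, _ = _residual(t_new, nu, offset, totals)
                    n2 = float(np.linalg.norm(f_new))
                    if np.all(np.isfinite(f_new)) and n2 < norm2:
                        t, f, norm2 = t_new, f_new, n2
                        accepted = True
                        break
                    alpha *= 0.5
            if not accepted:
                # half-power multiplicative rescue step
                t, f = multiplicative(t, f, power=0.5)
                norm2 = float(np.linalg.norm(f))
            n_iter += 1

        best_norm = float(np.max(np.abs(f)))
    converged = bool(best_norm <= tolerance)
    logc = offset + nu @ t
    c = np.exp(np.minimum(logc, _EXP_CAP))
    free = {n: float(np.exp(t[j])) for j, n in enumerate(comps)}
    free.update({n: float(v) for n, v in problem.fixed.items()})
    return SpeciationResult(
        free=free,
        species_conc={s.label: float(ci) for s, ci in zip(problem.species, c)},
        converged=converged,
        residual=float(best_norm),
        iterations=n_iter,
        problem=problem,
    )


def species_distribution(result: SpeciationResult, group_by: str) -> dict[str, float]:
    """Percent of a component's total held in each species (free ion included).

    Stoichiometric multiplicity counts: a bis complex holding two equivalents
    of ``group_by`` contributes twice its molar concentration.
    """
    result.require_converged()
    problem = result.problem
    if group_by in problem.fixed:
        raise ValueError(f"{group_by!r} is a fixed component; no total to distribute")
    total = problem.totals.get(group_by)
    if total is None:
        raise LookupError(f"component {group_by!r} not in problem")
    if total <= 0:
        raise ValueError(f"component {group_by!r} has zero total")
    out: dict[str, float] = {}
    for s in problem.species:
        v = s.coeff(group_by)
        if v > 0:
            out[s.label] = 100.0 * v * result.species_conc[s.label] / total
    out[f"{group_by} (free)"] = 100.0 * result.free[group_by] / total
    return out


def bound_fraction(result: SpeciationResult, metal: str, chelator: str) -> float:
    """Fraction of the metal total held in species containing the chelator."""
    result.require_converged()
    problem = result.problem
    total = problem.totals.get(metal)
    if total is None or total <= 0:
        raise ValueError(f"metal {metal!r} absent or zero total")
    bound = 0.0
    for s in problem.species:
        vm = s.coeff(metal)
        if vm > 0 and s.coeff(chelator) > 0:
            bound += vm * result.species_conc[s.label]
    return bound / total
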