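"""Independent oracles for solver verification.

These deliberately avoid the package's Newton solver: closed forms for 1:1
binding and brute-force residual-minimizing grid searches in log space.
"""

from __future__ import annotations

import numpy as np


def closed_form_1to1(log_k: float, total_m: float, total_l: float) -> float:
    """Exact [ML] for M + L <=> ML with equal or unequal totals.

    Solves the quadratic K*(Tm - c)*(Tl - c) = c for the complex
    concentration c on the physical branch.
    """
    k = 10.0**log_k
    b = total_m + total_l + 1.0 / k
    c = (b - np.sqrt(b * b - 4.0 * total_m * total_l)) / 2.0
    return float(c)


def grid_search_free(
    nu: np.ndarray,
    log_beta: np.ndarray,
    totals: np.ndarray,
    n_points: int = 100,
    decades_down: float = 30.0,
    refine: int = 2,
) -> np.ndarray:
    """Free concentrations minimizing the total squared relative residual.

    Exhaustive search over a log10 grid (``n_points`` per dimension, up to 3
    components), optionally refined by zooming twice around the coarse
    argmin.  Returns log10 of the free concentrations.
    """
    n_comp = totals.size
    assert 1 <= n_comp <= 3
    lo = np.log10(totals) - decades_down
    hi = np.log10(totals)

    best = None
    for _ in range(refine + 1):
        axes = [np.linspace(lo[j], hi[j], n_points) for j in range(n_comp)]
        mesh = np.meshgrid(*axes, indexing="ij")
        logx = np.stack([m.ravel() for m in mesh], axis=1)  # (P, n_comp)
        # residual for every grid point
        logc = log_beta[None, :] + logx @ nu.T  # (P, n_species)
        c = 10.0 ** np.minimum(logc, 300.0)
        recon = 10.0**logx + c @ nu  # (P, n_comp)
        resid = (((recon - totals) / totals) ** 2).sum(axis=1)
        best = logx[int(np.argmin(resid))]
        step = np.array([ax[1] - ax[0] if len(ax) > 1 else 0.0 for ax in axes])
        lo = best - 1.5 * step
        hi = np.minimum(best + 1.5 * step, np.log10(totals))
    return best


def grid_oracle_for_problem(problem, **kwargs) -> dict[str, float]:
    """Run :func:`grid_search_free` on a SpeciationProblem (no fixed-component
    involvement besides species offsets)."""
    comps = list(problem.components)
    nu = np.zeros((len(problem.species), len(comps)))
    log_beta = np.empty(len(problem.species))
    for i, s in enumerate(problem.species):
        off = s.log_beta
        for name, v in s.stoichiometry.items():
            if name in comps:
                nu[i, comps.index(name)] = v
            else:
                off += v * np.log10(problem.fixed[name])
        log_beta[i] = off
    totals = np.array([problem.totals[n] for n in comps])
    logx = grid_search_free(nu, log_beta, totals, **kwargs)
    return dict(zip(comps, logx))
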