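"""Mean-field (deterministic) receptor-ligand kinetics.

The moment-closure limit of the birth-death binding process gives a Riccati
equation for z(t), the mean number of TCR-pMHC complexes per T cell:

    dz/dt = f(z) = a (z - z1)(z - z2),      z(0) = 0,

where a = k_plus * N_c = k_on * N_c / (V N_A) and z1 < z2 are the roots of
the stationary quadratic

    f(z) = a [ z^2 - (N_R + L + K_d V N_A / N_c) z + N_R L ],

with L = rho V N_A / N_c the initial number of free ligands per T cell.  The
closure sets the second moment w(t) = z(t)^2; it is exact in the
large-copy-number limit, and the Gillespie ensemble mean converges to z(t)
as copy numbers grow.

z(t) rises monotonically from 0 to the smaller root z_eq = z1 (the stable
equilibrium; the larger root is unreachable from below).  The fraction of
unbound receptors at equilibrium is f_eq = 1 - z_eq/N_R, which reproduces
dose-response binding curves, and the *equilibrium criterion* time

    T_N : z(T_N) = N

is finite only when z_eq > N; weaker ligands or low doses make the threshold
unreachable, which this module returns as ``inf`` rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .params import AVOGADRO, BindingParams, CellContext

__all__ = [
    "MeanFieldSolution",
    "mean_field_rhs",
    "solve_mean_field",
    "time_to_N",
    "dose_response",
    "UNREACHABLE",
]

#: Serialized representation of an unreachable equilibrium-criterion time.
UNREACHABLE = math.inf


@dataclass(frozen=True)
class MeanFieldSolution:
    """Stationary structure of the mean-field kinetics for one ligand.

    ``z1 <= z2`` are the roots of the stationary quadratic (complexes per
    cell); ``z_eq = z1`` is the stable equilibrium reached from z(0) = 0 and
    ``f_eq = 1 - z_eq/N_R`` the equilibrium fraction of unbound receptors.
    ``timescale`` is the exponential relaxation rate a (z2 - z1) in 1/s.
    """

    z1: float
    z2: float
    z_eq: float
    f_eq: float
    timescale: float
    _a: float
    _N_R: float

    def z_of_t(self, t):
        """Closed-form trajectory z(t) from z(0) = 0, vectorized over t.

        z(t) = z1 z2 (1 - E) / (z2 - z1 E) with E = exp(-a (z2 - z1) t);
        at a double root z1 = z2 = r it degenerates to the algebraic decay
        z(t) = a r^2 t / (1 + a r t).
        """
        t = np.asarray(t, dtype=float)
        z1, z2, a = self.z1, self.z2, self._a
        if z2 - z1 < 1e-12 * z2:
            r = 0.5 * (z1 + z2)
            return a * r * r * t / (1.0 + a * r * t)
        E = np.exp(-self.timescale * t)
        return z1 * z2 * (1.0 - E) / (z2 - z1 * E)

    def time_to(self, N: float) -> float:
        """First time z(t) = N, or ``inf`` if N >= z_eq (never reached).

        Inverting the closed form gives
        T_N = ln[ z1 (z2 - N) / (z2 (z1 - N)) ] / (a (z2 - z1)).
        """
        if N <= 0:
            return 0.0
        z1, z2, a = self.z1, self.z2, self._a
        if N >= self.z_eq:
            return UNREACHABLE
        if z2 - z1 < 1e-12 * z2:
            r = 0.5 * (z1 + z2)
            return N / (a * r * (r - N))
        return math.log(z1 * (z2 - N) / (z2 * (z1 - N))) / self.timescale


def _per_cell_ligand(context: CellContext) -> float:
    """Initial free ligands per T cell, L = rho V N_A / N_c."""
    return context.rho * context.volume * AVOGADRO / context.N_c


def mean_field_rhs(z: float, k_on: float, k_off: float, rho: float,
                   N_R: float, *, volume: float, N_c: float = 1.0) -> float:
    """dz/dt at complex count z: bilinear depletion of receptor and ligand.

    f(z) = (k_on N_c / (V N_A)) (N_R - z)(L - z) - k_off z with
    L = rho V N_A / N_c.
    """
    if not 0 <= z <= N_R:
        raise ValueError(f"z must lie in [0, N_R], got {z!r}")
    a = k_on * N_c / (volume * AVOGADRO)
    L = rho * volume * AVOGADRO / N_c
    return a * (N_R - z) * (L - z) - k_off * z


def solve_mean_field(context: CellContext,
                     params: BindingParams) -> MeanFieldSolution:
    """Roots, stable equilibrium and closed-form trajectory for one ligand.

    The stationary quadratic z^2 - S z + P = 0 has S = N_R + L + K V N_A/N_c
    and P = N_R L with K = k_minus/k_on.  Both roots are real and positive;
    the smaller one is the stable state reached from z(0) = 0 (checked:
    f'(z1) = a (z1 - z2) < 0).  Roots are computed with the numerically
    stable product formula to avoid cancellation when S^2 >> 4P.
    """
    N_R = context.N_R
    L = _per_cell_ligand(context)
    K_counts = (params.k_minus / params.k_on) * context.volume * AVOGADRO / context.N_c
    # k_on and k_minus are the authoritative columns; the per-pair rate is
    # derived from k_on and the context volume rather than the (rounded)
    # printed k_plus, so the trajectory is exactly consistent with the rhs
    a = params.k_on * context.N_c / (context.volume * AVOGADRO)

    S = N_R + L + K_counts
    P = N_R * L
    disc = S * S - 4.0 * P
    # disc >= K_counts^2 + 2 K_counts (N_R + L) >= 0 algebraically; clamp
    # tiny negative round-off
    disc = max(disc, 0.0)
    root = math.sqrt(disc)
    z2 = 0.5 * (S + root)
    z1 = P / z2 if z2 > 0 else 0.0
    z_eq = z1
    return MeanFieldSolution(
        z1=z1, z2=z2, z_eq=z_eq,
        f_eq=1.0 - z_eq / N_R,
        timescale=a * (z2 - z1),
        _a=a, _N_R=N_R,
    )


def time_to_N(N: float, context: CellContext,
              params: BindingParams) -> float:
    """Equilibrium-criterion time T_N with z(T_N) = N complexes per cell.

    Returns ``inf`` when the equilibrium occupancy z_eq does not exceed N,
    i.e. the cell never accumulates N complexes under mean-field kinetics.
    """
    if N < 0:
        raise ValueError("N must be >= 0")
    return solve_mean_field(context, params).time_to(N)


def dose_response(context: CellContext, params_list: Sequence[BindingParams],
                  rho_grid: Sequence[float], N: float = 10) -> pd.DataFrame:
    """Equilibrium occupancy and T_N over a ligand-concentration grid.

    Returns a long-format frame with columns ``ligand, cell_type, rho_M,
    f_eq, T_N_s``; T_N_s is ``inf`` where the threshold is unreachable.
    ``context.rho`` is ignored in favour of the grid.
    """
    rho_grid = list(rho_grid)
    if any(r <= 0 for r in rho_grid):
        raise ValueError("rho grid must be positive")
    if sorted(rho_grid) != rho_grid:
        raise ValueError("rho grid must be sorted ascending")
    rows = []
    for p in params_list:
        for rho in rho_grid:
            ctx = CellContext(N_R=context.N_R, N_c=context.N_c,
                              volume=context.volume, rho=rho)
            sol = solve_mean_field(ctx, p)
            rows.append({
                "ligand": p.ligand,
                "cell_type": p.cell_type,
                "rho_M": rho,
                "f_eq": sol.f_eq,
                "T_N_s": sol.time_to(N),
            })
    return pd.DataFrame(rows)
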