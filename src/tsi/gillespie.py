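"""Exact stochastic simulation of receptor-ligand binding (Gillespie / SSA).

The number of engaged receptors is a birth-death process on
{0, ..., min(M_R, M_L)} with propensities

    lambda_n = k_plus (M_R - n)(M_L - n)      (binding)
    mu_n     = k_minus n                      (unbinding)

starting from n = 0 (all receptors free, M_L free ligands).  Each realization
is generated event-by-event; because bound complexes are exchangeable and
dissociation is memoryless, the complex that unbinds at an unbinding event is
a uniform draw among those currently bound, which yields exact per-binding
durations without tracking receptor identity.

A binding is *productive* when it remains intact for at least the dwell time
tau; the same receptor re-binding later counts as a new event (serial
engagement).  The first-passage time of the stochastic response criterion is

    FPT = (start time of the N-th productive binding, ordered by start) + tau,

the first instant at which N engagements have each lasted tau.  A realization
ends as soon as the criterion is certain to be satisfied; bindings still open
at that moment are irrelevant to the result.

By default simulations are per cell: M_R = N_R and M_L = rho V N_A / N_c
free ligands available to that cell.  A bulk mode (M_R = N_c N_R, all
ligand shared) is available via ``per_cell=False``.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .mtsi import Criterion
from .params import BindingParams, CellContext

__all__ = [
    "Rates",
    "Trajectory",
    "FPTEnsemble",
    "NotReachedError",
    "propensities",
    "rates_from_params",
    "simulate_fpt",
    "simulate_trajectory",
    "estimate_mtsi",
]

#: Default realization caps: events per realization, simulated seconds.
DEFAULT_MAX_EVENTS = 10**8
DEFAULT_MAX_TIME = 1e9


class NotReachedError(RuntimeError):
    """The realization hit its event/time cap before satisfying the criterion."""


@dataclass(frozen=True)
class Rates:
    """Raw birth-death parameters: per-pair rates and copy numbers."""

    k_plus: float   # s^-1 per receptor-ligand pair
    k_minus: float  # s^-1
    M_R: float      # receptor copies
    M_L: float      # ligand copies

    def __post_init__(self) -> None:
        if not self.k_plus > 0:
            raise ValueError("k_plus must be positive")
        if self.k_minus < 0:
            raise ValueError("k_minus must be >= 0")
        if self.M_R < 1 or self.M_L < 1:
            raise ValueError("M_R and M_L must each be >= 1")

    @property
    def n_max(self) -> int:
        return int(min(self.M_R, self.M_L))


@dataclass
class Trajectory:
    """Event log of one realization.

    ``events`` holds (time, kind) pairs with kind "bind"/"unbind";
    ``bindings`` holds (start, end) pairs with ``end = inf`` for bindings
    still open when the realization stopped.
    """

    events: list[tuple[float, str]] = field(default_factory=list)
    bindings: list[tuple[float, float]] = field(default_factory=list)

    def n_bound(self, t: float) -> int:
        """Number of complexes bound at time t (from the binding log)."""
        return sum(1 for s, e in self.bindings if s <= t < e)


def propensities(n: int, k_plus: float, k_minus: float,
                 M_R: float, M_L: float) -> tuple[float, float]:
    """(lambda_n, mu_n) at state n bound complexes.

    lambda_n = k_plus (M_R - n)(M_L - n): each of the (M_R - n) free
    receptors can pair with each of the (M_L - n) free ligands.
    mu_n = k_minus n.
    """
    if not 0 <= n <= min(M_R, M_L):
        raise ValueError(f"n = {n} outside [0, min(M_R, M_L)]")
    return k_plus * (M_R - n) * (M_L - n), k_minus * n


def rates_from_params(params: BindingParams, context: CellContext,
                      *, per_cell: bool = True) -> Rates:
    """Build birth-death rates from a binding table row and a cell context.

    Per-cell mode (default) simulates one T cell: M_R = N_R receptors and
    an equal share M_L = rho V N_A / N_c of the free ligand.  Bulk mode
    pools every cell: M_R = N_c N_R against all M_L = rho V N_A ligands.
    """
    if per_cell:
        m_r = context.N_R
        m_l = context.M_L / context.N_c
    else:
        m_r = context.M_R
        m_l = context.M_L
    return Rates(k_plus=params.k_plus, k_minus=params.k_minus,
                 M_R=m_r, M_L=m_l)


def _as_rates(params: Union[Rates, BindingParams],
              context: Optional[CellContext],
              per_cell: bool) -> Rates:
    if isinstance(params, Rates):
        return params
    if context is None:
        raise ValueError("a CellContext is required with BindingParams input")
    return rates_from_params(params, context, per_cell=per_cell)


def simulate_fpt(params: Union[Rates, BindingParams],
                 criterion: Criterion,
                 rng: Union[int, np.random.Generator],
                 context: Optional[CellContext] = None,
                 *,
                 per_cell: bool = True,
                 max_events: int = DEFAULT_MAX_EVENTS,
                 max_time: float = DEFAULT_MAX_TIME,
                 trajectory: Optional[Trajectory] = None) -> float:
    """One realization of the stochastic criterion's first-passage time.

    Simulates the birth-death process exactly and returns
    tau + (start of the N-th productive binding).  The realization must run
    past a binding's start by tau before that binding can be classified, so
    simulated time may exceed the returned FPT slightly.

    Parameters
    ----------
    params : Rates or BindingParams (the latter needs ``context``).
    criterion : the (N, tau) response criterion.
    rng : integer seed or a ``numpy.random.Generator``.
    trajectory : optional Trajectory to be filled with the event log.

    Raises
    ------
    NotReachedError
        When ``max_events`` or ``max_time`` is exceeded first.
    """
    rates = _as_rates(params, context, per_cell)
    gen = np.random.default_rng(rng)
    N, tau = criterion.N, criterion.tau
    k_plus, k_minus = rates.k_plus, rates.k_minus
    M_R, M_L = rates.M_R, rates.M_L

    t = 0.0
    bound: list[float] = []       # starts of ALL currently open bindings
    mat_heap: list[float] = []    # starts of open, not-yet-matured bindings
    dead: set = set()             # starts that unbound before maturing (lazy)
    productive: list[float] = []  # confirmed productive starts, in order
    events = 0
    while True:
        n = len(bound)
        lam = k_plus * (M_R - n) * (M_L - n)
        mu = k_minus * n
        total = lam + mu
        if total <= 0:  # absorbing: no ligand/receptor left and nothing bound
            raise NotReachedError(
                f"process absorbed at n = {n} before criterion was met")
        dt = gen.exponential(1.0 / total)
        t_next = t + dt

        # A binding open at t matures (is confirmed productive) at start +
        # tau; maturations up to t_next are certain regardless of the next
        # event, since even an unbind exactly at t_next leaves duration >=
        # tau.  Confirmations therefore happen in increasing start order.
        while mat_heap and mat_heap[0] + tau <= t_next:
            start = heapq.heappop(mat_heap)
            if start in dead:
                dead.discard(start)
                continue
            productive.append(start)
            if len(productive) >= N:
                # N-th productive maturation completes the criterion
                if trajectory is not None:
                    trajectory.bindings.extend(
                        (s, math.inf) for s in sorted(bound))
                return productive[N - 1] + tau

        t = t_next
        if t > max_time:
            raise NotReachedError(f"simulated time exceeded {max_time:g} s")
        events += 1
        if events > max_events:
            raise NotReachedError(f"event count exceeded {max_events:g}")

        if gen.random() * total < lam:
            bound.append(t)
            heapq.heappush(mat_heap, t)
            if trajectory is not None:
                trajectory.events.append((t, "bind"))
        else:
            # memoryless lifetimes: the unbinding complex is a uniform draw
            # among the currently bound (matured ones included)
            idx = int(gen.integers(n))
            start = bound[idx]
            bound[idx] = bound[-1]
            bound.pop()
            if t - start < tau:
                dead.add(start)  # unproductive; skip when popped from heap
            if trajectory is not None:
                trajectory.events.append((t, "unbind"))
                trajectory.bindings.append((start, t))


def simulate_trajectory(params: Union[Rates, BindingParams],
                        criterion: Criterion,
                        rng: Union[int, np.random.Generator],
                        context: Optional[CellContext] = None,
                        **kwargs) -> tuple[float, Trajectory]:
    """Like :func:`simulate_fpt` but also returns the event log."""
    traj = Trajectory()
    fpt = simulate_fpt(params, criterion, rng, context,
                       trajectory=traj, **kwargs)
    return fpt, traj


@dataclass(frozen=True)
class FPTEnsemble:
    """Summary of an ensemble of first-passage-time realizations."""

    fpt_samples: np.ndarray
    mean: float
    sd: float
    se: float
    n_realizations: int
    seed: int
    n_not_reached: int = 0

    @property
    def cv(self) -> float:
        return self.sd / self.mean

    @property
    def variance(self) -> float:
        return self.sd**2


def estimate_mtsi(params: Union[Rates, BindingParams],
                  criterion: Criterion,
                  n_realizations: int,
                  seed: int,
                  context: Optional[CellContext] = None,
                  **kwargs) -> FPTEnsemble:
    """Monte-Carlo estimate of the mean time to signal initiation.

    Each realization runs on an independent child stream of the master
    seed, so the ensemble is reproducible and realization-order independent.
    Realizations that hit the event/time caps are dropped from the samples
    and counted in ``n_not_reached``.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations for a standard error")
    streams = np.random.SeedSequence(seed).spawn(n_realizations)
    samples = []
    not_reached = 0
    for ss in streams:
        try:
            samples.append(simulate_fpt(params, criterion,
                                        np.random.default_rng(ss),
                                        context, **kwargs))
        except NotReachedError:
            not_reached += 1
    arr = np.asarray(samples)
    if arr.size < 2:
        raise NotReachedError(
            f"only {arr.size} of {n_realizations} realizations reached the "
            f"criterion; cannot summarize")
    sd = float(arr.std(ddof=1))
    return FPTEnsemble(
        fpt_samples=arr,
        mean=float(arr.mean()),
        sd=sd,
        se=sd / math.sqrt(arr.size),
        n_realizations=n_realizations,
        seed=seed,
        n_not_reached=not_reached,
    )
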