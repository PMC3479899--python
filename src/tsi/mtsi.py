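"""Closed-form statistics of the first time to signal initiation (TSI).

The stochastic T cell response criterion asks for the first time at which
``N`` receptor-ligand engagements have each lasted at least a dwell time
``tau`` (such engagements are called *productive*).  When the number of bound
receptors stays far below both the receptor count and the free-ligand count,
binding events form a Poisson process with propensity ``k_on * rho * N_R``
(events per second), each newly formed complex survives past ``tau`` with
probability ``exp(-tau * k_off)`` independently, and the first-passage time is

    TSI(N, tau) = tau + t_{N'},

where ``N' = N * exp(tau * k_off)`` is the mean number of binding events
needed before the N-th productive one, and ``t_{N'}`` is a sum of N'
exponential waiting times of mean ``1/(k_on rho N_R)``.  Hence

    mean     T(N, tau) = tau + N e^{tau k_off} / (k_on rho N_R)
    variance Var(N, tau) = N e^{tau k_off} / (k_on rho N_R)^2
    CV       = sqrt(Var) / T

The same expressions hold for membrane-anchored (2-D) binding with the
propensity ``k_on^{2D} M_R M_L A_c`` built from surface densities and the
contact area; see :func:`propensity_2d`.

A finite-receptor correction (:func:`mtsi_corrected`) drops the assumption
that bound receptors are a negligible fraction of ``N_R`` while still
neglecting ligand depletion, and solves the implicit equation
``C(T - tau) = N'`` where ``C(t)`` is the exact mean cumulative number of
binding events.

Means larger than ``1e30`` s are reported as ``+inf`` with a warning: they
are physically meaningless magnitudes and expected behaviour for weak
ligands, not errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Criterion",
    "FPTStats",
    "SurfaceContext",
    "UnreachableCriterionError",
    "MEAN_OVERFLOW_S",
    "n_productive",
    "binding_propensity_3d",
    "propensity_2d",
    "mtsi_3d",
    "mtsi_variance_3d",
    "mtsi_cv",
    "mtsi_stats_3d",
    "mtsi_2d",
    "mean_bound_receptors",
    "mean_binding_events",
    "mtsi_corrected",
]

#: Means above this value (seconds) are reported as +inf.
MEAN_OVERFLOW_S = 1e30

_LOG_OVERFLOW = math.log(MEAN_OVERFLOW_S)


class UnreachableCriterionError(ValueError):
    """The response criterion cannot be met under the given kinetics."""


@dataclass(frozen=True)
class Criterion:
    """The response criterion: N productive bindings of dwell >= tau seconds."""

    N: int
    tau: float

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError(f"N must be an integer >= 1, got {self.N!r}")
        if not (self.tau >= 0 and math.isfinite(self.tau)):
            raise ValueError(f"tau must be finite and >= 0, got {self.tau!r}")


@dataclass(frozen=True)
class FPTStats:
    """First-passage-time summary for the stochastic criterion.

    ``n_prime`` is the expected total number of binding events before the
    N-th productive one (real-valued, >= N).
    """

    mean: float      # s
    variance: float  # s^2
    cv: float        # dimensionless
    n_prime: float   # expected binding events


@dataclass(frozen=True)
class SurfaceContext:
    """Membrane-anchored (2-D) binding setting.

    ``M_R`` and ``M_L`` are receptor and ligand number densities on the
    apposed membranes (per unit area), ``A_c`` is the contact area, and
    ``kon2d``/``koff2d`` are the 2-D association and dissociation rates.
    Only the product kon2d * M_R * M_L * A_c (events/s) and koff2d enter the
    first-passage-time statistics, so any self-consistent unit system for
    densities and area is acceptable.
    """

    M_R: float
    M_L: float
    A_c: float
    kon2d: float
    koff2d: float

    def __post_init__(self) -> None:
        for name in ("M_R", "M_L", "A_c", "kon2d", "koff2d"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# building blocks

def n_productive(criterion: Criterion, k_off: float) -> float:
    """Mean number of binding events before the N-th productive one.

    A complex formed at any instant outlasts the dwell time with probability
    ``exp(-tau * k_off)``, independently of every other complex, so on
    average ``N * exp(tau * k_off)`` bindings are needed for N productive
    ones.
    """
    if k_off < 0:
        raise ValueError(f"k_off must be >= 0, got {k_off!r}")
    return criterion.N * math.exp(criterion.tau * k_off)


def binding_propensity_3d(k_on: float, rho: float, N_R: float) -> float:
    """Total binding propensity k_on * rho * N_R (events/s) for one cell."""
    for name, value in (("k_on", k_on), ("rho", rho), ("N_R", N_R)):
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value!r}")
    return k_on * rho * N_R


def propensity_2d(surface: SurfaceContext) -> float:
    """Total 2-D binding propensity kon2d * M_R * M_L * A_c (events/s).

    The grouping treats kon2d as a rate per receptor-ligand density pair per
    unit contact area, so the total pair-formation rate over the contact
    scales with both densities and the contact area.  It is deliberately
    isolated here: any alternative grouping is a one-line change.
    """
    return surface.kon2d * surface.M_R * surface.M_L * surface.A_c


def _stats_from_propensity(criterion: Criterion, k_off: float,
                           propensity: float) -> FPTStats:
    """Mean/variance/CV given a total binding propensity (events/s)."""
    if not propensity > 0:
        raise ValueError(f"binding propensity must be positive, got {propensity!r}")
    if k_off < 0:
        raise ValueError(f"k_off must be >= 0, got {k_off!r}")
    # log-space guard: N' = N exp(tau k_off) overflows long before float64
    log_nprime = math.log(criterion.N) + criterion.tau * k_off
    log_wait = log_nprime - math.log(propensity)
    if log_wait > _LOG_OVERFLOW:
        warnings.warn(
            "mean time to signal initiation exceeds 1e30 s; reporting +inf",
            RuntimeWarning,
            stacklevel=3,
        )
        return FPTStats(mean=math.inf, variance=math.inf, cv=math.nan,
                        n_prime=math.exp(log_nprime))
    n_prime = math.exp(log_nprime)
    wait = n_prime / propensity
    mean = criterion.tau + wait
    variance = n_prime / propensity**2
    return FPTStats(mean=mean, variance=variance,
                    cv=math.sqrt(variance) / mean, n_prime=n_prime)


# ---------------------------------------------------------------------------
# 3-D (soluble ligand) statistics

def mtsi_3d(criterion: Criterion, k_on: float, k_off: float,
            rho: float, N_R: float) -> float:
    """Mean time to signal initiation, tau + N e^{tau k_off}/(k_on rho N_R)."""
    propensity = binding_propensity_3d(k_on, rho, N_R)
    return _stats_from_propensity(criterion, k_off, propensity).mean


def mtsi_variance_3d(criterion: Criterion, k_on: float, k_off: float,
                     rho: float, N_R: float) -> float:
    """Variance of the TSI, N e^{tau k_off}/(k_on rho N_R)^2.

    This is the variance of a sum of N' independent exponential waiting
    times of mean 1/(k_on rho N_R); the dwell-time offset tau is
    deterministic and contributes nothing.
    """
    propensity = binding_propensity_3d(k_on, rho, N_R)
    return _stats_from_propensity(criterion, k_off, propensity).variance


def mtsi_cv(criterion: Criterion, k_on: float, k_off: float,
            rho: float, N_R: float) -> float:
    """Coefficient of variation sqrt(Var)/mean; tends to 0 as N grows."""
    propensity = binding_propensity_3d(k_on, rho, N_R)
    return _stats_from_propensity(criterion, k_off, propensity).cv


def mtsi_stats_3d(criterion: Criterion, k_on: float, k_off: float,
                  rho: float, N_R: float) -> FPTStats:
    """Full first-passage summary (mean, variance, CV, N') in one call."""
    propensity = binding_propensity_3d(k_on, rho, N_R)
    return _stats_from_propensity(criterion, k_off, propensity)


# ---------------------------------------------------------------------------
# 2-D (membrane-anchored) statistics

def mtsi_2d(criterion: Criterion, surface: SurfaceContext) -> FPTStats:
    """TSI statistics for membrane-anchored binding.

    Identical functional form to the 3-D case with the binding propensity
    k_on rho N_R replaced by kon2d * M_R * M_L * A_c and k_off by the 2-D
    off-rate.
    """
    return _stats_from_propensity(criterion, surface.koff2d,
                                  propensity_2d(surface))


# ---------------------------------------------------------------------------
# finite-receptor correction

def mean_bound_receptors(t: float, k_on: float, k_off: float,
                         rho: float, N_R: float) -> float:
    """Mean number of bound receptors B(t) at constant ligand concentration.

    Solves dB/dt = k_on rho (N_R - B) - k_off B with B(0) = 0:

        B(t) = B_eq (1 - exp(-gamma t)),
        gamma = k_on rho + k_off,  B_eq = k_on rho N_R / gamma.
    """
    gamma = k_on * rho + k_off
    b_eq = k_on * rho * N_R / gamma
    return b_eq * -math.expm1(-gamma * t)


def mean_binding_events(t: float, k_on: float, k_off: float,
                        rho: float, N_R: float) -> float:
    """Mean cumulative number of binding events C(t) up to time t.

    New bindings occur at rate k_on rho (N_R - B(t)), so

        C(t) = k_on rho [ (N_R - B_eq) t + B_eq (1 - e^{-gamma t}) / gamma ].

    For k_off > 0 the slope stays positive (receptors recycle) and C grows
    without bound; for k_off = 0 it saturates at N_R.
    """
    gamma = k_on * rho + k_off
    b_eq = k_on * rho * N_R / gamma
    return k_on * rho * ((N_R - b_eq) * t + b_eq * -math.expm1(-gamma * t) / gamma)


def mtsi_corrected(criterion: Criterion, k_on: float, k_off: float,
                   rho: float, N_R: float) -> float:
    """Mean TSI with the finite-receptor correction.

    Solves C(T - tau) = N' for T, where C is the exact mean cumulative
    binding count of :func:`mean_binding_events`.  Reduces to
    :func:`mtsi_3d` when N' << N_R (bound receptors never deplete the free
    pool appreciably).

    Raises
    ------
    UnreachableCriterionError
        If C saturates below N' (possible when k_off = 0 and
        N' > N_R: each receptor can bind at most once).
    """
    propensity = binding_propensity_3d(k_on, rho, N_R)
    if k_off < 0:
        raise ValueError(f"k_off must be >= 0, got {k_off!r}")
    n_prime = n_productive(criterion, k_off)

    if k_off == 0 and n_prime >= N_R:
        raise UnreachableCriterionError(
            f"criterion needs N' = {n_prime:g} binding events but only "
            f"N_R = {N_R:g} receptors can ever bind (k_off = 0)"
        )

    def residual(t: float) -> float:
        return mean_binding_events(t, k_on, k_off, rho, N_R) - n_prime

    # The uncorrected waiting time n_prime/propensity is a lower bound on
    # the corrected one (the binding rate only decreases as receptors fill).
    lo = n_prime / propensity
    hi = lo
    for _ in range(200):
        hi *= 2.0
        if residual(hi) > 0:
            break
    else:
        raise UnreachableCriterionError(
            f"mean binding count saturates below N' = {n_prime:g}"
        )
    if residual(lo) >= 0:
        t_star = lo
    else:
        t_star = brentq(residual, lo, hi, rtol=1e-10)
    return criterion.tau + t_star
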