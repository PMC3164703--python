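"""Fixed points, stability and bistability analysis.

The ODE system is piecewise smooth: the two Heaviside gates of the
Factor-Y loop split state space into at most four smooth regimes.  Within
a regime the algebraic steady-state system is triangular given the
late-time input values -- H, Y, S are explicit functions of M, and Z, D,
T are explicit functions of the rest -- so the whole problem reduces to a
one-dimensional root search for M.  Fixed points are found per regime by
a dense scan plus bisection, checked for regime self-consistency,
deduplicated, and classified by the eigenvalues of a finite-difference
Jacobian evaluated with the gates frozen (the gates are locally constant
away from their boundaries, so this is the correct linearisation).

This reproduces, numerically, the analytic steady-state treatment of the
*sox10*-mutant full model: a stable "off" state with Mitfa at zero and a
stable differentiated "on" state, i.e. bistability, with the thresholds
M*/Y* stabilising the off state against small Mitfa fluctuations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .core import (
    SPECIES,
    Genotype,
    RegulatoryParameters,
    _act,
    _gate,
    _rep,
    mask_params,
    rhs,
)
from .dynamics import integrate

__all__ = [
    "SteadyState",
    "NoSteadyStateError",
    "ConsistencyError",
    "find_steady_states",
    "classify_stability",
    "consistency_check",
    "steady_state_records",
]

#: default solver tolerances (nM/hr, nM)
TOL_RESIDUAL = 1e-10
DEDUPE_DISTANCE = 1e-6
BOUNDARY_EPS = 1e-6


class NoSteadyStateError(RuntimeError):
    """No self-consistent fixed point was found in any gate regime."""


class ConsistencyError(RuntimeError):
    """Integrator and steady-state solver disagree about an attractor."""

    def __init__(self, message: str, start: np.ndarray, end: np.ndarray):
        super().__init__(message)
        self.start = start
        self.end = end


@dataclass(frozen=True)
class SteadyState:
    """A fixed point of one model variant under one genotype."""

    variant: str
    genotype: Genotype
    concentrations: np.ndarray        # (n_species,), nM, SPECIES order
    regime: Tuple[int, int]           # frozen gate values (M-gate, Y-gate)
    residual: float                   # max |rhs| at the point, nM/hr
    stable: Optional[bool] = None     # None = boundary-degenerate/undetermined

    def __getitem__(self, species: str) -> float:
        return float(self.concentrations[SPECIES.index(species)])

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "genotype": self.genotype.to_dict(),
            "concentrations_nM": {s: self[s] for s in SPECIES},
            "regime": list(self.regime),
            "residual": self.residual,
            "stable": self.stable,
        }


def _late_time(params: RegulatoryParameters, genotype: Genotype) -> float:
    """A time safely beyond every finite pulse edge and Hdac window."""
    edges = [0.0]
    for p in (params.pulse_A, params.pulse_B,
              genotype.exogenous_M, genotype.exogenous_S):
        if p is not None:
            edges.append(p.t_on)
            if np.isfinite(p.t_off):
                edges.append(p.t_off)
    for _, end in genotype.hdac_blocked_windows:
        edges.append(end)
    return max(edges) + 1e3


def _cascade(M: float, p: RegulatoryParameters, genotype: Genotype,
             regime: Tuple[int, int], A_inf: float, e_S: float,
             e_M: float) -> np.ndarray:
    """Full candidate state implied by a Mitfa level within one regime."""
    gM, gY = regime
    a_s, a_m = genotype.sox10_activity, genotype.mitfa_activity
    M_eff = a_m * M + e_M
    H = (p.c_H / p.d_H) * _act(M_eff, p.theta)
    Y = (p.c_Y / p.d_Y) * _act(M_eff, p.delta_MY) * gM
    S = (p.c_S / p.d_S) * min(
        1.0,
        _act(A_inf, p.alpha) * _rep(H, p.phi) + _act(M_eff, p.sigma) * _rep(H, p.xi),
    ) * _rep(M_eff, p.beta)
    S_eff = a_s * S + e_S
    B_inf = p.pulse_B.late_value()
    Z = (p.c_Z / p.d_Z) * genotype.factorZ_scale * _act(B_inf, p.kappa)
    D = (p.c_D / p.d_D) * min(
        1.0, _act(M_eff, p.mu_D) + p.w_Z * _act(Z, p.zeta)) * _rep(S_eff, p.rho)
    T = (p.c_T / p.d_T) * _act(M_eff, p.mu_T)
    return np.array([S, M, H, Y, Z, D, T], dtype=float)


def _mitfa_map(M: float, p: RegulatoryParameters, genotype: Genotype,
               regime: Tuple[int, int], A_inf: float, e_S: float,
               e_M: float) -> float:
    """Steady Mitfa level implied by a trial Mitfa level (fixed-point map)."""
    state = _cascade(M, p, genotype, regime, A_inf, e_S, e_M)
    S_eff = genotype.sox10_activity * state[0] + e_S
    Y = state[3]
    _, gY = regime
    return (p.c_M / p.d_M) * min(
        1.0, _act(S_eff, p.gamma) + _act(Y, p.delta_YM) * gY)


def find_steady_states(variant: str, params: RegulatoryParameters,
                       genotype: Optional[Genotype] = None,
                       n_starts: int = 64,
                       tol: float = TOL_RESIDUAL) -> List[SteadyState]:
    """All self-consistent fixed points in the constant late-time input regime.

    Pulses are evaluated at their late-time limits (a constant input keeps
    its amplitude; a decaying pulse contributes zero).  For the
    thresholded variant C all four gate-regime combinations are solved;
    the masked variants have permanently open gates and a single smooth
    regime.  Returns the deduplicated list, each with a stability label
    (``None`` where the point sits within ``BOUNDARY_EPS`` of a gate
    boundary and the linearisation is undefined).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    gt = genotype or Genotype.wild_type()
    p = mask_params(params, variant)
    d = p.degradation_rates()
    c = p.synthesis_rates()
    if np.any((np.asarray(d) <= 0) & (np.asarray(c) > 0)):
        raise NoSteadyStateError("a species with zero degradation and "
                                 "positive synthesis has no fixed point")
    t_inf = _late_time(p, gt)
    A_inf = p.pulse_A.late_value()
    e_S = gt.exogenous_S.late_value() if gt.exogenous_S is not None else 0.0
    e_M = gt.exogenous_M.late_value() if gt.exogenous_M is not None else 0.0
    M_cap = float(p.c_M) / float(p.d_M) if float(p.d_M) > 0 else 0.0
    M_hi = 1.05 * M_cap + 1e-9

    if variant == "C":
        regimes = list(itertools.product((0, 1), (0, 1)))
    else:
        regimes = [(1, 1)]  # thresholds masked open

    # scan grid: 0 plus log-spaced points up to just above capacity
    n = max(int(n_starts), 8)
    grid = np.unique(np.concatenate([[0.0], np.logspace(-6, np.log10(M_hi), n)]))

    found: List[SteadyState] = []
    for regime in regimes:
        def residual_M(M, _regime=regime):
            return _mitfa_map(M, p, gt, _regime, A_inf, e_S, e_M) - M

        roots: List[float] = []
        vals = np.array([residual_M(m) for m in grid])
        for i in range(len(grid) - 1):
            a, b = vals[i], vals[i + 1]
            if a == 0.0:
                roots.append(float(grid[i]))
            elif a * b < 0:
                roots.append(float(brentq(residual_M, grid[i], grid[i + 1],
                                          xtol=1e-14, rtol=8.9e-16)))
        if vals[-1] == 0.0:
            roots.append(float(grid[-1]))

        for M_root in roots:
            state = _cascade(M_root, p, gt, regime, A_inf, e_S, e_M)
            M_eff = gt.mitfa_activity * state[1] + e_M
            Y = state[3]
            # regime self-consistency with a boundary guard
            if variant == "C":
                near_boundary = (abs(M_eff - p.M_star) < BOUNDARY_EPS
                                 or abs(Y - p.Y_star) < BOUNDARY_EPS)
                if not near_boundary:
                    if (_gate(M_eff, p.M_star), _gate(Y, p.Y_star)) != regime:
                        continue
            else:
                near_boundary = False
            res = float(np.max(np.abs(
                rhs(variant, state, t_inf, params, gt, frozen_gates=regime))))
            if res > tol:
                continue
            if any(np.max(np.abs(state - s.concentrations)) < DEDUPE_DISTANCE
                   for s in found):
                continue
            stable = None if near_boundary else _stable_from_jacobian(
                state, regime, variant, params, gt, t_inf)
            found.append(SteadyState(variant=variant, genotype=gt,
                                     concentrations=state, regime=regime,
                                     residual=res, stable=stable))
    if not found:
        probe = np.array([np.max(np.abs(rhs(
            variant, _cascade(m, p, gt, regimes[0], A_inf, e_S, e_M),
            t_inf, params, gt))) for m in grid[:: max(1, len(grid) // 8)]])
        raise NoSteadyStateError(
            "no self-consistent fixed point found in any gate regime; "
            f"residual landscape (sampled): min={probe.min():.3g}, "
            f"max={probe.max():.3g}")
    found.sort(key=lambda s: s["M"])
    return found


def _jacobian(state: np.ndarray, regime: Tuple[int, int], variant: str,
              params: RegulatoryParameters, genotype: Genotype,
              t: float, h: float = 1e-7) -> np.ndarray:
    n = len(state)
    jac = np.empty((n, n))
    for j in range(n):
        bump = np.zeros(n)
        bump[j] = h * max(1.0, abs(state[j]))
        hi = rhs(variant, np.maximum(state + bump, 0.0), t, params, genotype,
                 frozen_gates=regime)
        lo = rhs(variant, np.maximum(state - bump, 0.0), t, params, genotype,
                 frozen_gates=regime)
        jac[:, j] = (hi - lo) / (2 * bump[j])
    return jac


def _stable_from_jacobian(state, regime, variant, params, genotype, t) -> bool:
    eig = np.linalg.eigvals(_jacobian(state, regime, variant, params, genotype, t))
    return bool(np.all(eig.real < 0))


def classify_stability(ss: SteadyState, params: RegulatoryParameters,
                       genotype: Optional[Genotype] = None,
                       eps: float = BOUNDARY_EPS) -> Optional[bool]:
    """Linear stability of a fixed point within its frozen gate regime.

    Returns True iff every eigenvalue of the finite-difference Jacobian
    (gates frozen at ``ss.regime``) has negative real part; ``None`` when
    the point lies within ``eps`` of a gate boundary, where the piecewise
    linearisation is undefined ("boundary-degenerate").
    """
    gt = genotype or ss.genotype
    p = mask_params(params, ss.variant)
    t_inf = _late_time(p, gt)
    if ss.variant == "C":
        M_eff = gt.mitfa_activity * ss["M"]
        if gt.exogenous_M is not None:
            M_eff += gt.exogenous_M.late_value()
        if abs(M_eff - p.M_star) < eps or abs(ss["Y"] - p.Y_star) < eps:
            return None
    return _stable_from_jacobian(ss.concentrations, ss.regime, ss.variant,
                                 params, gt, t_inf)


def consistency_check(ss: SteadyState, variant: str,
                      params: RegulatoryParameters,
                      genotype: Optional[Genotype] = None,
                      horizon: float = 150.0, tol2: float = 1e-3,
                      rel_perturbation: float = 0.01,
                      dt: float = 0.01) -> bool:
    """Cross-validate a stable fixed point against the integrator.

    Integrates from the fixed point perturbed by ±1% for ``horizon``
    hours of constant late-time inputs and requires the trajectory to
    return within ``tol2`` (max-abs, nM).  Raises :class:`ConsistencyError`
    carrying both endpoints if it does not -- e.g. for a mislabeled
    unstable point.
    """
    if not ss.stable:
        raise ValueError("consistency_check expects a stable fixed point")
    gt = genotype or ss.genotype
    t_inf = _late_time(mask_params(params, variant), gt)
    for sign in (+1.0, -1.0):
        start = ss.concentrations * (1.0 + sign * rel_perturbation)
        traj = integrate(variant, params, gt, t0=t_inf, t1=t_inf + horizon,
                         dt=dt, initial_state=np.maximum(start, 0.0))
        end = traj.values[-1]
        if np.max(np.abs(end - ss.concentrations)) > tol2:
            raise ConsistencyError(
                f"perturbed trajectory did not return to the fixed point "
                f"(max deviation {np.max(np.abs(end - ss.concentrations)):.3g} nM)",
                start=start, end=end)
    return True


def steady_state_records(states: List[SteadyState]) -> List[dict]:
    """JSON-serialisable records for export."""
    return [s.to_dict() for s in states]
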