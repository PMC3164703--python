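"""Core definitions of the melanocyte gene-regulatory-network models.

The circuit couples the neural-crest specifier Sox10 (S), the melanocyte
master regulator Mitfa (M), a Mitfa-recruited Hdac repressive activity (H),
a Sox10-independent positive-feedback activator of *mitfa* (Factor Y), a
transiently induced weak activator of differentiation genes (Factor Z,
biologically Sox9b), a representative Sox10-repressed differentiation gene
(D, standing for *dct*/*silva*/*tyr*) and the Sox10-insensitive exception
*tyrp1b* (T).  Two exogenous inputs drive the network: Factor A (composite
*sox10* enhancer inputs such as Wnt/Lef-Tcf, FoxD3, Pax, AP2) and Factor B
(the transient upstream signal inducing Factor Z).

Transcriptional regulation is modelled in quasi-equilibrium: each
activation is a first-order Hill occupancy ``act(x, k) = k*x / (1 + k*x)``
and each repression the complementary ``rep(x, k) = 1 / (1 + k*x)``, with
``k`` the ratio of binding to unbinding rate constants (units 1/nM).
Steep, switch-like behaviour is supplied not by Hill exponents but by two
explicit Heaviside gates on the Factor-Y feedback loop (thresholds
``M*`` and ``Y*``).

Three nested model variants are defined:

* ``"A"`` -- the minimal feed-forward repression circuit (A -> S -> M,
  M -| S, M -> D/T, S -| D);
* ``"B"`` -- adds Factor Y positive feedback on M and Hdac-mediated
  repression of the Mitfa-dependent activation of S;
* ``"C"`` -- the full model: Hdac additionally gates the Factor-A input to
  S, the Y loop is thresholded, and the Factor-B -> Z -> D branch is active.

Variants A and B are obtained from the full right-hand side by masking
parameters (see :func:`mask_params`), so the nesting C -> B -> A is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "SPECIES",
    "SPECIES_INDEX",
    "INPUTS",
    "MODEL_VARIANTS",
    "PulseInput",
    "RegulatoryParameters",
    "Genotype",
    "act",
    "rep",
    "gate",
    "soft_gate",
    "effective_activities",
    "mask_params",
    "rhs",
]

#: State species, in the canonical storage order used by every array in the
#: package.  A and B are exogenous inputs, never state variables.
SPECIES: Tuple[str, ...] = ("S", "M", "H", "Y", "Z", "D", "T")
SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}
INPUTS: Tuple[str, ...] = ("A", "B")
MODEL_VARIANTS: Tuple[str, ...] = ("A", "B", "C")

Number = Union[float, np.ndarray]


def _check_nonneg(name: str, value: Number) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative, got {value!r}")


# ---------------------------------------------------------------------------
# regulation primitives
# ---------------------------------------------------------------------------

def act(x: Number, k: Number) -> Number:
    """Hill-like activation fraction ``k*x / (1 + k*x)``.

    Parameters
    ----------
    x : concentration of the activating factor, nM (>= 0).
    k : binding affinity (binding/unbinding ratio), 1/nM (>= 0).

    Returns the promoter occupancy in ``[0, 1)``; monotone non-decreasing
    in both arguments, 0 at ``x = 0`` and 1/2 at ``k*x = 1``.
    """
    _check_nonneg("x", x)
    _check_nonneg("k", k)
    return _act(x, k)


def rep(x: Number, k: Number) -> Number:
    """Hill-like repression fraction ``1 / (1 + k*x)`` in ``(0, 1]``.

    Complementary to :func:`act`: ``rep(x, k) == 1 - act(x, k)``.
    """
    _check_nonneg("x", x)
    _check_nonneg("k", k)
    return _rep(x, k)


def gate(x: Number, x_star: Number) -> Number:
    """Heaviside threshold gate: 1 where ``x >= x_star``, else 0.

    The boundary is inclusive.  A threshold of exactly 0 means the gate is
    permanently open (used internally to disable thresholds in the
    non-thresholded model variants).
    """
    _check_nonneg("x", x)
    _check_nonneg("x_star", x_star)
    return _gate(x, x_star)


def soft_gate(x: Number, x_star: Number, hill: float = 20.0) -> Number:
    """Smooth alternative to :func:`gate` (steep Hill function).

    Provided for solver-smoothness experiments; value is 1/2 at the
    threshold and approaches the hard gate as ``hill`` grows.  Not used by
    the default integration path.
    """
    _check_nonneg("x", x)
    if np.any(np.asarray(x_star) <= 0):
        raise ValueError("soft_gate requires a strictly positive threshold")
    r = np.asarray(x, dtype=float) / x_star
    return r**hill / (1.0 + r**hill)


def _act(x, k):
    kx = np.multiply(k, x)
    return kx / (1.0 + kx)


def _rep(x, k):
    return 1.0 / (1.0 + np.multiply(k, x))


def _gate(x, x_star):
    return np.where(np.greater_equal(x, x_star), 1.0, 0.0)


# ---------------------------------------------------------------------------
# inputs and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseInput:
    """Piecewise-constant input with exponential tail.

    Value is 0 before ``t_on``, ``amplitude`` on ``[t_on, t_off]`` and
    ``amplitude * exp(-decay_rate * (t - t_off))`` afterwards; ``t_off``
    may be ``inf`` for a constant (step) input.
    """

    amplitude: float  # nM
    t_on: float = 0.0  # hpf
    t_off: float = math.inf  # hpf
    decay_rate: float = 0.0  # 1/hr, applied after t_off

    def __post_init__(self) -> None:
        _check_nonneg("amplitude", self.amplitude)
        _check_nonneg("decay_rate", self.decay_rate)
        if self.t_on > self.t_off:
            raise ValueError("pulse requires t_on <= t_off")

    def value(self, t: Number) -> Number:
        """Evaluate the pulse at time ``t`` (hpf); vectorised over ``t``."""
        t = np.asarray(t, dtype=float)
        tail = np.maximum(t - self.t_off, 0.0)  # 0 on the plateau, also for t_off=inf
        v = np.where(t < self.t_on, 0.0,
                     self.amplitude * np.exp(-self.decay_rate * tail))
        return float(v) if v.ndim == 0 else v

    def late_value(self) -> float:
        """Limit of the pulse as t -> infinity (used by steady-state analysis)."""
        if not math.isfinite(self.t_off):
            return self.amplitude
        return self.amplitude if self.decay_rate == 0.0 else 0.0

    @staticmethod
    def off() -> "PulseInput":
        return PulseInput(amplitude=0.0, t_on=0.0, t_off=math.inf)


_RATE_FIELDS = tuple(f"c_{g}" for g in SPECIES) + tuple(f"d_{g}" for g in SPECIES)
_AFFINITY_FIELDS = (
    "alpha", "gamma", "beta", "sigma", "delta_MY", "delta_YM",
    "theta", "xi", "phi", "kappa", "zeta", "mu_D", "mu_T", "rho",
)


@dataclass(frozen=True)
class RegulatoryParameters:
    """All rate constants, binding-affinity ratios, thresholds and pulses.

    Rates ``c_g`` (maximal synthesis, nM/hr) and ``d_g`` (first-order
    degradation, 1/hr) are per state species.  Affinities (1/nM) name the
    regulatory arrows of the network:

    ========  =================================================
    alpha     Factor A activation of S
    gamma     Sox10 activation of M
    beta      Mitfa repression of S
    sigma     Mitfa activation of S (Hdac-gated)
    delta_MY  Mitfa activation of Y
    delta_YM  Y activation of M
    theta     Mitfa activation of H
    xi        Hdac repression of the Mitfa->S activation term
    phi       Hdac repression of the FactorA->S activation term
    kappa     Factor B activation of Z
    zeta      Z activation of D (weighted by w_Z < 1: weak activator)
    mu_D      Mitfa activation of D
    mu_T      Mitfa activation of T
    rho       Sox10 repression of D
    ========  =================================================

    ``M_star``/``Y_star`` are the Heaviside thresholds of the Factor-Y
    feedback loop (nM).  Fields accept numpy arrays for vectorised
    parameter sweeps; broadcasting follows numpy rules.
    """

    c_S: Number
    c_M: Number
    c_H: Number
    c_Y: Number
    c_Z: Number
    c_D: Number
    c_T: Number
    d_S: Number
    d_M: Number
    d_H: Number
    d_Y: Number
    d_Z: Number
    d_D: Number
    d_T: Number
    alpha: Number
    gamma: Number
    beta: Number
    sigma: Number
    delta_MY: Number
    delta_YM: Number
    theta: Number
    xi: Number
    phi: Number
    kappa: Number
    zeta: Number
    w_Z: Number
    mu_D: Number
    mu_T: Number
    rho: Number
    M_star: Number = 0.01
    Y_star: Number = 0.01
    pulse_A: PulseInput = field(default_factory=PulseInput.off)
    pulse_B: PulseInput = field(default_factory=PulseInput.off)

    def __post_init__(self) -> None:
        for f in _RATE_FIELDS + _AFFINITY_FIELDS:
            _check_nonneg(f, getattr(self, f))
        if np.any(np.asarray(self.w_Z) < 0) or np.any(np.asarray(self.w_Z) > 1):
            raise ValueError("w_Z must lie in [0, 1]")
        _check_nonneg("M_star", self.M_star)
        _check_nonneg("Y_star", self.Y_star)

    def synthesis_rates(self) -> np.ndarray:
        return np.stack(np.broadcast_arrays(
            *[np.asarray(getattr(self, f"c_{g}"), float) for g in SPECIES]), axis=-1)

    def degradation_rates(self) -> np.ndarray:
        return np.stack(np.broadcast_arrays(
            *[np.asarray(getattr(self, f"d_{g}"), float) for g in SPECIES]), axis=-1)

    def capacity(self) -> np.ndarray:
        """Saturation bound ``c_g / d_g`` per species (inf where d_g = 0)."""
        c = self.synthesis_rates()
        d = self.degradation_rates()
        with np.errstate(divide="ignore", invalid="ignore"):
            cap = np.where(d > 0, c / np.where(d > 0, d, 1.0), np.inf)
        return np.where((c == 0) & (d == 0), 0.0, cap)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, PulseInput):
                out[f.name] = {"amplitude": v.amplitude, "t_on": v.t_on,
                               "t_off": v.t_off, "decay_rate": v.decay_rate}
            else:
                out[f.name] = float(v) if np.ndim(v) == 0 else np.asarray(v).tolist()
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RegulatoryParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        kw = dict(data)
        for p in ("pulse_A", "pulse_B"):
            if p in kw and isinstance(kw[p], dict):
                pk = dict(kw[p])
                extra = set(pk) - {"amplitude", "t_on", "t_off", "decay_rate"}
                if extra:
                    raise KeyError(f"unknown keys in {p}: {sorted(extra)}")
                if isinstance(pk.get("t_off"), str):
                    pk["t_off"] = float(pk["t_off"])
                kw[p] = PulseInput(**pk)
        return cls(**kw)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Genotype:
    """Functional-activity scalings representing mutant/morphant/drug scenarios.

    Mutant alleles are modelled as activity masking: the transcript (state
    variable) keeps evolving, but its regulatory influence is scaled by the
    activity in ``[0, 1]``.  This matches the observation that *sox10* and
    *mitfa* transcripts persist in the corresponding null mutants.
    ``hdac_blocked_windows`` lists (start, end) intervals (hpf) during which
    Hdac activity contributes zero repression (chemical Hdac inhibition).
    ``exogenous_M``/``exogenous_S`` inject additional effective activity
    (mRNA rescue/injection experiments).
    """

    sox10_activity: float = 1.0
    mitfa_activity: float = 1.0
    factorZ_scale: float = 1.0
    hdac_blocked_windows: Tuple[Tuple[float, float], ...] = ()
    exogenous_M: Optional[PulseInput] = None
    exogenous_S: Optional[PulseInput] = None

    def __post_init__(self) -> None:
        for name in ("sox10_activity", "mitfa_activity", "factorZ_scale"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        windows = tuple(tuple(map(float, w)) for w in self.hdac_blocked_windows)
        object.__setattr__(self, "hdac_blocked_windows", windows)
        prev_end = -math.inf
        for start, end in windows:
            if start > end:
                raise ValueError(f"hdac window start > end: {(start, end)}")
            if start < prev_end:
                raise ValueError("hdac windows must be ordered and non-overlapping")
            prev_end = end

    # canonical genotypes -------------------------------------------------
    @staticmethod
    def wild_type() -> "Genotype":
        return Genotype()

    @staticmethod
    def sox10_null(**kw) -> "Genotype":
        return Genotype(sox10_activity=0.0, **kw)

    @staticmethod
    def mitfa_null(**kw) -> "Genotype":
        return Genotype(mitfa_activity=0.0, **kw)

    @staticmethod
    def double_null(**kw) -> "Genotype":
        return Genotype(sox10_activity=0.0, mitfa_activity=0.0, **kw)

    def hdac_blocked(self, t: Number) -> Number:
        """Boolean (array): does ``t`` fall in an Hdac-inhibition window?

        Windows are half-open ``[start, end)`` so a zero-length window is
        genuinely empty.
        """
        t = np.asarray(t, dtype=float)
        blocked = np.zeros(t.shape, dtype=bool)
        for start, end in self.hdac_blocked_windows:
            blocked |= (t >= start) & (t < end)
        return bool(blocked) if blocked.ndim == 0 else blocked

    def to_dict(self) -> dict:
        out = {
            "sox10_activity": self.sox10_activity,
            "mitfa_activity": self.mitfa_activity,
            "factorZ_scale": self.factorZ_scale,
            "hdac_blocked_windows": [list(w) for w in self.hdac_blocked_windows],
        }
        for name in ("exogenous_M", "exogenous_S"):
            p = getattr(self, name)
            out[name] = None if p is None else {
                "amplitude": p.amplitude, "t_on": p.t_on,
                "t_off": p.t_off, "decay_rate": p.decay_rate}
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "Genotype":
        known = {"sox10_activity", "mitfa_activity", "factorZ_scale",
                 "hdac_blocked_windows", "exogenous_M", "exogenous_S"}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown genotype keys: {sorted(unknown)}")
        kw = dict(data)
        kw["hdac_blocked_windows"] = tuple(
            tuple(w) for w in kw.get("hdac_blocked_windows", ()) or ())
        for name in ("exogenous_M", "exogenous_S"):
            p = kw.get(name)
            if isinstance(p, dict):
                pk = dict(p)
                if isinstance(pk.get("t_off"), str):
                    pk["t_off"] = float(pk["t_off"])
                kw[name] = PulseInput(**pk)
        return cls(**kw)


def effective_activities(state: np.ndarray, t: Number,
                         genotype: Genotype) -> Tuple[Number, Number, Number]:
    """Genotype-adjusted regulatory activities (S_eff, M_eff, H_eff) at time t.

    State variables themselves are never zeroed by a genotype -- only the
    influence they exert downstream is scaled.
    """
    state = np.asarray(state, dtype=float)
    S = state[..., SPECIES_INDEX["S"]]
    M = state[..., SPECIES_INDEX["M"]]
    H = state[..., SPECIES_INDEX["H"]]
    S_eff = genotype.sox10_activity * S
    M_eff = genotype.mitfa_activity * M
    if genotype.exogenous_S is not None:
        S_eff = S_eff + genotype.exogenous_S.value(t)
    if genotype.exogenous_M is not None:
        M_eff = M_eff + genotype.exogenous_M.value(t)
    H_eff = np.where(genotype.hdac_blocked(t), 0.0, H)
    return S_eff, M_eff, H_eff


# ---------------------------------------------------------------------------
# variant masking and the right-hand side
# ---------------------------------------------------------------------------

def mask_params(params: RegulatoryParameters, variant: str) -> RegulatoryParameters:
    """Reduce a full parameter set to the given model variant.

    Variant C returns the parameters unchanged.  Variant B removes the
    Hdac gate on the Factor-A input (phi = 0), the Factor-B/Z branch
    (kappa = w_Z = 0) and opens both thresholds (M* = Y* = 0, i.e. the
    gates are permanently on).  Variant A additionally removes the H and Y
    intermediates (sigma = xi = theta = delta_MY = delta_YM = 0), leaving
    the minimal feed-forward repression circuit.
    """
    if variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {MODEL_VARIANTS}")
    if variant == "C":
        return params
    masked = replace(params, phi=0.0, kappa=0.0, w_Z=0.0, M_star=0.0, Y_star=0.0)
    if variant == "A":
        masked = replace(masked, sigma=0.0, xi=0.0, theta=0.0,
                         delta_MY=0.0, delta_YM=0.0)
    return masked


def rhs(variant: str, state: np.ndarray, t: Number,
        params: RegulatoryParameters, genotype: Optional[Genotype] = None,
        frozen_gates: Optional[Tuple[float, float]] = None) -> np.ndarray:
    """Time derivative of the state vector, nM/hr, for one model variant.

    ``state`` has the species of :data:`SPECIES` along its last axis and
    may carry arbitrary leading batch dimensions (used by parameter
    sweeps, with array-valued parameter fields broadcasting against the
    batch).  ``frozen_gates`` fixes the two Heaviside gate values
    ``(gate(M_eff - M*), gate(Y - Y*))`` instead of evaluating them --
    used by the steady-state machinery to linearise within a gate regime.
    """
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != len(SPECIES):
        raise ValueError(f"state must have {len(SPECIES)} species on the last axis")
    if np.any(np.isnan(state)):
        raise ValueError("NaN in state vector")
    p = mask_params(params, variant)
    return _rhs_masked(state, t, p, genotype or Genotype.wild_type(), frozen_gates)


def _rhs_masked(state: np.ndarray, t: Number, p: RegulatoryParameters,
                genotype: Genotype,
                frozen_gates: Optional[Tuple[float, float]] = None) -> np.ndarray:
    """rhs on pre-masked parameters (hot path used by the integrators)."""
    S = state[..., 0]
    M = state[..., 1]
    H = state[..., 2]
    Y = state[..., 3]
    Z = state[..., 4]
    D = state[..., 5]
    T = state[..., 6]
    S_eff, M_eff, H_eff = effective_activities(state, t, genotype)
    A = p.pulse_A.value(t)
    B = p.pulse_B.value(t)
    if frozen_gates is not None:
        gM, gY = frozen_gates
    else:
        # a threshold of 0 (masked variants) opens the gate identically
        gM = _gate(M_eff, p.M_star)
        gY = _gate(Y, p.Y_star)
    dS = p.c_S * np.minimum(
        1.0,
        _act(A, p.alpha) * _rep(H_eff, p.phi) + _act(M_eff, p.sigma) * _rep(H_eff, p.xi),
    ) * _rep(M_eff, p.beta) - p.d_S * S
    dM = p.c_M * np.minimum(
        1.0, _act(S_eff, p.gamma) + _act(Y, p.delta_YM) * gY) - p.d_M * M
    dH = p.c_H * _act(M_eff, p.theta) - p.d_H * H
    dY = p.c_Y * _act(M_eff, p.delta_MY) * gM - p.d_Y * Y
    dZ = p.c_Z * genotype.factorZ_scale * _act(B, p.kappa) - p.d_Z * Z
    dD = p.c_D * np.minimum(
        1.0, _act(M_eff, p.mu_D) + p.w_Z * _act(Z, p.zeta)) * _rep(S_eff, p.rho) - p.d_D * D
    dT = p.c_T * _act(M_eff, p.mu_T) - p.d_T * T
    return np.stack(np.broadcast_arrays(dS, dM, dH, dY, dZ, dD, dT), axis=-1)
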