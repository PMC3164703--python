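"""Canonical in-silico experiments on the melanocyte network.

Each scenario mirrors one of the experimental manipulations used to probe
the circuit: the four-genotype expression panel, transient Mitfa rescue of
*sox10* mutants, blastomere mRNA overexpression/co-injection, chemical
Hdac inhibition in a time window, and Sox9b (Factor Z) knockdown.
Contract outcomes are reported as booleans in result objects -- never
raised -- so that parameter sweeps can tally them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .core import Genotype, PulseInput, RegulatoryParameters, SPECIES, SPECIES_INDEX
from .dynamics import Trajectory, integrate
from .reference import DEFAULT_DT, DEFAULT_T0, DEFAULT_T1, THETA_DET
from .steady_state import SteadyState, find_steady_states

__all__ = [
    "PANEL_GENOTYPES",
    "PanelResult",
    "RescueResult",
    "HdacInhibitionResult",
    "KnockdownResult",
    "run_panel",
    "run_rescue",
    "run_overexpression",
    "run_hdac_inhibition",
    "run_sox9b_knockdown",
    "OVEREXPRESSION_DOSE_M",
    "OVEREXPRESSION_DOSE_S",
]

PANEL_GENOTYPES: Dict[str, Genotype] = {
    "WT": Genotype.wild_type(),
    "mitfa_null": Genotype.mitfa_null(),
    "sox10_null": Genotype.sox10_null(),
    "double_null": Genotype.double_null(),
}

#: Default overexpression doses (nM).  The Mitfa dose is ten times the
#: wild-type steady Mitfa level; the Sox10 dose scales it by the 115:35
#: injected-RNA mass ratio of the corresponding experiments.
OVEREXPRESSION_DOSE_M = 8.0
OVEREXPRESSION_DOSE_S = OVEREXPRESSION_DOSE_M * 115.0 / 35.0


def duration_above(traj: Trajectory, species: str, theta_det: float) -> float:
    """Total time (hr) a species spends at or above the detection threshold."""
    return float(np.count_nonzero(traj.species(species) >= theta_det) * traj.dt)


def peak(traj: Trajectory, species: str) -> float:
    return float(np.max(traj.species(species)))


@dataclass(frozen=True)
class PanelResult:
    """Four-genotype simulation panel with per-genotype readout metrics."""

    variant: str
    params: RegulatoryParameters
    trajectories: Dict[str, Trajectory]
    theta_det: float

    def metrics(self) -> pd.DataFrame:
        """duration_above and peak for every readout species and genotype.

        Pure function of the stored trajectories (recomputable round trip).
        """
        rows = []
        for name, traj in self.trajectories.items():
            for sp in SPECIES:
                rows.append({
                    "genotype": name,
                    "species": sp,
                    "duration_above_hr": duration_above(traj, sp, self.theta_det),
                    "peak_nM": peak(traj, sp),
                    "final_nM": traj.final(sp),
                })
        return pd.DataFrame(rows)

    def contracts(self) -> Dict[str, bool]:
        """Qualitative expression-pattern contracts of the full model.

        Evaluated per clause and returned (never raised): the *dct*-class
        signal D is transient in all three mutants, is weakest and most
        transient in the *mitfa* mutant, and is Mitfa-independent in the
        *sox10* background (double mutant ~ *sox10* mutant); *sox10*
        persists at late times in the *mitfa* mutant but not in wild type.
        """
        th = self.theta_det
        tr = self.trajectories
        mutants = ("mitfa_null", "sox10_null", "double_null")
        dur = {g: duration_above(tr[g], "D", th) for g in mutants}
        pk = {g: peak(tr[g], "D") for g in mutants}
        transient = all(pk[g] >= th and tr[g].final("D") < th for g in mutants)
        weakest = (dur["mitfa_null"] < min(dur["sox10_null"], dur["double_null"])
                   and pk["mitfa_null"] < min(pk["sox10_null"], pk["double_null"]))
        ds = np.abs(tr["double_null"].species("D") - tr["sox10_null"].species("D"))
        double_matches = float(np.max(ds)) <= 0.05 * max(pk["sox10_null"], th)
        return {
            "D_transient_in_all_mutants": bool(transient),
            "D_weakest_in_mitfa_null": bool(weakest),
            "double_null_matches_sox10_null": bool(double_matches),
            "sox10_persists_in_mitfa_null": tr["mitfa_null"].final("S") >= th,
            "sox10_off_late_in_WT": tr["WT"].final("S") < th,
        }


def run_panel(variant: str, params: RegulatoryParameters,
              theta_det: float = THETA_DET,
              t0: float = DEFAULT_T0, t1: float = DEFAULT_T1,
              dt: float = DEFAULT_DT) -> PanelResult:
    """Simulate WT and the three mutant genotypes on a shared grid."""
    trajectories = {name: integrate(variant, params, gt, t0=t0, t1=t1, dt=dt)
                    for name, gt in PANEL_GENOTYPES.items()}
    return PanelResult(variant=variant, params=params,
                       trajectories=trajectories, theta_det=theta_det)


@dataclass(frozen=True)
class RescueResult:
    trajectory: Trajectory
    converged_to: str                 # "on" | "off"
    attractors: Tuple[SteadyState, SteadyState]


def run_rescue(params: RegulatoryParameters, pulse: PulseInput,
               t0: float = DEFAULT_T0, t1: float = DEFAULT_T1,
               dt: float = DEFAULT_DT,
               atol: float = 0.05) -> RescueResult:
    """Transient exogenous Mitfa in the *sox10* mutant (rescue experiment).

    The full model in the *sox10*-null genotype is bistable; the run is
    classified by which of the two stable fixed points the end state lies
    nearest on the switch coordinates -- Mitfa and the differentiation
    output D, which separate the attractors -- within ``atol`` nM
    (anything else raises).  Species upstream of the switch (e.g. Sox10
    itself) may still be relaxing after a long pulse without affecting
    the attractor identity.  A pulse whose plateau never reaches the
    Mitfa threshold M* cannot open the Factor-Y gate and always returns
    to the undifferentiated "off" state.
    """
    base = Genotype.sox10_null()
    stable = [s for s in find_steady_states("C", params, base) if s.stable]
    if len(stable) != 2:
        raise RuntimeError(f"expected 2 stable states in the sox10-null full "
                           f"model, found {len(stable)}")
    off, on = sorted(stable, key=lambda s: s["M"])
    gt = Genotype.sox10_null(exogenous_M=pulse)
    traj = integrate("C", params, gt, t0=t0, t1=t1, dt=dt)
    switch = [SPECIES_INDEX["M"], SPECIES_INDEX["D"]]
    end = traj.values[-1][switch]
    d_off = float(np.max(np.abs(end - off.concentrations[switch])))
    d_on = float(np.max(np.abs(end - on.concentrations[switch])))
    if min(d_off, d_on) > atol:
        raise RuntimeError(f"end state near neither attractor "
                           f"(d_off={d_off:.3g}, d_on={d_on:.3g} nM)")
    return RescueResult(trajectory=traj,
                        converged_to="off" if d_off < d_on else "on",
                        attractors=(off, on))


def run_overexpression(params: RegulatoryParameters,
                       init_S: float = 0.0, init_M: float = 0.0,
                       t_early: float = 6.0, t_late: float = 10.5,
                       theta_det: float = THETA_DET,
                       dt: float = 0.005) -> pd.DataFrame:
    """Blastomere mRNA injection emulation: initial conditions only.

    The Factor A and B inputs are disabled (no neural-crest context); the
    injected dose enters purely as the initial Sox10/Mitfa concentration.
    Returns a table of which species are detectable (>= ``theta_det``) at
    the early and late assay times, with the underlying concentrations.
    """
    p = replace(params, pulse_A=PulseInput.off(), pulse_B=PulseInput.off())
    x0 = np.zeros(len(SPECIES))
    x0[SPECIES_INDEX["S"]] = init_S
    x0[SPECIES_INDEX["M"]] = init_M
    traj = integrate("C", p, t0=0.0, t1=t_late + 1.0, dt=dt, initial_state=x0)
    rows = []
    for sp in SPECIES:
        early = float(traj.at(sp, t_early))
        late = float(traj.at(sp, t_late))
        rows.append({
            "species": sp,
            "on_at_early": early >= theta_det,
            "on_at_late": late >= theta_det,
            "early_nM": early,
            "late_nM": late,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HdacInhibitionResult:
    window: Tuple[float, float]
    wt_control: Trajectory
    wt_treated: Trajectory
    mitfa_null_control: Trajectory
    mitfa_null_treated: Trajectory
    theta_det: float

    def contracts(self) -> Dict[str, bool]:
        t_end = self.window[1]
        upto = self.wt_control.times <= t_end
        d_ctrl = float(np.max(self.wt_control.species("D")[upto]))
        d_trt = float(np.max(self.wt_treated.species("D")[upto]))
        ds = np.abs(self.mitfa_null_treated.species("S")
                    - self.mitfa_null_control.species("S"))
        return {
            "wt_sox10_prolonged": (
                float(self.wt_treated.at("S", t_end)) >= self.theta_det
                > float(self.wt_control.at("S", t_end))),
            "wt_D_peak_reduced": d_trt < d_ctrl,
            "mitfa_null_sox10_unchanged": float(np.max(ds)) <= 1e-6,
        }


def run_hdac_inhibition(params: RegulatoryParameters,
                        window: Tuple[float, float] = (24.0, 48.0),
                        theta_det: float = THETA_DET,
                        t0: float = DEFAULT_T0, t1: float = DEFAULT_T1,
                        dt: float = DEFAULT_DT) -> HdacInhibitionResult:
    """Chemical Hdac inhibition during a time window, WT and *mitfa* mutant.

    During the window Hdac activity exerts no repression.  Melanisation
    readouts (the D peak) are compared up to the window end, the stage at
    which the corresponding treated embryos were assessed.  Because Hdac
    induction is Mitfa-dependent, the *mitfa* mutant is predicted -- and
    required -- to be completely insensitive to the treatment.
    """
    if not (t0 <= window[0] <= window[1] <= t1):
        raise ValueError("window must lie within [t0, t1]")
    blocked = (tuple(map(float, window)),)
    runs = {}
    for label, base in (("wt", {}), ("mn", {"mitfa_activity": 0.0})):
        runs[label + "_ctrl"] = integrate(
            "C", params, Genotype(**base), t0=t0, t1=t1, dt=dt)
        runs[label + "_trt"] = integrate(
            "C", params, Genotype(hdac_blocked_windows=blocked, **base),
            t0=t0, t1=t1, dt=dt)
    return HdacInhibitionResult(
        window=(float(window[0]), float(window[1])),
        wt_control=runs["wt_ctrl"], wt_treated=runs["wt_trt"],
        mitfa_null_control=runs["mn_ctrl"], mitfa_null_treated=runs["mn_trt"],
        theta_det=theta_det)


@dataclass(frozen=True)
class KnockdownResult:
    factorZ_scale: float
    full: Trajectory
    reduced: Trajectory

    @property
    def auc_full(self) -> float:
        return float(np.trapezoid(self.full.species("D"), self.full.times))

    @property
    def auc_reduced(self) -> float:
        return float(np.trapezoid(self.reduced.species("D"), self.reduced.times))


def run_sox9b_knockdown(params: RegulatoryParameters, factorZ_scale: float,
                        mitfa_activity: float = 1.0,
                        t0: float = DEFAULT_T0, t1: float = DEFAULT_T1,
                        dt: float = DEFAULT_DT) -> KnockdownResult:
    """Factor Z (Sox9b) knockdown in the *sox10* mutant background.

    Compares the residual differentiation output D (time-integrated
    signal) at full versus reduced Factor Z activity; in the double
    mutant with full knockdown D has no input at all and stays at zero.
    """
    full = integrate("C", params,
                     Genotype(sox10_activity=0.0, mitfa_activity=mitfa_activity),
                     t0=t0, t1=t1, dt=dt)
    reduced = integrate("C", params,
                        Genotype(sox10_activity=0.0, mitfa_activity=mitfa_activity,
                                 factorZ_scale=factorZ_scale),
                        t0=t0, t1=t1, dt=dt)
    return KnockdownResult(factorZ_scale=factorZ_scale, full=full, reduced=reduced)
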