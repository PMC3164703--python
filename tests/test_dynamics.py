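"""Euler integration, pulse evaluation and behaviour-criteria flags."""

import dataclasses
import math

import numpy as np
import pytest

from melgrn.core import Genotype, PulseInput, RegulatoryParameters, SPECIES, SPECIES_INDEX
from melgrn.dynamics import (
    IntegrationError,
    Trajectory,
    behaviour_flags,
    integrate,
    pulse_value,
    run_summary,
)


def _decay_only_params(r=0.3, d=0.2):
    """One decoupled species (T) with constant synthesis r and decay d."""
    kw = {f"c_{g}": 0.0 for g in SPECIES}
    kw.update({f"d_{g}": d for g in SPECIES})
    kw.update({a: 0.0 for a in ("alpha", "gamma", "beta", "sigma", "delta_MY",
                                "delta_YM", "theta", "xi", "phi", "kappa",
                                "zeta", "mu_D", "rho")})
    # T synthesises at rate c_T * act(M; mu_T) ~= c_T for saturating mu_T * M
    kw["c_T"] = r
    kw["mu_T"] = 1e12
    kw["w_Z"] = 0.0
    return RegulatoryParameters(**kw)


class TestPulse:
    def test_piecewise_form(self):
        p = PulseInput(amplitude=2.0, t_on=10.0, t_off=20.0, decay_rate=0.5)
        assert pulse_value(5.0, p) == 0.0
        assert pulse_value(15.0, p) == 2.0
        assert pulse_value(20.0, p) == 2.0  # continuous at t_off
        # one decay time after switch-off: amplitude / e
        assert pulse_value(22.0, p) == pytest.approx(2.0 * math.exp(-1.0))

    def test_constant_input(self):
        p = PulseInput(amplitude=1.5, t_on=12.0)
        t = np.array([0.0, 12.0, 1e6])
        np.testing.assert_allclose(pulse_value(t, p), [0.0, 1.5, 1.5])

    def test_invalid_pulse(self):
        with pytest.raises(ValueError):
            PulseInput(amplitude=-1.0)
        with pytest.raises(ValueError):
            PulseInput(amplitude=1.0, t_on=5.0, t_off=4.0)


class TestIntegrate:
    def test_zero_synthesis_zero_state(self):
        p = _decay_only_params(r=0.0)
        traj = integrate("C", p, t0=0, t1=10, dt=0.05)
        assert np.all(traj.values == 0.0)

    def test_single_species_closed_form(self):
        """x' = r - d*x, x(0) = 0 has solution (r/d)(1 - exp(-d t))."""
        r, d, dt = 0.3, 0.2, 0.01
        traj = integrate("C", _decay_only_params(r, d), t0=0, t1=40, dt=dt)
        # M saturates act instantly only if M > 0; use T driven by mu_T -> inf?
        # T responds to M_eff which is 0 here, so drive the decoupled species
        # directly instead: exact solution applies to a constant input.
        exact = (r / d) * (1 - np.exp(-d * traj.times))
        x = traj.species("T")
        # T' = c_T * act(M_eff=0) = 0 -> stays 0; the synthesising case needs
        # M_eff > 0, so rerun with an exogenous saturating Mitfa input.
        assert np.all(x == 0.0)
        gt = Genotype(exogenous_M=PulseInput(amplitude=1e6, t_on=0.0))
        traj = integrate("C", _decay_only_params(r, d), gt, t0=0, t1=40, dt=dt)
        x = traj.species("T")
        assert np.max(np.abs(x - exact)) < 2.0 * r * dt  # O(dt) global error

    def test_grid_self_convergence(self, ref_params):
        t1 = 60.0
        fine = integrate("C", ref_params, t0=0, t1=t1, dt=0.005)
        coarse = integrate("C", ref_params, t0=0, t1=t1, dt=0.01)
        scale = np.max(coarse.values, axis=0, keepdims=True)
        common = coarse.times
        diff = np.abs(fine.values[::2] - coarse.values) / np.maximum(scale, 1e-12)
        assert len(fine.times[::2]) == len(common)
        assert np.max(diff) < 5e-3

    def test_deterministic_replay(self, ref_params):
        a = integrate("C", ref_params, t0=0, t1=30, dt=0.02)
        b = integrate("C", ref_params, t0=0, t1=30, dt=0.02)
        assert np.array_equal(a.values, b.values)

    def test_stability_error_names_species(self):
        with pytest.raises(IntegrationError, match="T"):
            integrate("C", _decay_only_params(r=0.3, d=0.2),
                      Genotype(exogenous_M=PulseInput(amplitude=1e6, t_on=0.0)),
                      t0=0, t1=10, dt=6.0)

    def test_negative_clipping_counted(self):
        # pure decay from 1 with d*dt close to the stability limit undershoots
        p = _decay_only_params(r=0.0, d=0.45)
        x0 = np.zeros(len(SPECIES))
        x0[:] = 1.0
        traj = integrate("C", p, t0=0, t1=10, dt=1.0, initial_state=x0)
        assert np.all(traj.values >= 0.0)
        assert traj.clip_count == 0  # 0.45 per step never crosses zero
        # forcing an undershoot requires d*dt > 1, which trips the stability
        # guard first -- clipping is exercised by tiny near-zero states below
        p2 = dataclasses.replace(p)
        x0 = np.full(len(SPECIES), 1e-300)
        traj = integrate("C", p2, t0=0, t1=1, dt=0.5, initial_state=x0)
        assert np.all(traj.values >= 0.0)

    def test_invalid_arguments(self, ref_params):
        with pytest.raises(ValueError):
            integrate("C", ref_params, dt=-0.1)
        with pytest.raises(ValueError):
            integrate("C", ref_params, t0=10, t1=5)
        with pytest.raises(ValueError):
            integrate("C", ref_params, initial_state=-np.ones(len(SPECIES)))


class TestBehaviourFlags:
    def _synthetic(self, times, S, M):
        values = np.zeros((len(times), len(SPECIES)))
        values[:, SPECIES_INDEX["S"]] = S
        values[:, SPECIES_INDEX["M"]] = M
        from melgrn.reference import reference_parameters
        return Trajectory(variant="C", genotype=Genotype.wild_type(),
                          params=reference_parameters(), times=times,
                          values=values, dt=float(times[1] - times[0]))

    def test_silent_sox10(self):
        t = np.linspace(0, 96, 97)
        flags = behaviour_flags(self._synthetic(t, np.zeros_like(t),
                                                np.ones_like(t)))
        assert flags.sox10_off_late and not flags.sox10_transient_peak
        assert flags.mitfa_maintained

    def test_boundary_peak_rejected(self):
        """A monotone decline has a huge peak ratio but no interior peak."""
        t = np.linspace(0, 96, 961)
        S = np.exp(-t / 10.0)
        flags = behaviour_flags(self._synthetic(t, S, np.ones_like(t)), r_min=5)
        assert flags.peak_ratio > 5
        assert not flags.sox10_transient_peak
        assert flags.t_peak == t[0]

    def test_reference_wild_type_all_flags(self, wt_traj):
        flags = behaviour_flags(wt_traj)
        assert flags.all_criteria()
        assert flags.peak_ratio >= 5
        assert wt_traj.times[0] < flags.t_peak < wt_traj.times[-1]

    def test_rescaling_invariance(self, wt_traj):
        scale = 37.5
        scaled = Trajectory(variant=wt_traj.variant, genotype=wt_traj.genotype,
                            params=wt_traj.params, times=wt_traj.times,
                            values=wt_traj.values * scale, dt=wt_traj.dt)
        f0 = behaviour_flags(wt_traj, theta_det=0.01)
        f1 = behaviour_flags(scaled, theta_det=0.01 * scale)
        assert (f0.mitfa_maintained, f0.sox10_transient_peak, f0.sox10_off_late) \
            == (f1.mitfa_maintained, f1.sox10_transient_peak, f1.sox10_off_late)
        assert f0.peak_ratio == pytest.approx(f1.peak_ratio, rel=1e-9)

    def test_empty_and_out_of_range(self, ref_params):
        empty = Trajectory(variant="C", genotype=Genotype.wild_type(),
                           params=ref_params, times=np.array([]),
                           values=np.zeros((0, len(SPECIES))), dt=0.01)
        with pytest.raises(ValueError):
            behaviour_flags(empty)
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            behaviour_flags(self._synthetic(t, t, t), t_late=60.0)


class TestExports:
    def test_tidy_frame_and_summary(self, ref_params):
        traj = integrate("C", ref_params, t0=0, t1=5, dt=0.1)
        frame = traj.to_frame()
        assert set(frame.columns) == {"time_hpf", "species",
                                      "concentration_nM", "genotype", "variant"}
        assert len(frame) == len(traj.times) * len(SPECIES)
        s = run_summary(traj, t_late=4.0)
        assert set(s["flags"]) == {"mitfa_maintained", "sox10_transient_peak",
                                   "sox10_off_late"}
        assert len(s["config_sha256"]) == 64
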