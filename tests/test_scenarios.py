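"""Genotype panels, rescue, overexpression, Hdac inhibition, knockdown."""

import numpy as np
import pytest

from melgrn.core import Genotype, PulseInput
from melgrn.dynamics import integrate
from melgrn.scenarios import (
    OVEREXPRESSION_DOSE_M,
    OVEREXPRESSION_DOSE_S,
    duration_above,
    peak,
    run_hdac_inhibition,
    run_overexpression,
    run_panel,
    run_rescue,
    run_sox9b_knockdown,
)


class TestPanel:
    def test_reference_contracts_all_hold(self, panel_coarse):
        contracts = panel_coarse.contracts()
        assert all(contracts.values()), contracts

    def test_model_b_keeps_sox10_on_in_wt(self, ref_params):
        """The intermediate model cannot shut Sox10 down in wild type."""
        result = run_panel("B", ref_params, dt=0.02)
        assert not result.contracts()["sox10_off_late_in_WT"]

    def test_double_null_equals_sox10_null_D(self, panel_coarse):
        """With no functional Mitfa contribution in either, D is identical."""
        d1 = panel_coarse.trajectories["double_null"].species("D")
        d2 = panel_coarse.trajectories["sox10_null"].species("D")
        np.testing.assert_array_equal(d1, d2)

    def test_metrics_recomputable_from_trajectories(self, panel_coarse):
        m = panel_coarse.metrics()
        row = m[(m.genotype == "sox10_null") & (m.species == "D")].iloc[0]
        traj = panel_coarse.trajectories["sox10_null"]
        assert row.peak_nM == peak(traj, "D")
        assert row.duration_above_hr == duration_above(traj, "D",
                                                       panel_coarse.theta_det)

    def test_derepression_ordering(self, panel_coarse):
        th = panel_coarse.theta_det
        tr = panel_coarse.trajectories
        dur = {g: duration_above(tr[g], "D", th)
               for g in ("mitfa_null", "sox10_null", "double_null")}
        pk = {g: peak(tr[g], "D")
              for g in ("mitfa_null", "sox10_null", "double_null")}
        assert dur["mitfa_null"] < dur["sox10_null"]
        assert pk["mitfa_null"] < pk["sox10_null"]


class TestRescue:
    def test_zero_pulse_stays_off(self, ref_params):
        res = run_rescue(ref_params, PulseInput.off(), dt=0.02)
        assert res.converged_to == "off"

    def test_subthreshold_plateau_always_off(self, ref_params):
        """A plateau at half of M* can never open the Mitfa gate."""
        pulse = PulseInput(amplitude=0.5 * ref_params.M_star,
                           t_on=20.0, t_off=90.0, decay_rate=5.0)
        res = run_rescue(ref_params, pulse, dt=0.02)
        assert res.converged_to == "off"
        assert res.trajectory.final("M") == 0.0

    def test_suprathreshold_pulse_switches_on(self, ref_params):
        pulse = PulseInput(amplitude=10 * ref_params.M_star,
                           t_on=24.0, t_off=34.0, decay_rate=5.0)
        res = run_rescue(ref_params, pulse, dt=0.02)
        assert res.converged_to == "on"
        assert res.trajectory.final("D") > 0.5

    def test_pointwise_dominating_pulse_preserves_on(self, ref_params):
        """If p1 >= p2 pointwise and p2 switches on, so does p1."""
        p2 = PulseInput(amplitude=10 * ref_params.M_star, t_on=24.0,
                        t_off=34.0, decay_rate=5.0)
        p1 = PulseInput(amplitude=20 * ref_params.M_star, t_on=24.0,
                        t_off=40.0, decay_rate=1.0)
        t = np.linspace(0, 96, 400)
        assert np.all(p1.value(t) >= p2.value(t))
        assert run_rescue(ref_params, p2, dt=0.02).converged_to == "on"
        assert run_rescue(ref_params, p1, dt=0.02).converged_to == "on"


class TestOverexpression:
    def _on(self, table, sp, when):
        return bool(table.set_index("species").loc[sp, f"on_at_{when}"])

    def test_nothing_without_injection(self, ref_params):
        table = run_overexpression(ref_params, init_S=0.0, init_M=0.0)
        assert not table.on_at_early.any() and not table.on_at_late.any()

    def test_mitfa_alone_drives_differentiation_early(self, ref_params):
        table = run_overexpression(ref_params, init_S=0.0,
                                   init_M=OVEREXPRESSION_DOSE_M)
        assert self._on(table, "D", "early") and self._on(table, "T", "early")

    def test_sox10_alone_delays_tyrp1b_and_silences_dct(self, ref_params):
        table = run_overexpression(ref_params, init_S=OVEREXPRESSION_DOSE_S,
                                   init_M=0.0)
        assert self._on(table, "M", "early")          # mitfa induced fast
        assert not self._on(table, "T", "early")      # tyrp1b needs Mitfa
        assert self._on(table, "T", "late")
        assert not self._on(table, "D", "early")
        assert not self._on(table, "D", "late")       # dct repressed by Sox10

    def test_coinjection_represses_dct_not_tyrp1b(self, ref_params):
        table = run_overexpression(ref_params, init_S=OVEREXPRESSION_DOSE_S,
                                   init_M=OVEREXPRESSION_DOSE_M)
        assert self._on(table, "T", "early")
        assert not self._on(table, "D", "early")
        assert not self._on(table, "D", "late")


class TestHdacInhibition:
    def test_empty_window_is_identity(self, ref_params):
        res = run_hdac_inhibition(ref_params, window=(30.0, 30.0), dt=0.02)
        np.testing.assert_array_equal(res.wt_control.values,
                                      res.wt_treated.values)

    def test_window_contracts(self, ref_params):
        res = run_hdac_inhibition(ref_params, window=(24.0, 48.0), dt=0.02)
        assert all(res.contracts().values()), res.contracts()

    def test_mitfa_null_exactly_insensitive(self, ref_params):
        res = run_hdac_inhibition(ref_params, window=(24.0, 48.0), dt=0.02)
        np.testing.assert_array_equal(res.mitfa_null_control.values,
                                      res.mitfa_null_treated.values)

    def test_window_validation(self, ref_params):
        with pytest.raises(ValueError):
            run_hdac_inhibition(ref_params, window=(24.0, 200.0))


class TestKnockdown:
    def test_identity_at_full_scale(self, ref_params):
        res = run_sox9b_knockdown(ref_params, 1.0, dt=0.02)
        assert res.auc_full == res.auc_reduced

    def test_double_null_full_knockdown_silences_D(self, ref_params):
        res = run_sox9b_knockdown(ref_params, 0.0, mitfa_activity=0.0, dt=0.02)
        assert np.all(res.reduced.species("D") == 0.0)

    def test_auc_decreasing_in_knockdown_strength(self, ref_params):
        aucs = [run_sox9b_knockdown(ref_params, s, dt=0.05).auc_reduced
                for s in (1.0, 0.7, 0.3, 0.0)]
        assert all(a > b for a, b in zip(aucs, aucs[1:]))


class TestGenotypeResponse:
    def _auc_D(self, ref_params, **kw):
        traj = integrate("C", ref_params, Genotype(**kw), dt=0.05)
        return float(np.trapezoid(traj.species("D"), traj.times))

    def test_D_output_monotone_in_mitfa_and_Z_activity(self, ref_params):
        grid = (0.0, 0.25, 0.5, 0.75, 1.0)
        for name in ("mitfa_activity", "factorZ_scale"):
            aucs = [self._auc_D(ref_params, **{name: a}) for a in grid]
            assert all(b >= a for a, b in zip(aucs, aucs[1:])), (name, aucs)

    def test_D_output_requires_sox10_for_full_differentiation(self, ref_params):
        """Any functional Sox10 ignites Mitfa and raises D far above the
        sox10-null residual; above ignition, extra Sox10 is a (mild) net
        repressor of D, so strict monotonicity is not expected there."""
        grid = (0.25, 0.5, 0.75, 1.0)
        auc_null = self._auc_D(ref_params, sox10_activity=0.0)
        for a in grid:
            assert self._auc_D(ref_params, sox10_activity=a) > 5 * auc_null
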