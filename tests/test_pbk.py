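import numpy as np
import pytest

from qivive.parameters import DoseRegimen
from qivive.pbk import (SimulationResult, fit_eddp_clearance, mass_balance,
                        simulate, steady_state_metrics)


class TestForwardSimulation:
    def test_zero_dose_gives_identically_zero(self, default_params):
        res = simulate(default_params, DoseRegimen(0.0, n_days=2))
        assert np.all(res.y == 0.0)
        assert mass_balance(res) == 0.0

    def test_time_grid_strictly_increasing(self, result_70mg_74kg):
        assert np.all(np.diff(result_70mg_74kg.t) > 0)

    def test_amounts_nonnegative(self, result_70mg_74kg):
        assert result_70mg_74kg.y.min() >= 0.0

    def test_low_dose_linearity(self, default_params):
        """In the linear regime (liver levels far below Km = 275 uM) the
        steady-state Cmax is proportional to dose within 1%."""
        cmaxes = []
        for dose in (1.0, 2.0):
            res = simulate(default_params, DoseRegimen(dose),
                           until_steady_state=True)
            cmaxes.append(steady_state_metrics(res).Cmax_blood_uM)
        assert cmaxes[1] / cmaxes[0] == pytest.approx(2.0, rel=0.01)

    def test_saturation_raises_dose_normalized_exposure(self, default_params):
        """At 2000 mg/day hepatic metabolism saturates, so dose-normalized
        Cmax exceeds the low-dose value."""
        low = simulate(default_params, DoseRegimen(1.0),
                       until_steady_state=True)
        high = simulate(default_params, DoseRegimen(2000.0),
                        until_steady_state=True)
        per_mg_low = steady_state_metrics(low).Cmax_blood_uM / 1.0
        per_mg_high = steady_state_metrics(high).Cmax_blood_uM / 2000.0
        assert per_mg_high > per_mg_low

    def test_cmax_monotone_in_dose(self, default_params):
        doses = [1.0, 10.0, 100.0, 1000.0]
        cmaxes = [steady_state_metrics(
            simulate(default_params, DoseRegimen(d), until_steady_state=True)
        ).Cmax_blood_uM for d in doses]
        assert np.all(np.diff(cmaxes) > 0)

    def test_steady_state_reached_within_30_days(self, default_params):
        res = simulate(default_params, DoseRegimen(70.0, n_days=32))
        conc = res.venous_blood_conc("methadone")
        day = 24.0
        c31 = conc[(res.t >= 30 * day) & (res.t <= 31 * day)].max()
        c32 = conc[(res.t >= 31 * day) & (res.t <= 32 * day)].max()
        assert abs(c32 - c31) / c31 < 0.005

    def test_eddp_starts_at_zero_and_tracks_metabolism(self, result_70mg_74kg):
        res = result_70mg_74kg
        assert res.amount("eddp", "venous_blood")[0] == 0.0
        # total EDDP ever formed equals methadone cumulatively metabolized
        eddp_total = (sum(res.amount("eddp", c)[-1] for c in
                          ("liver", "fat", "lung", "kidney", "heart",
                           "slowly_perfused", "rapidly_perfused",
                           "arterial_blood", "venous_blood"))
                      + res.cumulative("renal_eddp")[-1]
                      + res.cumulative("bile_eddp")[-1])
        formed = res.cumulative("metabolized")[-1]
        assert eddp_total == pytest.approx(formed, rel=1e-9)

    def test_unknown_compound_rejected(self, result_70mg_74kg):
        with pytest.raises(KeyError):
            result_70mg_74kg.amount("emdp", "liver")
        with pytest.raises(KeyError):
            steady_state_metrics(result_70mg_74kg, "emdp")

    def test_coarse_output_grid_rejected(self, default_params):
        with pytest.raises(ValueError, match="100 output points"):
            simulate(default_params, DoseRegimen(10.0, n_days=1),
                     n_points_per_interval=50)


class TestMassBalance:
    @pytest.mark.parametrize("dose", [0.1, 70.0, 3000.0])
    def test_residual_below_1e6(self, default_params, dose):
        res = simulate(default_params, DoseRegimen(dose, n_days=5))
        assert mass_balance(res) < 1e-6

    def test_residual_invariant_to_grid_density(self, default_params):
        reg = DoseRegimen(70.0, n_days=3)
        r1 = simulate(default_params, reg, n_points_per_interval=120)
        r2 = simulate(default_params, reg, n_points_per_interval=240)
        assert abs(mass_balance(r1) - mass_balance(r2)) < 1e-8


class TestSteadyStateMetrics:
    def _flat_result(self, params, conc_uM):
        """Hand-built result with constant venous concentration."""
        t = np.linspace(0.0, 24.0, 241)
        y = np.zeros((23, t.size))
        vv = params.physiology.VVc * params.physiology.BW
        y[9] = conc_uM * vv  # methadone venous blood amount
        return SimulationResult(t=t, y=y, params=params,
                                regimen=DoseRegimen(10.0, n_days=1), n_doses=1)

    def test_flat_curve_auc_and_cmax(self, default_params):
        res = self._flat_result(default_params, conc_uM=2.0)
        m = steady_state_metrics(res)
        mw = default_params.methadone.MW
        assert m.Cmax_blood_uM == pytest.approx(2.0)
        assert m.Cmax_blood_ng_per_ml == pytest.approx(2.0 * mw)
        assert m.AUC_interval_ng_h_per_ml == pytest.approx(24 * 2.0 * mw, rel=1e-12)

    def test_exponential_segment_auc_matches_closed_form(self, default_params):
        t = np.linspace(0.0, 24.0, 241)
        k, c0 = 0.2, 5.0
        y = np.zeros((23, t.size))
        vv = default_params.physiology.VVc * default_params.physiology.BW
        y[9] = c0 * np.exp(-k * t) * vv
        res = SimulationResult(t=t, y=y, params=default_params,
                               regimen=DoseRegimen(10.0, n_days=1), n_doses=1)
        mw = default_params.methadone.MW
        analytic = c0 / k * (1 - np.exp(-k * 24.0)) * mw
        m = steady_state_metrics(res)
        assert m.AUC_interval_ng_h_per_ml == pytest.approx(analytic, rel=1e-3)

    def test_unbound_conversion_consistency(self, result_70mg_74kg):
        m = steady_state_metrics(result_70mg_74kg, "eddp")
        cp = result_70mg_74kg.params.eddp
        assert m.Cmax_unbound_blood_uM == pytest.approx(
            m.Cmax_blood_uM * cp.fu_p / cp.BPr, rel=1e-12)
        assert m.Cmax_blood_ng_per_ml == pytest.approx(
            m.Cmax_blood_uM * cp.MW, rel=1e-12)

    def test_short_result_rejected(self, default_params):
        res = self._flat_result(default_params, 1.0)
        res.t = res.t[:100]
        res.y = res.y[:, :100]
        with pytest.raises(ValueError, match="full dosing interval"):
            steady_state_metrics(res)


class TestTidyExport:
    def test_frame_schema_and_units(self, result_70mg_74kg):
        df = result_70mg_74kg.to_frame()
        assert list(df.columns) == ["time_h", "compound", "compartment",
                                    "amount_umol", "conc_uM", "conc_ng_per_ml"]
        sub = df[(df.compound == "methadone")
                 & (df.compartment == "venous_blood")]
        mw = result_70mg_74kg.params.methadone.MW
        assert np.allclose(sub.conc_ng_per_ml, sub.conc_uM * mw)
        # gut lumen has amounts but no concentration
        gut = df[df.compartment == "gut_lumen"]
        assert set(gut.compound) == {"methadone"}
        assert gut.conc_uM.isna().all()


class TestEddpClearanceFit:
    def test_round_trip_recovers_rcleddp(self, default_params):
        truth = default_params.updated({"RCLeddp": 10.0})
        res = simulate(truth.updated({"BW": 64.7}), DoseRegimen(57.5),
                       until_steady_state=True)
        target = steady_state_metrics(res, "eddp").Cmax_blood_uM
        fitted = fit_eddp_clearance(default_params, 57.5, 64.7, target,
                                    free_param="RCLeddp")
        assert fitted.RCLeddp == pytest.approx(10.0, rel=0.01)
        assert fitted.kbile == default_params.clearance.kbile

    def test_fixed_point_returns_current_value(self, default_params):
        res = simulate(default_params.updated({"BW": 64.7}), DoseRegimen(57.5),
                       until_steady_state=True)
        target = steady_state_metrics(res, "eddp").Cmax_blood_uM
        fitted = fit_eddp_clearance(default_params, 57.5, 64.7, target)
        assert fitted.RCLeddp == pytest.approx(19.99, rel=0.01)

    def test_joint_fit_rejected_as_underdetermined(self, default_params):
        with pytest.raises(ValueError, match="under-determined"):
            fit_eddp_clearance(default_params, 57.5, 64.7, 0.1,
                               free_param="both")

    def test_unreachable_target_diagnosed(self, default_params):
        with pytest.raises(ValueError, match="not reachable"):
            fit_eddp_clearance(default_params, 57.5, 64.7, 1e6,
                               free_param="kbile", bounds=(1.0, 10.0))
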