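import numpy as np
import pytest

from qivive.mea import concentration_response, wells_to_frame
from qivive.pbk import fold_difference
from qivive.synthetic import (ClinicalPkConfig, MeaCrcConfig,
                              MmIncubationConfig, RedAssayConfig,
                              gen_clinical_pk, gen_mea_crc,
                              gen_mm_incubation, gen_red_assay,
                              hill_ec50_for_effect, hill_response)


class TestDeterminism:
    def test_mea_same_seed_identical(self):
        a = wells_to_frame(gen_mea_crc(MeaCrcConfig(seed=11))[0])
        b = wells_to_frame(gen_mea_crc(MeaCrcConfig(seed=11))[0])
        assert a.equals(b)

    def test_mea_different_seed_differs(self):
        a = wells_to_frame(gen_mea_crc(MeaCrcConfig(seed=11))[0])
        b = wells_to_frame(gen_mea_crc(MeaCrcConfig(seed=12))[0])
        assert not a.equals(b)

    def test_mm_and_red_and_pk_deterministic(self):
        a, _ = gen_mm_incubation(MmIncubationConfig(seed=2))
        b, _ = gen_mm_incubation(MmIncubationConfig(seed=2))
        assert np.array_equal(a.rate_nmol_min_mg, b.rate_nmol_min_mg)
        ra, _ = gen_red_assay(RedAssayConfig(seed=2))
        rb, _ = gen_red_assay(RedAssayConfig(seed=2))
        assert [m.buffer_conc for m in ra] == [m.buffer_conc for m in rb]
        pa, _ = gen_clinical_pk(ClinicalPkConfig(seed=2, n_days=3))
        pb, _ = gen_clinical_pk(ClinicalPkConfig(seed=2, n_days=3))
        assert pa.equals(pb)


class TestTruthSidecars:
    def test_mea_truth_anchors_20pct_concentration(self):
        cfg = MeaCrcConfig(seed=0)
        truth = cfg.truth()
        assert truth["ec20_uM"] == pytest.approx(0.6, rel=1e-9)
        assert float(hill_response(truth["ec20_uM"], truth["emax"],
                                   truth["ec50"], truth["hill"])) == \
            pytest.approx(20.0, rel=1e-9)

    def test_ec50_anchor_solver(self):
        ec50 = hill_ec50_for_effect(20.0, 80.0, 1.5, 0.6)
        assert float(hill_response(0.6, 80.0, ec50, 1.5)) == pytest.approx(20.0)
        with pytest.raises(ValueError):
            hill_ec50_for_effect(90.0, 80.0, 1.5, 0.6)

    def test_zero_vmax_truth_gives_zero_rates(self):
        data, _ = gen_mm_incubation(MmIncubationConfig(seed=0, vmax=0.0))
        assert np.all(data.rate_nmol_min_mg == 0.0)

    def test_mm_truth_recorded(self):
        _, truth = gen_mm_incubation(MmIncubationConfig(seed=0))
        assert truth == {"vmax": 0.82, "km": 275.0, "noise_cv": 0.05}


class TestMeaStructure:
    def test_design_matches_assay_layout(self):
        cfg = MeaCrcConfig(seed=3)
        wells, _ = gen_mea_crc(cfg)
        df = wells_to_frame(wells)
        assert df.experiment.nunique() == cfg.n_experiments
        treated = df[df.well != "vehicle"]
        assert treated.well.nunique() == cfg.treated_wells_per_experiment
        # vehicle wells never see compound
        assert (df[df.well == "vehicle"].conc_uM == 0).all()
        # irregularity flags start at the configured concentration
        flagged = df[df.irregularity != ""]
        assert flagged.conc_uM.min() == cfg.irregular_from_uM
        assert set(df[df.conc_uM >= cfg.arrest_at_uM].irregularity) == \
            {"beating_arrest"}

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            MeaCrcConfig(seed=0, concentrations=(0.0, 1.0))


class TestClinicalPk:
    def test_unperturbed_noise_free_fold_difference_is_one(self,
                                                           default_params):
        from qivive.parameters import DoseRegimen
        from qivive.pbk import simulate, steady_state_metrics

        cfg = ClinicalPkConfig(seed=0, perturb_fraction=0.0, noise_cv=0.0,
                               n_days=12)
        df, truth = gen_clinical_pk(cfg)
        params = default_params.updated({"BW": cfg.bw})
        res = simulate(params, DoseRegimen(cfg.dose_mg_per_day,
                                           n_days=cfg.n_days))
        m = steady_state_metrics(res)
        observed_cmax_blood = (df.plasma_ng_per_ml.max()
                               * default_params.methadone.BPr)
        # 13 samples over the dosing day resolve the peak to ~1%, so the
        # fold difference is 1.00 at that resolution
        assert fold_difference(m.Cmax_blood_ng_per_ml,
                               observed_cmax_blood) == pytest.approx(1.0,
                                                                     rel=0.01)
        assert all(f == 1.0 for f in truth["perturbation_factors"].values())

    def test_perturbed_fold_difference_within_documented_bounds(self):
        """With +/-20% parameter perturbations and 10% assay noise the
        predicted/observed Cmax ratio stays within ~2-fold."""
        from qivive.parameters import DoseRegimen, build_default_model
        from qivive.pbk import simulate, steady_state_metrics

        cfg = ClinicalPkConfig(seed=5, n_days=12)
        df, _ = gen_clinical_pk(cfg)
        params = build_default_model().updated({"BW": cfg.bw})
        res = simulate(params, DoseRegimen(cfg.dose_mg_per_day,
                                           n_days=cfg.n_days))
        m = steady_state_metrics(res)
        obs = df.plasma_ng_per_ml.max() * params.methadone.BPr
        assert 0.5 < fold_difference(m.Cmax_blood_ng_per_ml, obs) < 2.0


def test_noise_free_mea_pipeline_recovers_truth_curve():
    wells, truth = gen_mea_crc(MeaCrcConfig(seed=9, response_noise_cv=0.0))
    crc = concentration_response(wells)
    expected = 100.0 + hill_response(crc.concentrations[1:], truth["emax"],
                                     truth["ec50"], truth["hill"])
    assert np.allclose(crc.response_mean[1:], expected, atol=1e-9)
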