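"""Diagnostics: decline classifier, GOF, pcVPC and NPDE behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cardiopd as cpd
from cardiopd.datasets import DoseEvent, ObservationRecord
from cardiopd.diagnostics import (classify_lvef_decline, gof_table, npde,
                                  pcvpc)
from cardiopd.models import ConstantMeanModel, TroponinModel


class TestClassifyLvefDecline:
    @pytest.mark.parametrize("baseline,series,expected", [
        (0.60, [0.44], True),            # below the 45% floor
        (0.60, [0.46], False),           # drop 14 points, above floor
        (0.62, [0.47], True),            # drop of exactly 15 points counts
        (0.62, [0.471], False),          # one-tenth point short
        (0.70, [0.68, 0.52, 0.66], True),   # any follow-up can trigger (drop 18)
        (0.50, [0.50, 0.49, 0.46], False),
    ])
    def test_rule(self, baseline, series, expected):
        assert classify_lvef_decline(baseline, series) is expected

    def test_validates_range(self):
        with pytest.raises(ValueError):
            classify_lvef_decline(0.6, [1.2])
        with pytest.raises(ValueError):
            classify_lvef_decline(0.0, [0.5])
        with pytest.raises(ValueError):
            classify_lvef_decline(0.6, [])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(baseline=st.floats(0.4, 0.8),
           series=st.lists(st.floats(0.2, 0.8), min_size=1, max_size=8),
           drop=st.floats(0.001, 0.2))
    def test_monotone_in_followup_values(self, baseline, series, drop):
        """Lowering any follow-up value never flips a positive call."""
        if classify_lvef_decline(baseline, series):
            lowered = [max(v - drop, 0.01) for v in series]
            assert classify_lvef_decline(baseline, lowered)


@pytest.fixture(scope="module")
def calibrated_setup():
    """30-subject troponin model with data simulated from itself."""
    trial = cpd.simulate_trial(cpd.TrialDesign(n_subjects=30), seed=17)
    from cardiopd.models import CovariateEffect
    eff = CovariateEffect("type_effect", "slope", "binary_power",
                          "anthracycline_type")
    model = TroponinModel(trial.doses, trial.observations,
                          trial.covariates_frame, [eff])
    theta = {"trp0": 4.7, "ke": 8.49e-3, "slope": 8.84e-3, "type_effect": 0.524}
    omega = cpd.OmegaMatrix.from_cv(("trp0", "slope"), [39.2, 57.7])
    sigma = cpd.SigmaParams(sd=0.301)
    return model, theta, omega, sigma


class TestPcVpc:
    def test_self_simulated_medians_inside_bands(self, calibrated_setup):
        """Pooled over eight small cohorts, the observed bin medians fall
        inside the simulated 95% bands about 95% of the time.  (A single
        30-subject cohort shares its eta draws across all bins, so its
        band exceedances are strongly correlated; pooling cohorts restores
        the nominal rate.)"""
        theta, omega, sigma = calibrated_setup[1:]
        from cardiopd.models import CovariateEffect
        eff = CovariateEffect("type_effect", "slope", "binary_power",
                              "anthracycline_type")
        inside, total = 0, 0
        for seed in range(10, 18):
            trial = cpd.simulate_trial(cpd.TrialDesign(n_subjects=30), seed=seed)
            model = TroponinModel(trial.doses, trial.observations,
                                  trial.covariates_frame, [eff])
            t = pcvpc(model, theta, omega, sigma, n_sim=200, seed=5,
                      lloq=3.0).table
            ok = ((t["obs_p50"] >= t["sim_p50_lo"])
                  & (t["obs_p50"] <= t["sim_p50_hi"]))
            inside += int(ok.sum())
            total += len(t)
            assert (t["obs_p5"] <= t["obs_p50"]).all()
            assert (t["obs_p50"] <= t["obs_p95"]).all()
        assert inside / total >= 0.85

    def test_two_replicates_give_minmax_bands(self, calibrated_setup):
        model, theta, omega, sigma = calibrated_setup
        res = pcvpc(model, theta, omega, sigma, n_sim=2, seed=5)
        t = res.table
        assert (t["sim_p50_lo"] <= t["sim_p50_hi"]).all()
        assert res.n_sim == 2

    def test_single_replicate_rejected(self, calibrated_setup):
        model, theta, omega, sigma = calibrated_setup
        with pytest.raises(ValueError, match="n_sim"):
            pcvpc(model, theta, omega, sigma, n_sim=1)

    def test_exact_model_identical_observations_zero_width(self):
        """All observations identical + no variability: every percentile
        equals the single value and the bands have zero width."""
        obs = [ObservationRecord(f"S{i}", 0.0, "troponin_t", 5.0)
               for i in range(8)]
        model = ConstantMeanModel(obs)
        theta = {"mu": 5.0}
        omega = cpd.OmegaMatrix.diagonal(("mu",), [0.0])
        sigma = cpd.SigmaParams(sd=1e-12, kind="additive")
        res = pcvpc(model, theta, omega, sigma, n_sim=10, seed=1)
        t = res.table
        assert np.allclose(t[["obs_p5", "obs_p50", "obs_p95"]], 5.0)
        assert np.allclose(t["sim_p50_hi"] - t["sim_p50_lo"], 0.0, atol=1e-9)


class TestNpde:
    def test_self_simulated_calibration(self, full_trial, calibrated_setup):
        """NPDE of data simulated from the model is standard normal.

        Checked on the full 206-subject design; the variance tolerance is
        slightly wider than the iid sampling error because within-subject
        eta draws correlate the per-observation errors."""
        theta, omega, sigma = calibrated_setup[1:]
        from cardiopd.models import CovariateEffect
        eff = CovariateEffect("type_effect", "slope", "binary_power",
                              "anthracycline_type")
        model = TroponinModel(full_trial.doses, full_trial.observations,
                              full_trial.covariates_frame, [eff])
        res = npde(model, theta, omega, sigma, n_sim=1000, seed=23, lloq=3.0)
        n = model.n_obs
        assert abs(res.mean) < 3.0 / np.sqrt(n)
        assert res.variance == pytest.approx(1.0, abs=0.15)
        assert res.decorrelated

    def test_observation_above_all_simulations_hits_rank_guard(self):
        obs = [ObservationRecord("A", 0.0, "troponin_t", 100.0)]
        model = ConstantMeanModel(obs)
        theta = {"mu": 5.0}
        omega = cpd.OmegaMatrix.diagonal(("mu",), [0.01])
        sigma = cpd.SigmaParams(sd=0.5, kind="additive")
        res = npde(model, theta, omega, sigma, n_sim=100, seed=3)
        from scipy.stats import norm
        assert res.npde[0] == pytest.approx(norm.ppf(100 / 101))

    def test_single_observation_centered_on_simulations(self):
        obs = [ObservationRecord("A", 0.0, "troponin_t", 5.0)]
        model = ConstantMeanModel(obs)
        res = npde(model, {"mu": 5.0}, cpd.OmegaMatrix.diagonal(("mu",), [0.04]),
                   cpd.SigmaParams(sd=0.5, kind="additive"), n_sim=2000, seed=7)
        assert abs(res.npde[0]) < 0.1


class TestGofTable:
    def test_perfect_noiseless_fit_has_zero_iwres(self):
        """With noise-free data and a small residual SD the EBEs sit at the
        truth, so individual predictions reproduce the observations.  (At
        large proportional sigma the posterior mode shifts slightly because
        the residual variance itself depends on the prediction.)"""
        doses = [DoseEvent("A", 0.0, "doxorubicin", 100.0)]
        theta = {"trp0": 4.7, "ke": 8.49e-3, "slope": 8.84e-3}
        from cardiopd.exposure import KPDParams, anthracycline_amount
        obs = []
        for t in (0.0, 21.0, 42.0):
            a = anthracycline_amount(doses, KPDParams(theta["ke"]), t)
            obs.append(ObservationRecord("A", t, "troponin_t",
                                         4.7 * (1 + theta["slope"] * a)))
        model = TroponinModel(doses, obs, pd.DataFrame({"ID": ["A"], "ACTYPE": [0]}))
        omega = cpd.OmegaMatrix.diagonal(("trp0", "slope"), [0.1, 0.1])
        table = gof_table(model, theta, omega, cpd.SigmaParams(sd=1e-3))
        assert np.allclose(table["observed"], table["ipred"], rtol=1e-5)
        assert np.allclose(table["iwres"], 0.0, atol=1e-2)
        # eta = 0 data: population and individual predictions coincide
        assert np.allclose(table["pred"], table["ipred"], rtol=1e-5)

    def test_iwres_sd_near_one_under_correct_sigma(self, calibrated_setup):
        model, theta, omega, sigma = calibrated_setup
        table = gof_table(model, theta, omega, sigma)
        assert np.std(table["iwres"], ddof=1) == pytest.approx(1.0, abs=0.15)
        assert len(table) == model.n_obs
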