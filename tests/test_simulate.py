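"""Synthetic trial generator: determinism, design fidelity, latent truth."""

import collections
import dataclasses

import numpy as np
import pytest

import cardiopd as cpd
from cardiopd.datasets import (DOXORUBICIN, EPIRUBICIN, LVEF, NTPROBNP,
                               TRASTUZUMAB, TROPONIN_T)
from cardiopd.exposure import KPDParams
from cardiopd.simulate import (TrialDesign, TruthParameters, simulate_dropout,
                               simulate_trial)
from cardiopd.structural import TroponinParams, predicted_trpmax


def test_fixed_seed_reproduces_dataset_exactly(tmp_path):
    a = simulate_trial(TrialDesign(n_subjects=12), seed=9)
    b = simulate_trial(TrialDesign(n_subjects=12), seed=9)
    assert [(d.subject_id, d.time, d.amount) for d in a.doses] == \
           [(d.subject_id, d.time, d.amount) for d in b.doses]
    assert [(o.subject_id, o.time, o.value) for o in a.observations] == \
           [(o.subject_id, o.time, o.value) for o in b.observations]
    # byte-identical CSV output
    from cardiopd.datasets import write_dataset
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_dataset(pa, a.doses, a.observations, a.covariates_frame)
    write_dataset(pb, b.doses, b.observations, b.covariates_frame)
    assert pa.read_bytes() == pb.read_bytes()


def test_subject_substreams_stable_under_cohort_growth():
    small = simulate_trial(TrialDesign(n_subjects=5), seed=9)
    large = simulate_trial(TrialDesign(n_subjects=15), seed=9)
    small_obs = [(o.subject_id, o.time, o.value) for o in small.observations]
    large_obs = [(o.subject_id, o.time, o.value) for o in large.observations
                 if o.subject_id in {c.subject_id for c in small.covariates}]
    assert small_obs == large_obs


def test_zero_variability_reproduces_structural_predictions(truth):
    noiseless = dataclasses.replace(
        truth,
        troponin_omega=cpd.OmegaMatrix.diagonal(("trp0", "slope"), [0, 0]),
        lvef_omega=cpd.OmegaMatrix.diagonal(("lvef0", "ec50"), [0, 0]),
        troponin_sigma=cpd.SigmaParams(sd=1e-12),
        lvef_sigma=cpd.SigmaParams(sd=1e-12))
    trial = simulate_trial(TrialDesign(n_subjects=4), noiseless, seed=3)
    from cardiopd.exposure import anthracycline_amount
    from cardiopd.structural import troponin_prediction
    for cov in trial.covariates:
        sid = cov.subject_id
        ant = [d for d in trial.doses
               if d.subject_id == sid and d.drug != TRASTUZUMAB]
        for o in trial.observations:
            if o.subject_id != sid or o.biomarker != TROPONIN_T or o.below_lloq:
                continue
            a = anthracycline_amount(sorted(ant, key=lambda d: d.time),
                                     noiseless.kpd, o.time)
            expect = troponin_prediction(a, noiseless.troponin,
                                         cov.anthracycline_type)
            assert o.value == pytest.approx(expect, rel=1e-9)


def test_visit_structure_matches_protocol(full_trial):
    """Troponin/NT-proBNP have 10 scheduled samples, LVEF 8 (no week-3 or
    week-64 visit)."""
    per_subject = collections.defaultdict(collections.Counter)
    for o in full_trial.observations:
        per_subject[o.subject_id][o.biomarker] += 1
    for counts in per_subject.values():
        assert counts[TROPONIN_T] == 10
        assert counts[NTPROBNP] == 10
        assert counts[LVEF] == 8
    assert len(per_subject) == 206


def test_design_distributions_roughly_match_cohort(full_trial):
    covs = full_trial.covariates
    p_dox = np.mean([c.anthracycline_type == DOXORUBICIN for c in covs])
    assert p_dox == pytest.approx(0.879, abs=0.06)
    cycles = collections.Counter()
    doses_by = collections.defaultdict(list)
    for d in full_trial.doses:
        if d.drug in (DOXORUBICIN, EPIRUBICIN):
            doses_by[d.subject_id].append(d)
    n_cycles = [len(v) for v in doses_by.values()]
    assert int(np.median(n_cycles)) == 4
    assert min(n_cycles) >= 2 and max(n_cycles) <= 6
    for subj in doses_by.values():
        rng_ok = (75 <= min(d.amount for d in subj)
                  and max(d.amount for d in subj) <= 200)
        assert rng_ok
    weekly_frac = np.mean([
        len([d for d in full_trial.doses
             if d.subject_id == c.subject_id and d.drug == TRASTUZUMAB]) > 30
        for c in covs])
    assert weekly_frac == pytest.approx(144 / 206, abs=0.07)


def test_latent_truth_reproduces_trpmax_without_refitting(full_trial, truth):
    """The latent table's individual parameters give back the recorded
    troponin peak exactly (the oracle for covariate-linkage tests)."""
    lat = full_trial.latent.set_index("ID")
    covs = {c.subject_id: c for c in full_trial.covariates}
    for sid in list(lat.index)[:20]:
        row = lat.loc[sid]
        params = TroponinParams(trp0=row["trp0_i"], slope=row["slope_i"],
                                type_effect=truth.troponin.type_effect)
        ant = sorted((d for d in full_trial.doses
                      if d.subject_id == sid and d.drug != TRASTUZUMAB),
                     key=lambda d: d.time)
        got = predicted_trpmax(ant, params, truth.kpd,
                               covs[sid].anthracycline_type)
        assert got == pytest.approx(row["trp_max"], rel=1e-9)


def test_median_troponin_rises_then_decays(full_trial):
    """Qualitative trajectory: the cohort median troponin T is above
    baseline right after anthracyclines and relaxes back during
    trastuzumab follow-up."""
    lat = full_trial.latent.set_index("ID")
    baseline, early, late = [], [], []
    for o in full_trial.observations:
        if o.biomarker != TROPONIN_T:
            continue
        t_start = lat.loc[o.subject_id, "t_trastuzumab_start"]
        if o.time == 0.0:
            baseline.append(o.value)
        elif abs(o.time - t_start) < 1e-9:
            early.append(o.value)
        elif o.time > t_start + 500:
            late.append(o.value)
    assert np.median(early) > 2.0 * np.median(baseline)
    assert np.median(late) < 1.5 * np.median(baseline)


def test_blq_fraction_small_but_present(full_trial):
    trop = [o for o in full_trial.observations if o.biomarker == TROPONIN_T]
    frac = np.mean([o.below_lloq for o in trop])
    assert 0.0 < frac < 0.2
    for o in trop:
        if o.below_lloq:
            assert o.value == pytest.approx(1.5)


class TestDropout:
    def test_disabled_rule_returns_input_unchanged(self, small_trial):
        out = simulate_dropout(small_trial, enabled=False)
        assert out is small_trial

    def test_decliners_lose_subsequent_doses_and_lvef(self):
        truth = TruthParameters.published_estimates()
        sensitive = dataclasses.replace(
            truth, lvef=dataclasses.replace(truth.lvef, ec50=2.18e3))
        trial = simulate_trial(TrialDesign(n_subjects=40), sensitive, seed=21)
        out = simulate_dropout(trial)
        assert len(out.observations) < len(trial.observations)
        # after a subject's cutoff there are no trastuzumab doses or LVEF rows
        lost = {o.subject_id for o in trial.observations} - {
            o.subject_id for o in out.observations if o.biomarker == LVEF}
        dropped_subjects = set()
        for sid in {c.subject_id for c in trial.covariates}:
            before = [o for o in trial.observations
                      if o.subject_id == sid and o.biomarker == LVEF]
            after = [o for o in out.observations
                     if o.subject_id == sid and o.biomarker == LVEF]
            if len(after) < len(before):
                dropped_subjects.add(sid)
                t_cut = max(o.time for o in after)
                for d in out.doses:
                    if d.subject_id == sid and d.drug == TRASTUZUMAB:
                        assert d.time <= t_cut + 1e-9 or d.time <= min(
                            o.time for o in before[1:])
        assert dropped_subjects

    def test_insensitive_population_has_no_dropout(self):
        truth = TruthParameters.published_estimates()
        insensitive = dataclasses.replace(
            truth, lvef=dataclasses.replace(truth.lvef, ec50=1e12),
            lvef_omega=cpd.OmegaMatrix.diagonal(("lvef0", "ec50"), [0.001, 0]),
            lvef_sigma=cpd.SigmaParams(sd=0.01))
        trial = simulate_trial(TrialDesign(n_subjects=30), insensitive, seed=2)
        out = simulate_dropout(trial)
        assert len(out.observations) == len(trial.observations)
        assert len(out.doses) == len(trial.doses)


def test_invalid_design_rejected():
    with pytest.raises(ValueError):
        TrialDesign(n_subjects=0)
    with pytest.raises(ValueError):
        TrialDesign(cycle_probs=(0.5, 0.2, 0.1, 0.1, 0.05))
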