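"""Whole-body ODE engine: mass balance, oracles, populations, trials."""

import dataclasses
import warnings

import numpy as np
import pytest

from diazepbpk.absorption import bioavailability_components, build_dose_input
from diazepbpk.clearance import well_stirred_clh
from diazepbpk.config import Route
from diazepbpk.engine import (
    PopulationSummary, PopulationVariability, load_reference_physiology,
    reference_individual, run_trial, sample_individual, simulate_profile,
)
from diazepbpk.nca import ConcentrationTimeProfile, nca
from diazepbpk.partition import TISSUES

NO_VARIABILITY = PopulationVariability(
    cv_abundance=0.0, cv_flow=0.0, cv_kp=0.0, cv_weight_when_mean_only=0.0)


def plasma_referenced_vss(individual, drug, kp):
    """Analytic Vss (L) against venous plasma for the flow model."""
    blood = (individual.venous_volume + individual.arterial_volume) * drug.bp_ratio
    tissues = sum(kp[t] * individual.tissue_volumes[t] for t in TISSUES)
    return blood + tissues


class TestSimulateProfile:
    def test_mass_balance_every_route(self, drug, study_library, kp):
        ind = reference_individual()
        for label in ("iv_2mg", "oral_10mg", "intranasal_10mg_solution",
                      "rectal_10mg_suppository"):
            study = study_library[label]
            res = simulate_profile(ind, drug, build_dose_input(study, drug),
                                   study.sampling_times, kp=kp)
            assert res.mass_balance_residual < 1e-6

    def test_conservation_without_elimination(self, drug, study_library, kp):
        ind = reference_individual()
        study = study_library["iv_2mg"]
        res = simulate_profile(ind, drug, build_dose_input(study, drug),
                               study.sampling_times, kp=kp, linear_clearance=0.0)
        total = sum(res.compartment_amounts[c] for c in res.compartment_amounts)
        assert np.all(np.abs(total - 2e6) < 2e6 * 1e-7)
        assert res.eliminated[-1] == pytest.approx(0.0, abs=1e-3)

    def test_one_compartment_collapse_matches_exponential(self, drug, kp,
                                                          study_library):
        # flows blown up 1e4-fold equilibrate the whole body instantly, so
        # the system collapses to a single well-mixed volume with
        # first-order hepatic loss; compare with C0 exp(-kt) pointwise
        ind = reference_individual()
        flows = {t: q * 1e4 for t, q in ind.blood_flows.items()}
        ind = dataclasses.replace(ind, blood_flows=flows,
                                  cardiac_output=sum(flows.values()))
        clint_u = 50.0  # L/h, restrictive regime
        study = study_library["iv_10mg"]
        # start after the (instantaneous) venous bolus has equilibrated
        times = np.linspace(0.5, 48.0, 30)
        res = simulate_profile(ind, drug, build_dose_input(study, drug), times,
                               kp=kp, linear_clearance=clint_u)
        v_eff_blood = (ind.venous_volume + ind.arterial_volume
                       + sum(kp[t] * ind.tissue_volumes[t] for t in TISSUES)
                       / drug.bp_ratio)
        k = (drug.fu_plasma / drug.bp_ratio) * clint_u / v_eff_blood
        c0 = 1e7 / v_eff_blood / drug.bp_ratio / 1000.0  # ng/mL plasma
        expected = c0 * np.exp(-k * times)
        assert res.plasma_conc == pytest.approx(expected, rel=1e-3)

    def test_dose_linearity(self, drug, study_library, kp):
        # therapeutic concentrations sit far below every Km, so doubling
        # the dose must double the whole profile
        ind = reference_individual()
        study2 = study_library["iv_2mg"]
        study4 = study2.model_copy(update={"dose": 4.0})
        r2 = simulate_profile(ind, drug, build_dose_input(study2, drug),
                              study2.sampling_times, kp=kp)
        r4 = simulate_profile(ind, drug, build_dose_input(study4, drug),
                              study2.sampling_times, kp=kp)
        assert r4.plasma_conc == pytest.approx(2 * r2.plasma_conc, rel=0.01)

    def test_moment_vss_matches_analytic(self, drug, study_library, kp):
        ind = reference_individual()
        study = study_library["iv_10mg"]
        times = np.concatenate([[0.0], np.geomspace(0.01, 240.0, 200)])
        res = simulate_profile(ind, drug, build_dose_input(study, drug),
                               times, kp=kp)
        c = res.plasma_conc
        auc = np.trapezoid(c, times)
        aumc = np.trapezoid(c * times, times)
        cl = 1e7 / (auc * 1000.0)          # L/h vs plasma
        vss_moment = cl * aumc / auc * 1000.0 / 1000.0  # L
        assert vss_moment == pytest.approx(
            plasma_referenced_vss(ind, drug, kp), rel=0.05)

    def test_iv_clearance_matches_well_stirred(self, drug, study_library, kp):
        ind = reference_individual()
        study = study_library["iv_10mg"]
        times = np.concatenate([[0.0], np.geomspace(0.01, 240.0, 200)])
        res = simulate_profile(ind, drug, build_dose_input(study, drug),
                               times, kp=kp)
        auc = np.trapezoid(res.plasma_conc, times)  # essentially AUCinf
        cl_sim = 1e7 / auc / 1000.0
        from diazepbpk.clearance import (DEFAULT_ABUNDANCES, whole_liver_clint)
        clint = whole_liver_clint(drug.enzyme_kinetics, DEFAULT_ABUNDANCES,
                                  drug.fu_mic, ind.liver_scaling.mppgl,
                                  ind.liver_scaling.liver_weight)
        clh_blood = well_stirred_clh(ind.liver_blood_flow,
                                     drug.fu_plasma / drug.bp_ratio, clint)
        assert cl_sim == pytest.approx(clh_blood * drug.bp_ratio, rel=0.05)

    def test_clearance_scales_with_fu_in_restrictive_regime(self, drug,
                                                            study_library, kp):
        ind = reference_individual()
        study = study_library["iv_10mg"]
        times = np.concatenate([[0.0], np.geomspace(0.01, 240.0, 120)])
        drug_hi = drug.model_copy(update={"fu_plasma": drug.fu_plasma * 2})
        aucs = {}
        clint_u = 50.0  # L/h: fu_b*clint << Q_h, restrictive regime
        for d in (drug, drug_hi):
            res = simulate_profile(ind, d, build_dose_input(study, d), times,
                                   kp=kp, linear_clearance=clint_u)
            aucs[d.fu_plasma] = np.trapezoid(res.plasma_conc, times)
        cl_ratio = aucs[drug_hi.fu_plasma] / aucs[drug.fu_plasma]
        assert cl_ratio == pytest.approx(0.5, rel=0.05)


class TestPopulation:
    def test_flow_sum_equals_cardiac_output(self):
        ind = reference_individual()
        assert sum(ind.blood_flows.values()) == pytest.approx(ind.cardiac_output)

    def test_sex_sampling_respects_proportion(self, study_library):
        rng = np.random.default_rng(0)
        males = study_library["intranasal_2mg"]        # female proportion 0
        assert all(sample_individual(males, rng).sex == "male" for _ in range(20))
        females = males.model_copy(update={"female_proportion": 1.0})
        assert all(sample_individual(females, rng).sex == "female"
                   for _ in range(20))

    def test_weight_sampled_within_range(self, study_library):
        rng = np.random.default_rng(1)
        study = study_library["iv_2mg"]  # 58-80 kg
        for _ in range(20):
            ind = sample_individual(study, rng)
            assert 58 <= ind.body_weight <= 80

    def test_missing_weight_falls_back_with_warning(self, study_library):
        study = study_library["oral_2mg"]  # no weight data compiled
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="weight"):
            ind = sample_individual(study, rng)
        assert ind.body_weight > 0

    def test_same_stream_reproduces_subject(self, study_library):
        study = study_library["iv_5mg_b"]
        a = sample_individual(study, np.random.default_rng(42))
        b = sample_individual(study, np.random.default_rng(42))
        assert a == b


class TestRunTrial:
    def test_single_subject_summary_degenerates(self, drug, study_library):
        summary, results = run_trial(study_library["iv_2mg"], drug,
                                     n_virtual=1, seed=3)
        assert summary.n == 1
        np.testing.assert_allclose(summary.mean, summary.p5)
        np.testing.assert_allclose(summary.p95, summary.maximum)

    def test_zero_variability_collapses_population(self, drug, study_library):
        study = study_library["iv_7p5mg"]  # mean-only weight
        summary, results = run_trial(study, drug, n_virtual=4, seed=3,
                                     variability=NO_VARIABILITY)
        np.testing.assert_allclose(summary.minimum, summary.maximum, rtol=1e-10)

    def test_trials_are_deterministic(self, drug, study_library):
        s1, r1 = run_trial(study_library["oral_5mg"], drug, n_virtual=5, seed=11)
        s2, r2 = run_trial(study_library["oral_5mg"], drug, n_virtual=5, seed=11)
        assert np.array_equal(s1.mean, s2.mean)
        assert np.array_equal(r1[3].plasma_conc, r2[3].plasma_conc)

    def test_summary_ordering_enforced(self):
        t = np.array([0.0, 1.0])
        good = dict(times=t, mean=np.array([2.0, 2.0]), p5=np.array([1.0, 1.0]),
                    p95=np.array([3.0, 3.0]), minimum=np.array([0.5, 0.5]),
                    maximum=np.array([4.0, 4.0]), n=5, seed=1)
        PopulationSummary(**good)
        bad = dict(good, p5=np.array([3.5, 3.5]))
        with pytest.raises(ValueError, match="ordering"):
            PopulationSummary(**bad)

    def test_rejects_empty_population(self, drug, study_library):
        with pytest.raises(ValueError):
            run_trial(study_library["iv_2mg"], drug, n_virtual=0, seed=1)

    def test_overlay_plot_renders(self, drug, study_library):
        import matplotlib
        matplotlib.use("Agg")
        from diazepbpk.engine import plot_trial_summary
        summary, _ = run_trial(study_library["iv_2mg"], drug, n_virtual=2, seed=1)
        ax = plot_trial_summary(summary, title="iv_2mg")
        assert ax.get_ylabel().startswith("plasma")

    def test_iv_10mg_auc_within_twofold_of_reference_prediction(
            self, drug, study_library):
        summary, results = run_trial(study_library["iv_10mg"], drug,
                                     n_virtual=20, seed=5)
        aucs = [nca(ConcentrationTimeProfile(times=r.times, conc=r.plasma_conc,
                                             dose=10.0, route="iv")).auc_0_t
                for r in results]
        mean_auc = float(np.mean(aucs))
        assert 4364.79 / 2 <= mean_auc <= 4364.79 * 2
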