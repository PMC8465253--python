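"""NCA and model-qualification statistics against the compiled PK table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diazepbpk.nca import (
    ConcentrationTimeProfile, afe, build_summary_table, load_observed_predicted,
    mean_ratio_ci, nca, obs_pred_ratio, rows_from_table, twofold_check,
)
from diazepbpk.synthetic import SyntheticStudySpec, two_compartment_conc


@pytest.fixture(scope="module")
def pk_table():
    return load_observed_predicted()


@pytest.fixture(scope="module")
def pk_rows(pk_table):
    return rows_from_table(pk_table)


def ratios_for(rows, route, parameter):
    return [r.ratio for r in rows if r.route == route and r.parameter == parameter]


class TestNca:
    def test_trapezoid_example(self):
        p = nca(ConcentrationTimeProfile(times=[0, 1, 2], conc=[100, 50, 25],
                                         dose=1.0))
        assert p.cmax == 100
        assert p.tmax == 0
        assert p.auc_0_t == pytest.approx(112.5)

    @pytest.mark.parametrize("dose,auc,cl", [(10, 4364.79, 2.29),
                                             (5, 522.20, 9.57)])
    def test_clearance_convention(self, dose, auc, cl):
        # CL = dose/AUC0-t with mg and ng.h/mL -> L/h conversion
        times = np.array([0.0, 1.0, 2.0])
        conc = np.array([auc, auc, auc]) / 2.0  # rectangle of area auc
        p = nca(ConcentrationTimeProfile(times=times, conc=conc, dose=dose))
        assert round(p.cl, 2) == cl

    def test_terminal_extrapolation_recovers_exponential(self):
        t = np.linspace(0, 48, 25)
        c = 100 * np.exp(-0.1 * t)
        p = nca(ConcentrationTimeProfile(times=t, conc=c, dose=1.0))
        assert p.lambda_z == pytest.approx(0.1, rel=1e-6)
        assert p.t_half == pytest.approx(np.log(2) / 0.1, rel=1e-6)
        assert p.auc_inf == pytest.approx(1000.0, rel=0.01)
        assert p.auc_inf >= p.auc_0_t

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationTimeProfile(times=[0, 1], conc=[1, 1], dose=1.0)

    def test_analytic_two_compartment_auc_recovered(self):
        # dense noise-free trapezoid vs the closed-form AUCinf = F*D/CL
        spec = SyntheticStudySpec(route="iv", dose=10.0)
        t = np.concatenate([[0.0], np.geomspace(1e-3, 400.0, 3000)])
        c = two_compartment_conc(spec, t)
        auc = np.trapezoid(c, t)
        assert auc == pytest.approx(10.0 * 1e6 / spec.cl_true / 1000.0, rel=0.005)


class TestRatioStatistics:
    def test_ratio_examples(self):
        assert round(obs_pred_ratio(285.45, 256.60), 2) == 1.11
        assert round(obs_pred_ratio(2070.02, 2028.11), 2) == 1.02
        assert obs_pred_ratio(3.7, 3.7) == 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            obs_pred_ratio(0.0, 1.0)
        with pytest.raises(ValueError):
            obs_pred_ratio(1.0, -2.0)

    def test_afe_basics(self):
        assert afe([1.0]) == 1.0
        assert afe([2.0, 0.5]) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            afe([])
        with pytest.raises(ValueError):
            afe([1.0, -1.0])

    def test_afe_inverse_symmetry(self):
        r = [1.11, 0.87, 0.65, 1.02]
        assert afe([1 / x for x in r]) == pytest.approx(1 / afe(r), rel=1e-12)

    @given(st.lists(st.floats(0.01, 100), min_size=1, max_size=20))
    @settings(max_examples=100, derandomize=True)
    def test_afe_never_exceeds_arithmetic_mean(self, ratios):
        assert afe(ratios) <= np.mean(ratios) * (1 + 1e-12)

    def test_iv_auc_afe_from_compiled_table(self, pk_rows):
        # geometric mean of the six IV AUC ratios
        assert round(afe(ratios_for(pk_rows, "iv", "auc_0_t")), 2) == 0.93

    def test_confidence_interval_iv_auc(self, pk_rows):
        mean, lo, hi = mean_ratio_ci(ratios_for(pk_rows, "iv", "auc_0_t"))
        assert (round(mean, 2), round(lo, 2), round(hi, 2)) == (0.94, 0.75, 1.13)

    def test_confidence_interval_rectal_cl(self, pk_rows):
        mean, lo, hi = mean_ratio_ci(ratios_for(pk_rows, "rectal", "cl"))
        assert mean == pytest.approx(0.85, abs=0.01)
        assert lo == pytest.approx(0.56, abs=0.01)
        assert hi == pytest.approx(1.13, abs=0.01)

    def test_constant_ratios_zero_width_interval(self):
        mean, lo, hi = mean_ratio_ci([1.07, 1.07, 1.07])
        assert mean == lo == hi == pytest.approx(1.07)

    def test_ci_needs_two_points(self):
        with pytest.raises(ValueError):
            mean_ratio_ci([1.0])

    def test_twofold_boundaries(self):
        assert twofold_check([0.5]) == (True, 2.0)
        ok, fold = twofold_check([0.4])
        assert not ok and fold == pytest.approx(2.5)

    def test_all_compiled_ratios_within_twofold(self, pk_rows):
        ok, max_fold = twofold_check([r.ratio for r in pk_rows])
        assert ok
        assert max_fold == pytest.approx(1.5326, abs=0.001)


# printed qualification table: (route, parameter) -> (mean ratio, AFE)
REFERENCE_SUMMARY = {
    ("iv", "auc_0_t"): (0.94, 0.93), ("iv", "cl"): (1.10, 1.08),
    ("iv", "cmax"): (0.96, 0.95),
    ("oral", "auc_0_t"): (0.90, 0.89), ("oral", "cl"): (1.15, 1.13),
    ("oral", "cmax"): (0.94, 0.93),
    ("intranasal", "auc_0_t"): (0.93, 0.92), ("intranasal", "cl"): (1.10, 1.09),
    ("intranasal", "cmax"): (0.92, 0.90),
    ("rectal", "auc_0_t"): (1.19, 1.18), ("rectal", "cl"): (0.85, 0.85),
    ("rectal", "cmax"): (1.18, 1.17),
}


class TestSummaryTable:
    def test_regenerates_reference_summary(self, pk_rows):
        summaries = {(s.route, s.parameter): s
                     for s in build_summary_table(pk_rows)}
        assert set(summaries) == set(REFERENCE_SUMMARY)
        for key, (mean_ref, afe_ref) in REFERENCE_SUMMARY.items():
            s = summaries[key]
            assert s.mean_ratio == pytest.approx(mean_ref, abs=0.01), key
            assert s.afe == pytest.approx(afe_ref, abs=0.01), key
            assert s.within_twofold

    def test_group_counts(self, pk_rows):
        summaries = {(s.route, s.parameter): s.n for s in build_summary_table(pk_rows)}
        assert summaries[("iv", "auc_0_t")] == 6
        assert summaries[("oral", "cl")] == 5
        assert summaries[("rectal", "cmax")] == 3

    def test_single_member_group_has_no_ci(self):
        from diazepbpk.nca import EvaluationRow
        rows = [EvaluationRow(route="iv", parameter="cmax",
                              observed=10.0, predicted=8.0)]
        s, = build_summary_table(rows)
        assert s.ci95_low is None and s.ci95_high is None
        assert s.mean_ratio == pytest.approx(1.25)

    def test_empty_input_gives_empty_table(self):
        assert build_summary_table([]) == []

    def test_cl_convention_against_predicted_columns(self, pk_table):
        # dose/AUC0-t must reproduce the compiled predicted CL column
        auc = pk_table[pk_table.parameter == "auc_0_t"].reset_index()
        cl = pk_table[pk_table.parameter == "cl"].reset_index()
        assert len(auc) == len(cl) == 20
        within = 0
        for (_, a), (_, c) in zip(auc.iterrows(), cl.iterrows()):
            implied = a.dose_mg * 1e6 / a.predicted / 1000.0
            if abs(implied - c.predicted) / c.predicted <= 0.01:
                within += 1
        assert within >= 18
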