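"""Non-compartmental analysis: exact fixtures, closed-form oracles, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkpgx import nca, synth
from pkpgx.nca import NonEvaluableProfile

from conftest import make_profile


class TestPreprocessBloq:
    def test_all_bloq_profile_is_non_evaluable(self):
        p = make_profile([0, 1, 2], [None, None, None])
        clean = nca.preprocess_bloq(p)
        assert len(clean.times) == 0
        with pytest.raises(NonEvaluableProfile):
            nca.run_nca(p)

    def test_predose_bloq_becomes_leading_zero(self):
        p = make_profile([0, 1, 2], [None, 50, 30])
        clean = nca.preprocess_bloq(p)
        assert clean.concentrations[0] == 0.0 and clean.times[0] == 0.0
        # leading zero contributes a triangle trapezoid
        assert nca.auc_trapezoidal(clean) == pytest.approx(0.5 * 50 + 0.5 * 80)

    def test_embedded_bloq_dropped_17_to_16_points(self):
        times = list(synth.DEFAULT_SCHEDULE)
        concs = [None] + [100.0] * 16
        concs[8] = None  # one embedded BLOQ
        clean = nca.preprocess_bloq(make_profile(times, concs))
        assert len(clean.times) == 16

    def test_trailing_bloq_truncated(self):
        p = make_profile([0, 1, 2, 3, 4], [None, 50, 30, None, None])
        clean = nca.preprocess_bloq(p)
        assert clean.times[-1] == 2.0


class TestCmaxTmax:
    @pytest.mark.parametrize(
        "times, concs, cmax, tmax",
        [
            ([1, 2, 4], [5, 9, 3], 9.0, 2.0),  # direct maximum
            ([2, 3], [9, 9], 9.0, 2.0),        # tie -> earliest
        ],
    )
    def test_direct_retrieval(self, times, concs, cmax, tmax):
        got = nca.cmax_tmax(make_profile(times, concs))
        assert got == (cmax, tmax)

    def test_tmax_approaches_model_mode_under_dense_sampling(self, valsartan_params):
        p = valsartan_params
        t = np.linspace(0, 48, 4000)
        prof = synth.simulate_profile(p, 160.0, t, error_cv=0.0)
        _, tmax = nca.cmax_tmax(nca.preprocess_bloq(prof))
        mode = math.log(p.ka / p.ke) / (p.ka - p.ke) + p.tlag
        assert tmax == pytest.approx(mode, abs=0.02)


class TestAUC:
    @pytest.mark.parametrize(
        "times, concs, expected",
        [
            ([0, 1, 2], [0, 10, 0], 10.0),        # triangle
            ([0, 1, 2, 3], [0, 10, 10, 0], 20.0), # trapezoid
        ],
    )
    def test_trapezoidal_fixtures(self, times, concs, expected):
        p = make_profile(times, concs, bloq=[False] * len(times))
        assert nca.auc_trapezoidal(p) == pytest.approx(expected)

    def test_dense_noise_free_profile_matches_analytic_integral(self, valsartan_params):
        from pkpgx.validation import trapezoid_vs_analytic

        assert trapezoid_vs_analytic(n_points=200) < 0.01

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(NonEvaluableProfile):
            nca.auc_trapezoidal(make_profile([0.0], [5.0], bloq=[False]))


class TestTerminalSlope:
    def test_exact_exponential_recovers_rate_constant(self):
        t = np.array([0, 1, 6, 8, 12, 24, 48], float)
        c = 100 * np.exp(-0.1 * t)
        c[1] = 150  # absorption peak at 1 h so the tail is post-tmax
        p = make_profile(t, c, bloq=[True] + [False] * 6)
        ke, n, adj = nca.terminal_slope(nca.preprocess_bloq(p))
        assert ke == pytest.approx(0.1, rel=1e-10)
        assert adj == pytest.approx(1.0, abs=1e-12)
        assert n == 5

    def test_half_life_definition(self):
        assert math.log(2) / 0.0866 == pytest.approx(8.0, abs=0.005)

    def test_rising_tail_is_non_evaluable(self):
        p = make_profile([0, 1, 2, 4, 8], [0, 10, 11, 12, 13], bloq=[True] + [False] * 4)
        with pytest.raises(NonEvaluableProfile):
            nca.terminal_slope(nca.preprocess_bloq(p))

    def test_ke_recovery_under_proportional_noise(self):
        # simulated profiles at assay CV 15%: median relative Ke error < 10%
        errs = []
        for i in range(200):
            rng = np.random.default_rng(1000 + i)
            params = synth.PKTrueParameters("valsartan", **synth.DRUG_PARAMS["valsartan"])
            prof = synth.simulate_profile(params, 160.0, error_cv=0.15, rng=rng)
            res = nca.run_nca(prof)
            errs.append(abs(res.ke - params.ke) / params.ke)
        assert np.median(errs) < 0.10


class TestExtrapolation:
    def test_stated_formula(self):
        auc_inf, pct, flag = nca.extrapolate_auc(100.0, 5.0, 0.1)
        assert auc_inf == pytest.approx(150.0)
        assert pct == pytest.approx(100 * 50 / 150)
        assert flag  # > 20% extrapolated

    def test_vanishing_last_concentration(self):
        auc_inf, pct, flag = nca.extrapolate_auc(100.0, 1e-12, 0.1)
        assert auc_inf == pytest.approx(100.0)
        assert not flag

    def test_noise_free_auc_inf_near_dose_over_clearance(self, valsartan_params):
        t = np.linspace(0, 72, 500)
        prof = synth.simulate_profile(valsartan_params, 160.0, t, error_cv=0.0)
        res = nca.run_nca(prof, auc_end=72.0)
        assert res.auc_inf == pytest.approx(160_000 / valsartan_params.cl_f, rel=0.02)

    def test_non_positive_ke_rejected(self):
        with pytest.raises(NonEvaluableProfile):
            nca.extrapolate_auc(100.0, 5.0, 0.0)


class TestNormalization:
    def test_arithmetic(self):
        res = nca.NCAResult("s", "d", 1, "R", 12.5, 70.0, cmax=10.0, tmax=1.0,
                            auc_t=900.0, auc_inf=1000.0, ke=0.1, t_half=6.93,
                            n_lambda_points=3, adj_r2_lambda=1.0, pct_extrapolated=10.0)
        nca.normalize(res)
        assert res.auc_inf_d == pytest.approx(80.0)
        assert res.auc_inf_dw == pytest.approx(5600.0)

    def test_weight_equals_dose_identity(self):
        res = nca.NCAResult("s", "d", 1, "R", 70.0, 70.0, cmax=10.0, tmax=1.0,
                            auc_t=900.0, auc_inf=1000.0, ke=0.1, t_half=6.93,
                            n_lambda_points=3, adj_r2_lambda=1.0, pct_extrapolated=10.0)
        nca.normalize(res)
        assert res.auc_inf_dw == pytest.approx(res.auc_inf)

    @given(
        auc=st.floats(1.0, 1e6), dose=st.floats(0.1, 1000), weight=st.floats(35, 140)
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, auc, dose, weight):
        res = nca.NCAResult("s", "d", 1, "R", dose, weight, cmax=1.0, tmax=1.0,
                            auc_t=auc, auc_inf=auc, ke=0.1, t_half=6.93,
                            n_lambda_points=3, adj_r2_lambda=1.0, pct_extrapolated=0.0)
        nca.normalize(res)
        assert res.auc_inf_dw * dose / weight == pytest.approx(auc, rel=1e-12)


class TestAggregation:
    def _result(self, formulation, auc):
        r = nca.NCAResult("s", "d", 1, formulation, 160.0, 70.0, cmax=auc / 10,
                          tmax=2.0, auc_t=auc * 0.9, auc_inf=auc, ke=0.1,
                          t_half=6.93, n_lambda_points=3, adj_r2_lambda=1.0,
                          pct_extrapolated=10.0)
        return nca.normalize(r)

    def test_mean_tr(self):
        agg = nca.aggregate_formulations(
            [self._result("T", 100.0), self._result("R", 120.0)], "mean_TR"
        )
        assert agg.auc_inf == pytest.approx(110.0)

    def test_reference_only(self):
        agg = nca.aggregate_formulations(
            [self._result("T", 100.0), self._result("R", 120.0)], "reference_only"
        )
        assert agg.auc_inf == pytest.approx(120.0)

    def test_policies_agree_on_identical_periods(self):
        results = [self._result("T", 100.0), self._result("R", 100.0)]
        a = nca.aggregate_formulations(results, "mean_TR")
        b = nca.aggregate_formulations(results, "reference_only")
        assert a.auc_inf == b.auc_inf

    def test_missing_reference_period_rejected(self):
        with pytest.raises(ValueError):
            nca.aggregate_formulations([self._result("T", 100.0)], "reference_only")


class TestInvariants:
    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_linearity_in_concentration_scale(self, scale):
        t = [0, 0.5, 1, 2, 3, 4, 6, 8, 12, 24, 36, 48]
        c = [None, 30, 80, 120, 110, 95, 70, 52, 30, 8, 2.2, 0.6]
        base = make_profile(t, c, lloq=0.0)
        scaled = make_profile(
            t, [None if v is None else v * scale for v in c], lloq=0.0
        )
        r0, r1 = nca.run_nca(base), nca.run_nca(scaled)
        assert r1.cmax == pytest.approx(r0.cmax * scale, rel=1e-9)
        assert r1.auc_inf == pytest.approx(r0.auc_inf * scale, rel=1e-9)
        assert r1.tmax == r0.tmax
        assert r1.ke == pytest.approx(r0.ke, rel=1e-9)

    def test_auc_inf_dominates_auc_t_and_extrapolation_bounded(self, small_cohort):
        # per-period results: the half-life identity is algebraic per profile
        # (arithmetic T/R averaging deliberately breaks it at aggregate level)
        results = [nca.run_nca(p) for p in small_cohort.profiles]
        assert all(r.auc_inf >= r.auc_t for r in results)
        assert all(0 <= r.pct_extrapolated < 100 for r in results)
        assert np.allclose([r.t_half * r.ke for r in results], math.log(2))

    def test_tmax_stable_under_sample_reordering(self):
        t = np.array([0, 2, 1, 4, 3, 8, 6, 12], float)
        c = np.array([np.nan, 90, 50, 60, 90, 20, 40, 5])
        shuffled = nca.ConcentrationProfile(
            "s", "valsartan", 1, "R", 160.0, 70.0, t, c, np.isnan(c), 0.0
        )
        _, tmax = nca.cmax_tmax(nca.preprocess_bloq(shuffled))
        assert tmax == 2.0  # earliest of the tied maxima after canonical sort

    def test_noise_free_half_life_recovery(self):
        for drug, base in synth.DRUG_PARAMS.items():
            params = synth.PKTrueParameters(drug, **base)
            prof = synth.simulate_profile(params, 100.0, error_cv=0.0)
            res = nca.run_nca(prof)
            truth = math.log(2) * params.v_f / params.cl_f
            assert res.t_half == pytest.approx(truth, rel=0.05)
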