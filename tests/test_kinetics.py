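"""Moment-model simulation, half-time extraction, scaling and global fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import seedkin as sk
from seedkin.kinetics import DEFAULT_BOUNDS, estimate_noise_sd

from conftest import crossing_half_time, rk4_oracle


T_GRID = np.arange(0, 150 * 3600 + 1, 900.0)


class TestSimulate:
    def test_no_nuclei_no_growth(self):
        p = sk.RateParameters(k_plus=5e3, m_tot=5e-6)
        tr = sk.simulate_aggregation(p, T_GRID)
        assert np.all(tr.signal == 0.0)

    def test_no_elongation_mass_constant(self, frag_params):
        p = frag_params.evolve(k_plus=0.0)
        tr = sk.simulate_aggregation(p, T_GRID)
        np.testing.assert_allclose(tr.signal, p.M_0 / p.m_tot, rtol=1e-8)

    def test_early_time_matches_linear_elongation_limit(self):
        # seeded, all secondary pathways off: M ~ M0 + 2 k+ m0 P0 t early on
        p = sk.RateParameters(k_plus=5e3, m_tot=5e-6, M_0=5e-8, P_0=5e-12)
        t = np.linspace(0, 2000.0, 21)
        tr = sk.simulate_aggregation(p, t, rtol=1e-10)
        m0 = p.m_tot - p.M_0
        expected = (p.M_0 + 2 * p.k_plus * m0 * p.P_0 * t) / p.m_tot
        np.testing.assert_allclose(tr.signal, expected, rtol=1e-3)

    @pytest.mark.parametrize("model", ["fragmentation", "saturating"])
    def test_half_time_matches_fixed_step_integrator(self, model):
        p = sk.default_rate_parameters(5.0, model=model)
        tr = sk.simulate_aggregation(p, T_GRID)
        ht = crossing_half_time(tr.time, tr.signal)
        ts, _, M, _ = rk4_oracle(p, T_GRID[-1], n_steps=10_000)
        ht_oracle = crossing_half_time(ts, M / p.m_tot)
        assert abs(ht - ht_oracle) / ht_oracle < 0.005

    def test_mass_conservation_against_independent_monomer_ode(self, frag_params):
        ts, _, M, m = rk4_oracle(frag_params, T_GRID[-1])
        assert np.max(np.abs(m + M - frag_params.m_tot)) \
            <= 1e-6 * frag_params.m_tot

    def test_monotone_mass_and_bounds(self, sat_params):
        tr = sk.simulate_aggregation(sat_params, T_GRID)
        assert np.all(np.diff(tr.signal) >= 0)
        assert tr.signal.min() >= 0 and tr.signal.max() <= 1 + 1e-9

    def test_unsaturated_limit_reproduces_plain_secondary(self, sat_params):
        # K_M far above m: saturating model must agree with the plain one
        k2_eff = sat_params.k_2  # same constant, saturation negligible
        p_sat = sat_params.evolve(K_M=1.0)   # 1 M >> 5 uM
        p_plain = sat_params.evolve(K_M=math.inf, k_2=k2_eff)
        a = sk.simulate_aggregation(p_sat, T_GRID, rtol=1e-10)
        b = sk.simulate_aggregation(p_plain, T_GRID, rtol=1e-10)
        np.testing.assert_allclose(a.signal, b.signal, atol=1e-7)

    def test_time_grid_must_start_at_zero(self, frag_params):
        with pytest.raises(ValueError):
            sk.simulate_aggregation(frag_params, np.array([900.0, 1800.0]))

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(p0_scale=st.floats(1.0, 50.0))
    def test_seeding_accelerates(self, p0_scale):
        base = sk.default_rate_parameters(5.0)
        more = base.evolve(P_0=base.P_0 * p0_scale)
        t1 = crossing_half_time(*_sim(base))
        t2 = crossing_half_time(*_sim(more))
        assert t2 <= t1 * (1 + 1e-6)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        k_plus=st.floats(1e3, 1e4),
        k_minus=st.floats(1e-9, 1e-7),
        seed_frac=st.floats(0.005, 0.05),
    )
    def test_simulated_mass_valid_for_random_parameters(
            self, k_plus, k_minus, seed_frac):
        m_tot = 5e-6
        M0 = seed_frac * m_tot
        p = sk.RateParameters(k_plus=k_plus, k_minus=k_minus,
                              m_tot=m_tot, M_0=M0, P_0=M0 / 1e4)
        tr = sk.simulate_aggregation(p, T_GRID)
        assert np.all(np.diff(tr.signal) >= 0)
        assert 0 <= tr.signal.min() and tr.signal.max() <= 1 + 1e-9


def _sim(p):
    tr = sk.simulate_aggregation(p, T_GRID)
    return tr.time, tr.signal


class TestParameterValidation:
    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            sk.RateParameters(k_plus=-1.0)

    def test_rejects_seed_mass_above_total(self):
        with pytest.raises(ValueError):
            sk.RateParameters(m_tot=1e-6, M_0=2e-6, P_0=1e-9)

    def test_rejects_more_fibrils_than_monomers(self):
        with pytest.raises(ValueError):
            sk.RateParameters(m_tot=1e-6, M_0=1e-8, P_0=1e-7)


class TestHalfTime:
    def test_noise_free_logistic_midpoint_recovered(self):
        t = np.arange(0, 100 * 3600 + 1, 900.0)
        y = 100 + 1900 / (1 + np.exp(-(t - 36_000) / 4000))
        tr = sk.KineticTrace(t, y)
        ht = sk.extract_half_time(tr)
        assert abs(ht - 36_000) <= 900
        assert tr.fitted_baseline == pytest.approx(100, abs=1)
        assert tr.fitted_plateau == pytest.approx(2000, abs=1)

    def test_sigmoid_fit_agrees_with_crossing_oracle(self, frag_params):
        tr = sk.simulate_aggregation(frag_params, T_GRID)
        ht_fit = sk.extract_half_time(tr)
        ht_cross = crossing_half_time(tr.time, tr.signal)
        assert abs(ht_fit - ht_cross) / ht_cross < 0.02

    def test_flat_trace_returns_sentinel(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 50 * 3600, 900.0)
        tr = sk.KineticTrace(t, 100 + rng.normal(0, 5, t.size))
        assert sk.extract_half_time(tr) is sk.NO_AGGREGATION
        assert tr.half_time_flag == "no_aggregation"

    def test_sentinel_is_falsy_not_a_number(self):
        assert not sk.NO_AGGREGATION
        assert not isinstance(sk.NO_AGGREGATION, float)

    def test_incomplete_transition_is_flagged(self, frag_params):
        t = np.arange(0, 40 * 3600 + 1, 900.0)  # ends well before t1/2
        tr = sk.simulate_aggregation(frag_params, t)
        with pytest.warns(UserWarning, match="incomplete"):
            sk.extract_half_time(tr)
        assert tr.half_time_flag == "incomplete"

    def test_half_time_within_span_for_complete_trace(self, sat_params):
        tr = sk.simulate_aggregation(sat_params, T_GRID)
        ht = sk.extract_half_time(tr)
        assert 0 < ht < tr.span

    def test_noise_sd_estimator_on_known_noise(self):
        rng = np.random.default_rng(1)
        sd = estimate_noise_sd(rng.normal(0, 7.0, 4000))
        assert sd == pytest.approx(7.0, rel=0.1)


class TestScalingExponent:
    def test_constant_half_times_give_zero(self):
        g, _ = sk.scaling_exponent([100.0] * 4, [1.0, 2.0, 4.0, 8.0])
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_exact_inverse_power_law(self):
        m = np.array([1.0, 2.0, 5.0, 10.0])
        g, se = sk.scaling_exponent(42.0 / m, m)
        assert g == pytest.approx(-1.0, rel=1e-9)
        assert se == pytest.approx(0.0, abs=1e-6)

    def test_fragmentation_dilution_series_gives_minus_half(self):
        # noise-free seeded fragmentation kinetics over a 6-point dilution
        hts, concs = [], []
        for c in (3.2, 4.0, 6.0, 8.0, 12.0, 15.0):
            p = sk.default_rate_parameters(c, model="fragmentation")
            tr = sk.simulate_aggregation(p, T_GRID)
            hts.append(crossing_half_time(tr.time, tr.signal))
            concs.append(c)
        g, _ = sk.scaling_exponent(hts, concs)
        assert g == pytest.approx(-0.5, abs=0.05)

    def test_requires_three_points_and_positive_values(self):
        with pytest.raises(ValueError):
            sk.scaling_exponent([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            sk.scaling_exponent([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])


class TestGlobalFit:
    def make_traces(self, params, concs=(3.2, 8.0, 15.0)):
        traces = []
        for c in concs:
            p = sk.default_rate_parameters(c, model="fragmentation").evolve(
                k_plus=params.k_plus, k_minus=params.k_minus)
            tr = sk.simulate_aggregation(p, T_GRID)
            traces.append(tr)
        return traces

    def test_single_free_constant_recovered_within_1pct(self, frag_params):
        traces = self.make_traces(frag_params)
        start = frag_params.evolve(k_plus=1e3)  # wrong guess
        res = sk.global_fit(traces, start, free=["k_plus"], n_starts=3,
                            seed=0)
        assert res.values["k_plus"] == pytest.approx(frag_params.k_plus,
                                                     rel=0.01)

    def test_rate_product_recovered_when_both_free(self, frag_params):
        # individual constants trade off; the product k+ * k- (which sets
        # kappa^2) is the identifiable combination
        traces = self.make_traces(frag_params)
        res = sk.global_fit(traces, frag_params.evolve(k_plus=1e3,
                                                       k_minus=1e-7),
                            free=["k_plus", "k_minus"], n_starts=6, seed=1)
        prod_true = frag_params.k_plus * frag_params.k_minus
        prod_fit = res.values["k_plus"] * res.values["k_minus"]
        assert prod_fit == pytest.approx(prod_true, rel=0.05)

    def test_empty_free_set_returns_misfit_only(self, frag_params):
        traces = self.make_traces(frag_params)
        res = sk.global_fit(traces, frag_params, free=[])
        assert res.values == {}
        assert res.n_starts == 0
        assert res.total_sse == pytest.approx(0.0, abs=1e-6)
        assert len(res.per_trace_sse) == len(traces)

    def test_unknown_free_parameter_rejected(self, frag_params):
        traces = self.make_traces(frag_params)
        with pytest.raises(ValueError, match="bounds"):
            sk.global_fit(traces, frag_params, free=["n_2"])

    def test_result_serializes(self, frag_params):
        traces = self.make_traces(frag_params)[:1]
        res = sk.global_fit(traces, frag_params, free=[])
        d = res.to_dict()
        assert set(d) >= {"parameters", "per_trace_misfit", "seed", "starts"}

    def test_default_bounds_cover_generator_truth(self, frag_params):
        for name in ("k_plus", "k_minus"):
            lo, hi = DEFAULT_BOUNDS[name]
            assert lo <= getattr(frag_params, name) <= hi
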