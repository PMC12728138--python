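import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

import erplatency as e
from erplatency.matching import (
    DegenerateSeriesError,
    MatchResult,
    penalty_factor,
    screen_fit,
)
from erplatency.weighting import WeightVector


def noisy_subject_erp(b_true=1.1, a_true=0.8, seed=42, noise_sd=3.0):
    tpl = e.make_population_template()
    subj = e.SyntheticSubject(
        b_true=b_true, a_true=a_true, noise_sd=noise_sd, n_trials=80, seed=seed
    )
    erp, _ = e.generate_subject_erp(tpl, subj)
    return erp, tpl


class TestWeightedCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        w = rng.uniform(0.1, 1.0, size=50)
        assert e.weighted_correlation(x, x, w) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 80))
        r = e.weighted_correlation(x, y, np.ones(80))
        assert r == pytest.approx(pearsonr(x, y).statistic, abs=1e-12)

    def test_matches_literal_formula(self):
        # transcribe the weighted covariance / weighted mean definition
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 50))
        w = rng.uniform(0.0, 1.0, size=50)
        sw = sum(w)
        mx = sum(wi * xi for wi, xi in zip(w, x)) / sw
        my = sum(wi * yi for wi, yi in zip(w, y)) / sw
        cxy = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(w, x, y)) / sw
        cxx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(w, x)) / sw
        cyy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y)) / sw
        expected = cxy / math.sqrt(cxx * cyy)
        assert e.weighted_correlation(x, y, w) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            e.weighted_correlation(np.ones(10), np.arange(10.0), np.ones(10))


class TestObjectives:
    def test_perfect_match_is_zero(self, template, window):
        w = e.make_weights(template, window, "normalized")
        obj = e.minsq_objective(template, template, e.TransformParams(1, 1), w)
        assert obj == pytest.approx(0.0, abs=1e-18)

    def test_hand_summed_distance(self):
        times = np.array([-2.0, 0.0, 2.0, 4.0])
        tpl = e.SampledSignal(times, np.array([0.0, 1.0, 2.0, 0.0]))
        sig = e.SampledSignal(times, np.zeros(4))
        w = WeightVector(np.ones(4))
        obj = e.minsq_objective(sig, tpl, e.TransformParams(1, 1), w)
        assert obj == pytest.approx(5.0, abs=1e-12)  # 1^2 + 2^2

    @pytest.mark.parametrize("a,b", [(1.0, 1.0), (1.3, 0.9), (0.7, 1.2)])
    def test_matches_loop_summation_oracle(self, template, a, b):
        rng = np.random.default_rng(5)
        sig = e.SampledSignal(template.times, rng.normal(0, 3, template.n))
        w_arr = rng.uniform(0, 1, template.n)
        w_arr[w_arr.argmax()] = 1.0
        w = WeightVector(w_arr)
        transformed = e.scale_amplitude(e.stretch_signal(template, b), a)
        total = 0.0
        mass = 0.0
        for i in range(template.n):
            if transformed.valid_mask[i]:
                total += w_arr[i] * (transformed.values[i] - sig.values[i]) ** 2
                mass += w_arr[i]
        expected = total * (w_arr.sum() / mass)
        got = e.minsq_objective(sig, template, e.TransformParams(a, b), w)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_maxcor_matches_weighted_correlation(self, template, window):
        rng = np.random.default_rng(6)
        sig = e.SampledSignal(template.times, rng.normal(0, 3, template.n))
        w = e.make_weights(template, window, "normalized")
        params = e.TransformParams(1.0, 1.1)
        transformed = e.stretch_signal(template, 1.1)
        m = transformed.valid_mask
        expected = e.weighted_correlation(
            transformed.values[m], sig.values[m], w.weights[m]
        )
        got = e.maxcor_objective(sig, template, params, w)
        assert got == pytest.approx(expected, abs=1e-10)


class TestPenalty:
    def test_no_penalty_inside_band(self):
        assert e.apply_penalty(7.3, 1.0, "minimize") == 7.3
        assert penalty_factor(0.8) == 1.0 and penalty_factor(1.49) == 1.0

    def test_band_edges_are_penalized(self):
        # both edges carry the same factor e^1.5
        assert e.apply_penalty(1.0, 1.5, "minimize") == pytest.approx(math.exp(1.5))
        assert e.apply_penalty(1.0, 2.0 / 3.0, "minimize") == pytest.approx(
            math.exp(1.5)
        )

    def test_small_b_branch(self):
        assert e.apply_penalty(2.0, 0.5, "minimize") == pytest.approx(2 * math.exp(2))

    def test_maximize_divides(self):
        assert e.apply_penalty(0.8, 1.8, "maximize") == pytest.approx(
            0.8 / math.exp(1.8)
        )

    @given(b=st.floats(0.3, 2.0))
    @settings(deadline=None, max_examples=200)
    def test_factor_never_rewards(self, b):
        # penalty is 1 inside the open band, strictly > 1 outside
        p = penalty_factor(b)
        if 2.0 / 3.0 < b < 1.5:
            assert p == 1.0
        else:
            assert p > 1.0

    @given(
        data=st.lists(
            st.tuples(
                st.floats(-10, 10), st.floats(-10, 10), st.floats(0.01, 1.0)
            ),
            min_size=5,
            max_size=40,
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_weighted_correlation_bounded(self, data):
        x, y, w = (np.array(col) for col in zip(*data))
        try:
            r = e.weighted_correlation(x, y, w)
        except DegenerateSeriesError:
            return
        assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12


class TestFitTemplate:
    def test_self_match(self, template, l_ga):
        res = e.fit_template(template, template, l_ga, e.MatchConfig(method="minsq"))
        assert res.b_opt == pytest.approx(1.0, abs=0.01)
        assert res.a_opt == pytest.approx(1.0, abs=0.01)
        assert res.fit_r > 0.999
        assert res.latency_ms == pytest.approx(l_ga, rel=0.01)
        assert res.valid

    def test_recovers_known_transform_noiseless(self, template, l_ga):
        sig = e.scale_amplitude(e.stretch_signal(template, 0.9), 1.2)
        res = e.fit_template(sig, template, l_ga, e.MatchConfig(method="minsq"))
        assert res.b_opt == pytest.approx(0.90, abs=0.01)
        assert res.a_opt == pytest.approx(1.20, abs=0.02)

    def test_maxcor_amplitude_invariance(self, template, l_ga):
        erp, _ = noisy_subject_erp()
        cfg = e.MatchConfig(method="maxcor")
        ref = e.fit_template(erp, template, l_ga, cfg)
        for c in (0.5, 4.0):
            res = e.fit_template(e.scale_amplitude(erp, c), template, l_ga, cfg)
            assert res.b_opt == pytest.approx(ref.b_opt, abs=1e-6)
            assert res.fit_r == pytest.approx(ref.fit_r, abs=1e-9)
            assert res.a_opt == 1.0

    def test_beats_grid_search_minsq(self, template, window, l_ga):
        erp, _ = noisy_subject_erp(seed=7)
        w = e.make_weights(template, window, "normalized")
        cfg = e.MatchConfig(method="minsq", direction="forward")
        res = e.fit_template(erp, template, l_ga, cfg, weights=w)

        def penalized(a, b):
            obj = e.minsq_objective(erp, template, e.TransformParams(a, b), w)
            return e.apply_penalty(obj, b, "minimize")

        grid_best = min(
            penalized(a, b)
            for a in np.linspace(0.2, 20, 41)
            for b in np.linspace(0.3, 2, 41)
        )
        assert penalized(res.a_opt, res.b_opt) <= grid_best + 1e-6

    def test_beats_grid_search_maxcor(self, template, window, l_ga):
        erp, _ = noisy_subject_erp(seed=8)
        w = e.make_weights(template, window, "normalized")
        cfg = e.MatchConfig(method="maxcor", direction="forward")
        res = e.fit_template(erp, template, l_ga, cfg, weights=w)

        def penalized(b):
            obj = e.maxcor_objective(erp, template, e.TransformParams(1.0, b), w)
            return e.apply_penalty(obj, b, "maximize")

        grid_best = max(penalized(b) for b in np.linspace(0.3, 2, 41))
        assert penalized(res.b_opt) >= grid_best - 1e-6

    def test_direction_equivalence(self, template, l_ga):
        # transforming the template forward or rescaling the signal inversely
        # recovers the same stretch and fit
        rng = np.random.default_rng(123)
        for k in range(20):
            erp, _ = noisy_subject_erp(
                b_true=float(rng.uniform(0.85, 1.15)),
                a_true=float(rng.uniform(0.7, 1.4)),
                seed=1000 + k,
            )
            inv = e.fit_template(
                erp, template, l_ga, e.MatchConfig(method="minsq", direction="inverse")
            )
            fwd = e.fit_template(
                erp, template, l_ga, e.MatchConfig(method="minsq", direction="forward")
            )
            assert abs(inv.b_opt - fwd.b_opt) <= 0.01
            assert abs(inv.fit_r - fwd.fit_r) <= 0.005

    def test_flat_signal_is_degenerate(self, template, l_ga):
        flat = e.SampledSignal(template.times, np.zeros(template.n))
        res = e.fit_template(flat, template, l_ga, e.MatchConfig(method="maxcor"))
        assert not res.valid
        assert res.reject_reason == "degenerate"

    def test_penalty_pulls_in_extreme_stretches(self, template, l_ga):
        # with the penalty on, noisy replicates should not place more mass at
        # extreme b than without it
        rng = np.random.default_rng(55)
        extremes = {True: 0, False: 0}
        for k in range(15):
            erp, _ = noisy_subject_erp(seed=3000 + k, noise_sd=8.0)
            for pen in (True, False):
                cfg = e.MatchConfig(method="minsq", penalty=pen)
                res = e.fit_template(erp, template, l_ga, cfg)
                if not (0.5 <= res.b_opt <= 1.9):
                    extremes[pen] += 1
        assert extremes[True] <= extremes[False]

    def test_requires_positive_template_latency(self, template):
        with pytest.raises(ValueError):
            e.fit_template(template, template, 0.0, e.MatchConfig())


class TestScreenFit:
    def _result(self, fit_r):
        return MatchResult(1.0, 1.0, 0.0, fit_r, 400.0, True, "none")

    def test_below_cutoff_rejected(self):
        out = screen_fit(self._result(0.29), 0.3)
        assert not out.valid and out.reject_reason == "low_fit"
        assert out.latency_ms == 400.0  # retained for audit

    def test_boundary_is_inclusive(self):
        assert screen_fit(self._result(0.30), 0.3).valid

    def test_cutoff_minus_one_accepts_everything(self):
        assert screen_fit(self._result(-0.99), -1.0).valid
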