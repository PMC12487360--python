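import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalgrowth.exceptions import DataError, DomainError, ParameterError
from fetalgrowth.growth_models import (
    FAMILIES,
    GrowthCurveModel,
    GrowthModelSelector,
    derived_descriptors,
    eval_model,
    fit_curve,
    fit_percent_of_adult,
    gompertz_from_descriptors,
    select_model,
)

AGES = np.array([85.0, 97, 110, 122, 135, 147, 155])


class TestEvalModel:
    @pytest.mark.parametrize(
        "family,params,t,expected",
        [
            # half the asymptote at the inflection age
            ("logistic3", [48.5, 0.0566, 113], 113.0, 24.25),
            # four-parameter midpoint: (A-B)/2 + B
            ("logistic4", [10, 2, 1, 0], 0.0, 6.0),
            ("linear", [0.5, 0.0], 10.0, 5.0),
            ("quadratic", [1.0, 2.0, 3.0], 2.0, 1 + 4 + 12),
            # Gompertz value at its inflection is a/e
            ("gompertz", [5, 3, 0.1], math.log(3) / 0.1, 5 / math.e),
        ],
    )
    def test_closed_forms(self, family, params, t, expected):
        assert eval_model(family, params, t) == pytest.approx(expected, rel=1e-12)

    def test_gompertz_asymptote(self):
        assert eval_model("gompertz", [5, 3, 0.1], 1e6) == pytest.approx(5.0)

    def test_vectorizes(self):
        out = eval_model("logistic3", [10, 0.1, 100], AGES)
        assert out.shape == AGES.shape
        assert np.all(np.diff(out) > 0)

    def test_wrong_parameter_count(self):
        with pytest.raises(ParameterError):
            eval_model("logistic3", [1.0, 2.0], 100.0)

    def test_nonfinite_params(self):
        with pytest.raises(DomainError):
            eval_model("linear", [np.nan, 0.0], 1.0)

    def test_unknown_family(self):
        with pytest.raises(ParameterError):
            eval_model("cubic", [1, 2, 3], 1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    A=st.floats(1.0, 100.0),
    Rg=st.floats(0.01, 0.5),
    tmid=st.floats(50.0, 200.0),
)
def test_logistic3_half_asymptote_at_inflection(A, Rg, tmid):
    assert eval_model("logistic3", [A, Rg, tmid], tmid) == pytest.approx(A / 2)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    a=st.floats(0.5, 50.0),
    b=st.floats(1.1, 50.0),
    c=st.floats(0.005, 0.5),
)
def test_gompertz_value_at_inflection_is_a_over_e(a, b, c):
    tmid = math.log(b) / c
    assert eval_model("gompertz", [a, b, c], tmid) == pytest.approx(a / math.e)


class TestFitCurve:
    def test_noiseless_logistic3_roundtrip(self):
        truth = [40.0, 0.05, 110.0]
        y = eval_model("logistic3", truth, AGES)
        fit = fit_curve("logistic3", AGES, y)
        assert fit.converged
        assert fit.params == pytest.approx(truth, rel=1e-4)

    def test_two_point_line_exact(self):
        fit = fit_curve("linear", [0.0, 10.0], [0.0, 5.0])
        m, b = fit.params
        assert m == pytest.approx(0.5, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_constrained_fit_matches_free_fit_at_truth(self):
        truth = [5.0, 6.751, 0.014145]
        y = eval_model("gompertz", truth, AGES)
        free = fit_curve("gompertz", AGES, y, fixed={})
        pinned = fit_curve("gompertz", AGES, y, fixed={"a": truth[0]})
        assert free.params[1:] == pytest.approx(pinned.params[1:], abs=1e-6)

    def test_insufficient_points(self):
        with pytest.raises(DataError):
            fit_curve("logistic3", [85.0, 100.0], [1.0, 2.0])
        with pytest.raises(DataError):
            fit_curve("linear", [85.0], [1.0])

    def test_constant_values_sigmoid_not_converged(self):
        fit = fit_curve("logistic3", AGES, np.full_like(AGES, 3.0))
        assert not fit.converged

    def test_noiseless_gompertz_roundtrip(self):
        truth = [3.19, 6.751, 0.014145]
        y = eval_model("gompertz", truth, AGES)
        fit = fit_curve("gompertz", AGES, y)
        assert fit.converged
        assert fit.params == pytest.approx(truth, rel=1e-3)

    def test_loglik_and_bic_consistent(self):
        rng = np.random.default_rng(0)
        y = eval_model("logistic3", [40, 0.05, 110], AGES) + rng.normal(0, 0.5, 7)
        fit = fit_curve("logistic3", AGES, y)
        n, k = fit.n_obs, 3 + 1
        assert fit.bic == pytest.approx(n * np.log(fit.rss / n) + k * np.log(n))
        sigma2 = fit.rss / n
        assert fit.loglik == pytest.approx(
            -0.5 * n * (np.log(2 * np.pi * sigma2) + 1))

    def test_matches_brute_force_grid_search(self):
        """The optimizer should do at least as well as a dense grid oracle."""
        rng = np.random.default_rng(3)
        truth = [40.0, 0.05, 110.0]
        y = eval_model("logistic3", truth, AGES) + rng.normal(0, 0.5, 7)
        fit = fit_curve("logistic3", AGES, y)

        A_grid = np.linspace(30, 60, 40)
        Rg_grid = np.linspace(0.02, 0.10, 40)
        tmid_grid = np.linspace(95, 130, 40)
        best = (np.inf, None)
        for A in A_grid:
            for Rg in Rg_grid:
                pred = A / (1 + np.exp(-Rg * (AGES[None, :] - tmid_grid[:, None])))
                rss = ((pred - y) ** 2).sum(axis=1)
                j = int(np.argmin(rss))
                if rss[j] < best[0]:
                    best = (rss[j], (A, Rg, tmid_grid[j]))
        assert fit.rss <= best[0] + 1e-9
        res = (A_grid[1] - A_grid[0], Rg_grid[1] - Rg_grid[0],
               tmid_grid[1] - tmid_grid[0])
        assert np.all(np.abs(np.array(fit.params) - best[1]) <= res)


class TestSelectModel:
    def test_linear_data_selects_linear(self):
        rng = np.random.default_rng(1)
        t = np.linspace(80, 160, 40)
        y = 0.3 * t + 2 + rng.normal(0, 1e-3 * np.ptp(0.3 * t), 40)
        assert select_model(t, y).winner == "linear"

    def test_parabola_selects_quadratic(self):
        rng = np.random.default_rng(2)
        t = np.linspace(80, 160, 40)
        y = 1.6e-4 * (t - 110) ** 2 + 0.35 + rng.normal(0, 1e-4, 40)
        assert select_model(t, y).winner == "quadratic"

    def test_winner_minimizes_bic(self, default_cohort):
        sub = default_cohort[default_cohort.region == "whole_brain"]
        sel = select_model(sub.age_days, sub.value)
        finite = {f: b for f, b in sel.bic_table.items() if np.isfinite(b)}
        assert sel.bic_table[sel.winner] == min(finite.values())

    def test_requires_six_observations(self):
        with pytest.raises(DataError):
            select_model(AGES[:5], np.arange(5.0))

    @pytest.mark.parametrize("sigma_frac", [0.10, 0.01, 0.001])
    def test_logistic3_selection_rate(self, sigma_frac, _rates={}):
        """Selection of the generating family improves as noise shrinks."""
        rng = np.random.default_rng(42)
        wins = 0
        n_seeds = 40
        for _ in range(n_seeds):
            t = rng.uniform(80, 160, 100)
            y0 = eval_model("logistic3", [48, 0.0533, 116], t)
            y = y0 + rng.normal(0, sigma_frac * np.ptp(y0), t.size)
            wins += select_model(t, y).winner == "logistic3"
        _rates[sigma_frac] = wins / n_seeds
        if sigma_frac == 0.001:
            rates = [_rates[s] for s in (0.10, 0.01, 0.001)]
            assert rates[1] >= 0.9
            assert rates[0] <= rates[1] <= rates[2] or rates[2] == 1.0


class TestDerivedDescriptors:
    def test_gompertz_collapse(self):
        fit = fit_curve("gompertz", AGES,
                        eval_model("gompertz", [math.e, math.e, 1.0], AGES))
        d = derived_descriptors(
            type(fit)(family="gompertz", params=np.array([math.e, math.e, 1.0]),
                      rss=0, loglik=0, bic=0, n_obs=7, converged=True))
        assert d.t_mid == pytest.approx(1.0)
        assert d.r_max == pytest.approx(1.0)

    def test_brainstem_inversion_roundtrip(self):
        # published descriptors: a=3.19, max rate 0.0166 mL/day at day 135
        a, b, c = gompertz_from_descriptors(3.19, 0.0166, 135.0)
        assert c == pytest.approx(0.0166 * math.e / 3.19, rel=1e-12)
        assert b == pytest.approx(math.exp(c * 135.0), rel=1e-12)
        from fetalgrowth.growth_models import GrowthCurveFit

        d = derived_descriptors(GrowthCurveFit(
            family="gompertz", params=np.array([a, b, c]), rss=0, loglik=0,
            bic=0, n_obs=7, converged=True))
        assert d.r_max == pytest.approx(0.0166, rel=1e-10)
        assert d.t_mid == pytest.approx(135.0, rel=1e-10)

    def test_logistic3_whole_brain_female(self):
        from fetalgrowth.growth_models import GrowthCurveFit

        d = derived_descriptors(GrowthCurveFit(
            family="logistic3", params=np.array([48.0, 0.0533, 116.0]),
            rss=0, loglik=0, bic=0, n_obs=7, converged=True))
        assert d.r_max == pytest.approx(0.6396, abs=5e-5)
        assert d.t_mid == 116.0

    def test_logistic4_descriptors(self):
        from fetalgrowth.growth_models import GrowthCurveFit

        d = derived_descriptors(GrowthCurveFit(
            family="logistic4", params=np.array([14.3, 2.0, 0.109, 108.0]),
            rss=0, loglik=0, bic=0, n_obs=7, converged=True))
        assert d.asymptote == 14.3
        assert d.r_max == pytest.approx((14.3 - 2.0) * 0.109 / 4)

    def test_unsupported_family(self):
        fit = fit_curve("linear", [0.0, 10.0], [0.0, 5.0])
        with pytest.raises(ParameterError):
            derived_descriptors(fit)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(0.5, 50.0), rmax=st.floats(1e-3, 1.0),
           tmid=st.floats(50.0, 200.0))
    def test_descriptor_inversion_is_identity(self, a, rmax, tmid):
        from fetalgrowth.growth_models import GrowthCurveFit

        params = np.array(gompertz_from_descriptors(a, rmax, tmid))
        d = derived_descriptors(GrowthCurveFit(
            family="gompertz", params=params, rss=0, loglik=0, bic=0,
            n_obs=7, converged=True))
        assert d.asymptote == pytest.approx(a, rel=1e-9)
        assert d.r_max == pytest.approx(rmax, rel=1e-9)
        assert d.t_mid == pytest.approx(tmid, rel=1e-9)


class TestPercentOfAdult:
    def test_constrained_roundtrip_and_rate_scale(self):
        t = np.repeat(AGES, 3)
        y = eval_model("logistic3", [100.0, 0.1484, 135.0], t)
        fit = fit_percent_of_adult(t, y)
        assert fit.params[0] == 100.0
        assert fit.params[1] == pytest.approx(0.1484, rel=1e-4)
        assert 25.0 * fit.params[1] == pytest.approx(3.71, abs=0.01)

    def test_replicated_single_age_unidentifiable(self):
        fit = fit_percent_of_adult([110.0] * 8, [50.0] * 8)
        assert not fit.converged

    def test_inflection_beyond_sampled_range(self):
        rng = np.random.default_rng(5)
        t = np.repeat(AGES, 3)
        y = eval_model("logistic3", [100.0, 0.0599, 175.0], t)
        y = y * (1 + rng.normal(0, 0.01, t.size))
        fit = fit_percent_of_adult(t, y)
        assert fit.converged
        assert fit.params[2] == pytest.approx(175.0, abs=5.0)


def test_estimator_follows_sklearn_conventions():
    model = GrowthCurveModel(family="logistic3")
    assert model.get_params()["family"] == "logistic3"
    model.set_params(family="gompertz")
    y = eval_model("gompertz", [5, 6.751, 0.0141], AGES)
    model.fit(AGES, y)
    assert hasattr(model, "params_") and model.converged_
    assert model.predict(AGES) == pytest.approx(y, rel=1e-3)
    sel = GrowthModelSelector().fit(AGES, y)
    assert sel.winner_ in FAMILIES
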