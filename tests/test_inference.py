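"""MLE fitting, Wald intervals, the boundary test and resolution probabilities."""

import math

import numpy as np
import pytest

from resolvemsm import (
    FitResult,
    ModelParameters,
    boundary_lrt,
    fit_mle,
    format_estimate,
    resolution_probability,
    transition_matrix,
    wald_intervals,
)
from resolvemsm.generator import build_generator
from conftest import make_subject


@pytest.fixture(scope="module")
def two_state_panel(two_state):
    """50 subjects observed at 0 and Δ=2; exactly 10 absorbed by the next visit."""
    delta, n, absorbed = 2.0, 50, 10
    subjects = [
        make_subject(["D0", "R" if i < absorbed else "D0"], times=[0.0, delta], sid=f"S{i}")
        for i in range(n)
    ]
    return subjects, delta, absorbed / n


class TestFitMle:
    def test_two_state_panel_mle_closed_form(self, two_state, two_state_panel):
        """λ̂ = −log(1 − d)/Δ for a binomially observed absorbing chain."""
        subjects, delta, d = two_state_panel
        init = ModelParameters.from_intensities({("D0", "R"): 0.5})
        fit = fit_mle(subjects, two_state, init, regime="complete",
                      options={"ftol": 1e-15, "gtol": 1e-12, "jac": "3-point"})
        assert fit.converged
        expected = -math.log(1 - d) / delta
        assert fit.theta_hat.lam[("D0", "R")] == pytest.approx(expected, abs=1e-8)

    def test_fit_is_deterministic(self, two_state, two_state_panel):
        subjects, *_ = two_state_panel
        init = ModelParameters.from_intensities({("D0", "R"): 0.3})
        f1 = fit_mle(subjects, two_state, init)
        f2 = fit_mle(subjects, two_state, init)
        assert f1.theta_vector == pytest.approx(f2.theta_vector, rel=0)
        assert f1.loglik == f2.loglik

    def test_regimes_agree_without_ambiguous_codes(self, four_state, scenario1_params):
        subjects = [
            make_subject(["D1", "D2", "D1"], z={"z": 0.0}, sid="a"),
            make_subject(["D2", "D1", "D2", "D2"], z={"z": 1.0}, sid="b"),
        ] * 10
        init = scenario1_params
        fc = fit_mle(subjects, four_state, init, regime="complete")
        fp = fit_mle(subjects, four_state, init, regime="partial")
        assert fc.theta_vector == pytest.approx(fp.theta_vector, rel=0)

    def test_complete_regime_rejects_masked_data(self, four_state, scenario1_params):
        with pytest.raises(ValueError, match="ambiguous"):
            fit_mle(
                [make_subject(["D1", "0"], z={"z": 0.0})],
                four_state,
                scenario1_params,
                regime="complete",
            )

    def test_zero_coefficient_recovered_on_average(self, four_state):
        """Data generated without a covariate effect yields β̂ near 0."""
        from dataclasses import replace

        from resolvemsm import generate_scenario_dataset, mask_dataset, scenario_config

        cfg = scenario_config(1)
        gen = replace(cfg, beta={**{t: {"z": 1.0} for t in cfg.beta}, ("D0", "D1"): {"z": 0.0}})
        init = gen.true_parameters()
        ests = []
        for rep in range(10):
            sim = generate_scenario_dataset(gen, "complete", np.random.SeedSequence([3, rep]))
            fit = fit_mle(mask_dataset(sim).subjects, cfg.space, init)
            ests.append(fit.theta_hat.beta[("D0", "D1")]["z"])
        assert abs(np.mean(ests)) < 3 * np.std(ests, ddof=1) / math.sqrt(len(ests)) + 0.1


class TestWaldIntervals:
    def test_baseline_interval_multiplicatively_symmetric(self, two_state, two_state_panel):
        subjects, *_ = two_state_panel
        fit = fit_mle(subjects, two_state,
                      ModelParameters.from_intensities({("D0", "R"): 0.5}))
        est, lo, hi = wald_intervals(fit)["D0->R"]
        assert hi / est == pytest.approx(est / lo, rel=1e-9)

    def test_zero_se_gives_degenerate_interval(self, two_state):
        params = ModelParameters.from_intensities({("D0", "R"): 0.4})
        fit = FitResult(
            theta_hat=params, vcov=np.zeros((1, 1)), loglik=0.0, converged=True,
            n_subjects=1, n_observations=2,
            param_names=params.free_names(two_state), space=two_state,
        )
        est, lo, hi = wald_intervals(fit)["D0->R"]
        assert lo == est == hi == pytest.approx(0.4)

    def test_reporting_format(self):
        assert format_estimate(0.039, 0.024, 0.065) == "0.039 (0.024, 0.065)"


class TestBoundaryLrt:
    def test_null_attaining_maximum_gives_p_one(self):
        T, p = boundary_lrt(-100.0, -100.0)
        assert (T, p) == (0.0, 1.0)

    @pytest.mark.parametrize(
        "T, p", [(2.705543, 0.05), (10.827566, 0.0005)], ids=["5pct", "0.05pct"]
    )
    def test_mixture_tail_quantiles(self, T, p):
        stat, pval = boundary_lrt(-100.0 + T / 2, -100.0)
        assert stat == pytest.approx(T)
        assert pval == pytest.approx(p, rel=1e-4)

    def test_non_nested_null_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            boundary_lrt(-101.0, -100.0)


@pytest.fixture(scope="module")
def s1_fit(four_state, scenario1_params):
    """A fit object carrying the generating parameters and a small vcov."""
    return FitResult(
        theta_hat=scenario1_params,
        vcov=np.eye(scenario1_params.n_free(four_state)) * 1e-4,
        loglik=0.0, converged=True, n_subjects=0, n_observations=0,
        param_names=scenario1_params.free_names(four_state), space=four_state,
    )


class TestResolutionProbability:
    def test_zero_horizon_gives_zero(self, s1_fit):
        assert resolution_probability(s1_fit, "D0", 0.0, {"z": 0.0}, seed=1).estimate == 0.0

    def test_resolved_start_gives_one(self, s1_fit):
        est = resolution_probability(s1_fit, "R", 3.0, {"z": 0.0}, seed=1)
        assert (est.estimate, est.lower, est.upper) == (1.0, 1.0, 1.0)

    def test_point_estimate_matches_matrix_exponential(self, s1_fit, four_state,
                                                       scenario1_params):
        Q = build_generator(scenario1_params, {"z": 0.0}, four_state)
        expected = transition_matrix(Q, 8.0)[four_state.index("D0"), 0]
        est = resolution_probability(s1_fit, "D0", 8.0, {"z": 0.0}, seed=1)
        assert est.estimate == pytest.approx(expected, rel=1e-12)
        assert est.lower <= est.estimate <= est.upper

    def test_nondecreasing_in_horizon(self, s1_fit):
        vals = [resolution_probability(s1_fit, "D1", t, {"z": 0.0}).estimate
                for t in (0.0, 1.0, 2.0, 5.0, 10.0)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_milder_initial_state_resolves_sooner(self, s1_fit):
        ests = [resolution_probability(s1_fit, s0, 5.0, {"z": 0.0}).estimate
                for s0 in ("D0", "D1", "D2")]
        assert ests[0] >= ests[1] >= ests[2]

    def test_interval_deterministic_given_seed(self, s1_fit):
        a = resolution_probability(s1_fit, "D0", 5.0, {"z": 0.0}, n_draws=200, seed=9)
        b = resolution_probability(s1_fit, "D0", 5.0, {"z": 0.0}, n_draws=200, seed=9)
        assert (a.lower, a.upper) == (b.lower, b.upper)
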