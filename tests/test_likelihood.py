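"""Marginal likelihood: closed forms, the enumeration oracle, and path weighting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from resolvemsm import (
    ModelParameters,
    PanelLikelihood,
    PanelObservation,
    SubjectHistory,
    build_generator,
    initial_state_term,
    subject_loglik_complete,
    subject_loglik_partial,
    total_loglik,
    transition_matrix,
)
from conftest import enumerate_loglik, make_subject


@pytest.fixture(scope="module")
def lam04(two_state):
    return ModelParameters.from_intensities({("D0", "R"): 0.4})


class TestCompleteObservation:
    def test_staying_resolved_has_probability_one(self, two_state, lam04):
        subj = make_subject(["R", "R"], sid="r")
        assert subject_loglik_complete(subj, lam04, two_state) == 0.0

    def test_two_state_survival_closed_form(self, two_state, lam04):
        subj = make_subject(["D0", "D0"])
        assert subject_loglik_complete(subj, lam04, two_state) == pytest.approx(-0.4, abs=1e-12)

    def test_ambiguous_codes_are_rejected(self, two_state, lam04):
        with pytest.raises(ValueError, match="ambiguous"):
            subject_loglik_complete(make_subject(["0", "0"]), lam04, two_state)

    def test_impossible_history_gives_minus_inf(self, four_state, scenario1_params):
        subj = make_subject(["R", "D1"], z={"z": 0.0})
        assert subject_loglik_complete(subj, scenario1_params, four_state) == -math.inf


class TestPartialObservation:
    def test_no_ambiguity_reduces_to_complete(self, four_state, scenario1_params):
        subj = make_subject(["D1", "D2", "D1"], z={"z": 1.0})
        assert subject_loglik_partial(subj, scenario1_params, four_state) == pytest.approx(
            subject_loglik_complete(subj, scenario1_params, four_state), rel=1e-14
        )

    def test_single_ambiguous_visit_two_term_sum(self, four_state, scenario1_params):
        subj = make_subject(["D1", "0"], z={"z": 0.0})
        Q = build_generator(scenario1_params, {"z": 0.0}, four_state)
        P = transition_matrix(Q, 1.0)
        expected = math.log(P[2, 0] + P[2, 1])  # D1 -> R plus D1 -> D0
        assert subject_loglik_partial(subj, scenario1_params, four_state) == pytest.approx(
            expected, rel=1e-13
        )

    @given(st.integers(0, 500))
    def test_forward_recursion_equals_enumeration(self, four_state, seed):
        """The recursion must agree with the literal nested sum to ~1e-12."""
        rng = np.random.default_rng(seed)
        lam = {t: float(rng.uniform(0.05, 1.5)) for t in four_state.allowed}
        beta = {t: {"z": float(rng.normal(0, 1))} for t in four_state.allowed
                if t != ("D0", "R")}
        params = ModelParameters.from_intensities(lam, beta)
        codes = rng.choice(["0", "D1", "D2"], size=rng.integers(2, 10))
        times = np.cumsum(rng.uniform(0.2, 2.0, size=len(codes)))
        subj = make_subject(codes, times=times, z={"z": float(rng.integers(0, 2))})
        got = subject_loglik_partial(subj, params, four_state)
        want = enumerate_loglik(subj, params, four_state)
        assert got == pytest.approx(want, rel=1e-12)

    def test_marginal_is_sum_over_revealed_completions(self, four_state, scenario1_params):
        """exp(partial loglik) = sum of exp(complete loglik) over completions."""
        subj = make_subject(["D1", "0", "0"], z={"z": 0.0})
        total = 0.0
        for a in ("R", "D0"):
            for b in ("R", "D0"):
                revealed = make_subject(["D1", a, b], z={"z": 0.0})
                ll = subject_loglik_complete(revealed, scenario1_params, four_state)
                if a == "R" and b != "R":  # leaves R: zero weight
                    assert ll == -math.inf
                total += 0.0 if ll == -math.inf else math.exp(ll)
        got = subject_loglik_partial(subj, scenario1_params, four_state)
        assert math.exp(got) == pytest.approx(total, rel=1e-13)

    def test_trailing_zero_run_weights_resolution_monotonically(
        self, four_state, scenario1_params
    ):
        """Longer symptom-free tails shift posterior mass onto the resolved state."""
        posts = []
        for k in range(1, 7):
            subj = make_subject(["D1"] + ["0"] * k, z={"z": 0.0})
            ev = PanelLikelihood([subj], four_state)
            alpha = ev.filtered_state_probs(scenario1_params)[0]
            posts.append(alpha[four_state.index("R")])
        assert all(b >= a for a, b in zip(posts, posts[1:]))
        assert all(0.0 <= p <= 1.0 for p in posts)


class TestInitialStateTerm:
    def test_ambiguous_entry_defaults_to_temporary(self, four_state):
        term = initial_state_term(PanelObservation(0.0, "0"), four_state)
        assert term == {"R": 0.0, "D0": 1.0}

    def test_disability_entry_is_point_mass(self, four_state):
        term = initial_state_term(PanelObservation(0.0, "D2"), four_state)
        assert term == {"D2": 1.0}

    def test_configurable_split_passes_through(self, four_state):
        term = initial_state_term(
            PanelObservation(0.0, "0"), four_state, ambiguous_split=(0.1, 0.9)
        )
        assert term == {"R": 0.1, "D0": 0.9}

    def test_split_affects_partial_likelihood(self, four_state, scenario1_params):
        subj = make_subject(["0", "D1"], z={"z": 0.0})
        default = subject_loglik_partial(subj, scenario1_params, four_state)
        split = subject_loglik_partial(
            subj, scenario1_params, four_state, ambiguous_split=(0.5, 0.5)
        )
        # starting resolved can never reach D1, so halving the D0 mass halves L
        assert split == pytest.approx(default + math.log(0.5), rel=1e-12)


class TestTotalLoglik:
    def test_single_subject_equals_subject_value(self, four_state, scenario1_params):
        subj = make_subject(["D1", "0"], z={"z": 0.0})
        assert total_loglik([subj], scenario1_params, four_state) == pytest.approx(
            subject_loglik_partial(subj, scenario1_params, four_state)
        )

    def test_duplicated_dataset_scales_linearly(self, four_state, scenario1_params):
        subj = make_subject(["D2", "0", "D1"], z={"z": 1.0})
        one = total_loglik([subj], scenario1_params, four_state)
        five = total_loglik([subj] * 5, scenario1_params, four_state)
        assert five == pytest.approx(5 * one, rel=1e-12)

    def test_empty_dataset_is_an_error(self, four_state, scenario1_params):
        with pytest.raises(ValueError, match="empty"):
            total_loglik([], scenario1_params, four_state)

    def test_tied_visit_times_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            make_subject(["D1", "D1"], times=[1.0, 1.0])

    def test_truth_dominates_perturbed_parameters(self, four_state):
        """At the generating Θ the likelihood usually beats a perturbed Θ."""
        from resolvemsm import generate_scenario_dataset, scenario_config

        cfg = scenario_config(1, n_subjects=120)
        truth = cfg.true_parameters()
        shifted = truth.unpack(truth.pack(cfg.space) + 0.3, cfg.space)
        wins = 0
        for rep in range(100):
            sim = generate_scenario_dataset(cfg, "partial", np.random.SeedSequence([7, rep]))
            ev = PanelLikelihood(sim.subjects, cfg.space)
            wins += ev.total(truth) > ev.total(shifted)
        assert wins >= 95
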