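"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import settings

from resolvemsm import (
    ModelParameters,
    PanelObservation,
    StateSpace,
    SubjectHistory,
    build_generator,
    disability_space,
    initial_state_term,
    transition_matrix,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def four_state() -> StateSpace:
    return disability_space(2)


@pytest.fixture(scope="session")
def two_state() -> StateSpace:
    """Minimal absorbing chain D0 -> R."""
    return StateSpace(("R", "D0"), frozenset({("D0", "R")}))


@pytest.fixture(scope="session")
def scenario1_params(four_state) -> ModelParameters:
    return ModelParameters.from_intensities(
        {("D0", "R"): 0.4, ("D0", "D1"): 0.4, ("D1", "D0"): 0.6,
         ("D1", "D2"): 0.6, ("D2", "D1"): 0.4},
        {t: {"z": 1.0} for t in [("D0", "D1"), ("D1", "D0"), ("D1", "D2"), ("D2", "D1")]},
    )


def make_subject(codes, times=None, z=None, sid="S1") -> SubjectHistory:
    times = list(times) if times is not None else list(range(len(codes)))
    z = z or {}
    return SubjectHistory(
        sid, [PanelObservation(float(t), str(c), z) for t, c in zip(times, codes)]
    )


def enumerate_loglik(subject, params, space, ambiguous_split=None) -> float:
    """Brute-force marginal likelihood: literal sum over all latent assignments.

    Independent of the forward recursion — it multiplies individual
    transition-probability entries along every assignment consistent with
    the censored state sets and sums the products.
    """
    obs = subject.observations
    omegas = [sorted(space.censored_set(o.code)) for o in obs]
    init = initial_state_term(obs[0], space, ambiguous_split)
    P = []
    for a, b in zip(obs, obs[1:]):
        Q = build_generator(params, a.z, space)
        P.append(transition_matrix(Q, b.time - a.time))
    idx = {s: i for i, s in enumerate(space.states)}
    total = 0.0
    for path in itertools.product(*omegas):
        w = init.get(path[0], 0.0)
        for j in range(len(path) - 1):
            if w == 0.0:
                break
            w *= P[j][idx[path[j]], idx[path[j + 1]]]
        total += w
    return math.log(total) if total > 0 else -math.inf


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
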