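"""Simulation of latent trajectories, panel observation and masking.

Latent continuous-time paths are drawn by competing-exponentials (Gillespie)
sampling from the generator matrix.  Panel observation records the state
occupied at each scheduled visit (right-continuous: a jump exactly at a
visit time reports the new state).  Masking replaces the latent labels R and
D0 with the ambiguous observed code "0", producing the partial-observation
regime in which resolution is never directly seen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data import PanelObservation, SubjectHistory
from .params import ModelParameters
from .states import AMBIGUOUS_CODE, StateSpace, disability_space

__all__ = [
    "SamplePath",
    "ScenarioConfig",
    "SimulatedDataset",
    "scenario_config",
    "simulate_path",
    "panel_observe",
    "mask_resolution",
    "generate_scenario_dataset",
    "generate_psa_like_dataset",
    "PSA_LIKE_SPEC",
]

Transition = tuple[str, str]


@dataclass(frozen=True)
class SamplePath:
    """A latent trajectory: jump times (first is 0) and the state entered at each."""

    times: tuple[float, ...]
    states: tuple[str, ...]
    horizon: float

    def state_at(self, t: float) -> str:
        """State occupied at time t (right-continuous step function)."""
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.states[max(idx, 0)]


@dataclass(frozen=True)
class ScenarioConfig:
    """Design of a simulated panel study.

    ``lam`` holds natural-scale baseline intensities (a zero switches a
    transition off in the generating process); ``beta`` the per-transition
    coefficients of the named covariates.  ``allocation`` fixes how many
    subjects start in each transient state; the single binary covariate is
    assigned balanced (exactly half ones) within each initial-state group by
    default, or by independent Bernoulli draws with ``covariate_mode="bernoulli"``.
    """

    space: StateSpace
    lam: Mapping[Transition, float]
    beta: Mapping[Transition, Mapping[str, float]]
    allocation: Mapping[str, int]
    visit_times: tuple[float, ...]
    covariate: str = "z"
    covariate_p: float = 0.5
    covariate_mode: str = "balanced"
    horizon: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.horizon is None:
            object.__setattr__(self, "horizon", self.visit_times[-1])
        if self.horizon < self.visit_times[-1]:
            raise ValueError("horizon must cover the last visit")
        if self.covariate_mode not in ("balanced", "bernoulli"):
            raise ValueError(f"unknown covariate_mode {self.covariate_mode!r}")

    @property
    def n_subjects(self) -> int:
        return sum(self.allocation.values())

    def generator(self, z: Mapping[str, float]) -> np.ndarray:
        """True generating Q at covariate vector z (zero rates allowed)."""
        n = self.space.n_states
        idx = {s: i for i, s in enumerate(self.space.states)}
        Q = np.zeros((n, n))
        for (r, s), rate in self.lam.items():
            eta = sum(c * z[name] for name, c in self.beta.get((r, s), {}).items())
            Q[idx[r], idx[s]] = rate * math.exp(eta)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def true_parameters(self) -> ModelParameters:
        """The generating Θ as ModelParameters (requires all rates positive)."""
        return ModelParameters.from_intensities(
            dict(self.lam), {k: dict(v) for k, v in self.beta.items()}
        )


#: Baseline intensities of the two four-state study scenarios
#: (transitions per year; severity ladder R, D0, D1, D2).
SCENARIO_RATES: dict[int, dict[Transition, float]] = {
    1: {("D0", "R"): 0.4, ("D0", "D1"): 0.4, ("D1", "D0"): 0.6,
        ("D1", "D2"): 0.6, ("D2", "D1"): 0.4},
    2: {("D0", "R"): 0.06, ("D0", "D1"): 0.06, ("D1", "D0"): 0.08,
        ("D1", "D2"): 0.08, ("D2", "D1"): 0.06},
}


def scenario_config(
    scenario: int,
    n_subjects: int = 480,
    lam: Mapping[Transition, float] | None = None,
    covariate_mode: str = "balanced",
) -> ScenarioConfig:
    """The two standard four-state study designs.

    480 subjects split equally over the transient states D0, D1, D2 at entry,
    annual visits over an 8-year follow-up, and a balanced binary covariate
    with coefficient 1 on every transition except resolution (D0→R), whose
    identifiability is the object of study.  ``lam`` overrides individual
    generating rates (e.g. ``{("D0","R"): 0.0}`` for a no-resolution null);
    ``n_subjects`` scales the allocation while keeping it equal across
    initial states.
    """
    if scenario not in SCENARIO_RATES:
        raise ValueError(f"scenario must be one of {sorted(SCENARIO_RATES)}")
    if n_subjects % 6 != 0:
        raise ValueError("n_subjects must be divisible by 6 (3 initial states × 2 z groups)")
    rates = dict(SCENARIO_RATES[scenario])
    rates.update(lam or {})
    space = disability_space(2)
    beta = {t: {"z": 1.0} for t in rates if t != ("D0", "R")}
    per = n_subjects // 3
    return ScenarioConfig(
        space=space,
        lam=rates,
        beta=beta,
        allocation={"D0": per, "D1": per, "D2": per},
        visit_times=tuple(float(t) for t in range(9)),
        covariate_mode=covariate_mode,
    )


def simulate_path(
    Q: np.ndarray,
    start: str,
    horizon: float,
    rng: np.random.Generator,
    space: StateSpace,
) -> SamplePath:
    """Sample one latent trajectory by competing exponentials.

    From state s, the holding time is Exponential(−Q[s,s]) and the next state
    is drawn with probability Q[s,s']/(−Q[s,s]).  Sampling stops at the
    horizon or on entering an absorbing state (zero exit rate).
    """
    i = space.index(start)
    t = 0.0
    times = [0.0]
    states = [start]
    while True:
        rate = -Q[i, i]
        if rate <= 0.0:
            break
        t += rng.exponential(1.0 / rate)
        if t > horizon:
            break
        probs = np.clip(Q[i], 0.0, None)
        probs[i] = 0.0
        i = rng.choice(len(probs), p=probs / probs.sum())
        times.append(t)
        states.append(space.states[i])
    return SamplePath(tuple(times), tuple(states), horizon)


def panel_observe(path: SamplePath, visit_times: Sequence[float]) -> list[str]:
    """Latent state occupied at each visit time."""
    if visit_times and max(visit_times) > path.horizon:
        raise ValueError("visit times must lie within the simulated horizon")
    return [path.state_at(t) for t in visit_times]


def mask_resolution(
    visit_states: Sequence[str], space: StateSpace | None = None
) -> list[str]:
    """Replace the latent labels R and D0 by the ambiguous observed code."""
    hidden = {"R", "D0"} if space is None else {space.states[0], space.states[1]}
    return [AMBIGUOUS_CODE if s in hidden else s for s in visit_states]


@dataclass
class SimulatedDataset:
    """Observed panel data plus the generating truth, for oracle checks."""

    subjects: list[SubjectHistory]
    paths: list[SamplePath]
    latent_visit_states: list[list[str]]
    config: ScenarioConfig
    regime: str


def generate_scenario_dataset(
    config: ScenarioConfig,
    regime: str = "partial",
    seed: int | np.random.SeedSequence | None = None,
) -> SimulatedDataset:
    """Simulate one panel dataset under a study design.

    Per subject: assign the binary covariate (balanced within the subject's
    initial-state group), build the generating Q, sample the latent path,
    read it off at the visit schedule, and — under ``regime="partial"`` —
    mask R/D0 into code "0".  Deterministic given the seed; the complete and
    partial datasets from the same seed differ only in that masking.
    """
    if regime not in ("complete", "partial"):
        raise ValueError(f"regime must be 'complete' or 'partial', got {regime!r}")
    rng = np.random.default_rng(seed)
    subjects: list[SubjectHistory] = []
    paths: list[SamplePath] = []
    latent: list[list[str]] = []
    sid = 0
    for start, count in config.allocation.items():
        if config.covariate_mode == "balanced":
            if count % 2:
                raise ValueError("balanced covariate assignment needs even group sizes")
            zs = np.repeat([0.0, 1.0], count // 2)
        else:
            zs = (rng.random(count) < config.covariate_p).astype(float)
        for z in zs:
            sid += 1
            zdict = {config.covariate: float(z)}
            path = simulate_path(
                config.generator(zdict), start, config.horizon, rng, config.space
            )
            states = panel_observe(path, config.visit_times)
            codes = mask_resolution(states, config.space) if regime == "partial" else states
            obs = [
                PanelObservation(time=t, code=c, z=zdict)
                for t, c in zip(config.visit_times, codes)
            ]
            subjects.append(SubjectHistory(f"S{sid:04d}", obs))
            paths.append(path)
            latent.append(states)
    return SimulatedDataset(subjects, paths, latent, config, regime)


# ---------------------------------------------------------------------------
# Synthetic five-state clinic-like dataset
# ---------------------------------------------------------------------------

#: Synthetic five-state configuration shaped like a psoriatic-arthritis
#: disability cohort: severity ladder R, D0, D1, D2, D3; slow resolution;
#: patient-level covariates sex (1 = male), age at arthritis onset (years,
#: centred at 37), arthritis duration at entry (years, centred at 9) and
#: clinically damaged joint count.  The rates and coefficients are invented
#: but plausible for a disability process on the year scale.
PSA_LIKE_SPEC: dict = {
    "lam": {
        ("D0", "R"): 0.04, ("D0", "D1"): 0.5, ("D1", "D0"): 1.0,
        ("D1", "D2"): 0.9, ("D2", "D1"): 0.75, ("D2", "D3"): 0.08,
        ("D3", "D2"): 0.6,
    },
    "beta": {
        ("D0", "D1"): {"male": -0.15},
        ("D1", "D0"): {"male": 0.7, "age_onset_c": -0.015, "duration_c": -0.03},
        ("D1", "D2"): {"male": -0.35, "duration_c": -0.035},
        ("D2", "D1"): {"damaged_joints": -0.015, "duration_c": -0.03},
        ("D2", "D3"): {"duration_c": 0.03},
        ("D3", "D2"): {"damaged_joints": -0.017},
    },
    # baseline state frequencies at clinic entry (observed code for R/D0 is "0")
    "initial_probs": {"D0": 0.221, "D1": 0.221, "D2": 0.407, "D3": 0.151},
    # inter-visit gaps drawn from a half-year grid with mean 1.5 years
    "gap_choices": (0.5, 1.0, 1.5, 2.0, 2.5, 3.0),
    "gap_probs": (0.15, 0.3, 0.25, 0.15, 0.1, 0.05),
    "mean_extra_visits": 4.4,   # visits per subject = 2 + Poisson(·), capped at 18
    "max_visits": 18,
    "p_male": 0.59,
    "age_onset_mean": 36.6, "age_onset_sd": 12.9,
    "duration_mean": 9.2,
    "damaged_joints_mean": 5.0, "damaged_joints_shape": 0.35,
}


def generate_psa_like_dataset(
    n_subjects: int = 597,
    seed: int | np.random.SeedSequence | None = None,
    spec: Mapping | None = None,
) -> SimulatedDataset:
    """Synthetic five-state cohort with irregular visits and masked resolution.

    Emulates the *shape* of a tertiary-clinic disability cohort — five
    latent states, patient-level covariates, irregular inter-visit gaps with
    mean ≈ 1.5 years — under invented, documented parameters.  Continuous
    covariates enter centred so the baseline intensities describe an average
    patient.  Output codes are masked (partial-observation regime), as real
    data would be.
    """
    sp = dict(PSA_LIKE_SPEC)
    sp.update(spec or {})
    space = disability_space(3)
    rng = np.random.default_rng(seed)
    cfg = ScenarioConfig(
        space=space,
        lam=sp["lam"],
        beta=sp["beta"],
        allocation={"D0": n_subjects},  # placeholder; entry states drawn below
        visit_times=(0.0, 1.0),
        covariate="male",
        horizon=float(sp["max_visits"]) * max(sp["gap_choices"]),
    )
    init_states = list(sp["initial_probs"])
    init_p = np.array([sp["initial_probs"][s] for s in init_states], dtype=float)
    init_p /= init_p.sum()

    subjects: list[SubjectHistory] = []
    paths: list[SamplePath] = []
    latent: list[list[str]] = []
    for i in range(1, n_subjects + 1):
        covs = {
            "male": float(rng.random() < sp["p_male"]),
            "age_onset_c": float(rng.normal(0.0, sp["age_onset_sd"])),
            "duration_c": float(rng.exponential(sp["duration_mean"]) - sp["duration_mean"]),
            "damaged_joints": float(
                rng.negative_binomial(
                    sp["damaged_joints_shape"],
                    sp["damaged_joints_shape"]
                    / (sp["damaged_joints_shape"] + sp["damaged_joints_mean"]),
                )
            ),
        }
        n_visits = 2 + int(rng.poisson(sp["mean_extra_visits"]))
        n_visits = min(n_visits, int(sp["max_visits"]))
        gaps = rng.choice(sp["gap_choices"], size=n_visits - 1, p=sp["gap_probs"])
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        start = init_states[rng.choice(len(init_states), p=init_p)]
        Q = cfg.generator(covs)
        path = simulate_path(Q, start, float(times[-1]), rng, space)
        states = [path.state_at(t) for t in times]
        codes = mask_resolution(states, space)
        obs = [PanelObservation(time=float(t), code=c, z=covs) for t, c in zip(times, codes)]
        subjects.append(SubjectHistory(f"P{i:04d}", obs))
        paths.append(path)
        latent.append(states)
    return SimulatedDataset(subjects, paths, latent, cfg, "partial")
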