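"""Marginal likelihood for panel data with a latent resolved state.

For fully observed latent states the likelihood of a subject's visit sequence
is the product of interval transition probabilities, conditional on the first
state.  When "no disability" is observed, the latent state is ambiguous
between resolved (R) and temporary non-disability (D0); the marginal
likelihood sums over every latent assignment consistent with the censored
state sets Ω_j.  That sum is evaluated by a forward recursion over Ω
(hidden-Markov style), which is mathematically identical to the literal
nested sums but linear rather than exponential in the number of ambiguous
visits:

    α_{j+1}(s) = Σ_{r ∈ Ω_j} α_j(r) · P(dt_j)[r, s],   s ∈ Ω_{j+1},

started from the initial-state distribution on Ω_0.  Paths that leave R get
zero weight automatically because row R of P(dt) is a point mass at R.
Accumulation is in the log domain with per-visit rescaling, so long
symptom-free tails do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import PanelObservation, SubjectHistory
from .generator import build_generator, transition_matrix
from .params import ModelParameters
from .states import StateSpace

__all__ = [
    "initial_state_term",
    "subject_loglik_complete",
    "subject_loglik_partial",
    "total_loglik",
    "PanelLikelihood",
]


def initial_state_term(
    first_obs: PanelObservation,
    space: StateSpace,
    ambiguous_split: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Distribution of the latent initial state given the first observed code.

    A disability code pins the latent state down.  For the ambiguous
    symptom-free code the default convention is a point mass on temporary
    non-disability D0 — appropriate when subjects enter the study through a
    referral process that makes entry-while-resolved implausible.
    ``ambiguous_split=(p_R, p_D0)`` overrides the convention for sensitivity
    analyses.
    """
    omega = space.censored_set(first_obs.code)
    if len(omega) == 1:
        return {next(iter(omega)): 1.0}
    resolved, temp = space.states[0], space.states[1]
    if omega != frozenset({resolved, temp}):
        raise ValueError(f"unexpected ambiguous state set {set(omega)}")
    if ambiguous_split is None:
        return {resolved: 0.0, temp: 1.0}
    p_r, p_d0 = ambiguous_split
    if p_r < 0 or p_d0 < 0 or abs(p_r + p_d0 - 1.0) > 1e-12:
        raise ValueError("ambiguous_split must be a probability pair summing to 1")
    return {resolved: float(p_r), temp: float(p_d0)}


@dataclass
class _SubjectLayout:
    mask: np.ndarray      # (n_visits, n_states) bool, Ω membership per visit
    init: np.ndarray      # (n_states,) initial latent distribution on Ω_0
    signature: tuple      # (dt sequence, covariate sequence) batching key


class PanelLikelihood:
    """Reusable likelihood evaluator for a fixed dataset and state space.

    Precomputes, once, everything that does not depend on Θ: censored-state
    masks, initial distributions, interval lengths and covariate values, and
    a batching of subjects that share the same visit grid and covariates so
    the forward recursion runs vectorised across each batch.  Transition
    matrices are cached per unique (covariate vector, interval length) pair
    within one evaluation, so a dataset with a shared visit schedule and a
    binary covariate needs only a handful of matrix exponentials per call.
    """

    def __init__(
        self,
        dataset: Sequence[SubjectHistory],
        space: StateSpace,
        ambiguous_split: tuple[float, float] | None = None,
    ) -> None:
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.space = space
        self.n_subjects = len(dataset)
        self.n_observations = sum(len(s) for s in dataset)
        self.subject_ids = [s.subject_id for s in dataset]

        n = space.n_states
        state_idx = {s: i for i, s in enumerate(space.states)}
        layouts: list[_SubjectLayout] = []
        for subj in dataset:
            subj.validate_codes(space)
            obs = subj.observations
            mask = np.zeros((len(obs), n), dtype=bool)
            for j, o in enumerate(obs):
                for s in space.censored_set(o.code):
                    mask[j, state_idx[s]] = True
            init = np.zeros(n)
            for s, p in initial_state_term(obs[0], space, ambiguous_split).items():
                init[state_idx[s]] = p
            dts = tuple(b.time - a.time for a, b in zip(obs, obs[1:]))
            zsig = tuple(tuple(sorted(o.z.items())) for o in obs[:-1])
            layouts.append(_SubjectLayout(mask, init, (dts, zsig)))

        # batch subjects sharing (dt grid, covariate sequence)
        self._batches: list[dict] = []
        groups: dict[tuple, list[int]] = {}
        for i, lay in enumerate(layouts):
            groups.setdefault(lay.signature, []).append(i)
        for (dts, zsig), members in groups.items():
            self._batches.append(
                {
                    "members": np.array(members),
                    "dts": dts,
                    "zs": [dict(z) for z in zsig],
                    "zkeys": list(zsig),
                    "mask": np.stack([layouts[i].mask for i in members]),
                    "init": np.stack([layouts[i].init for i in members]),
                }
            )

    # -- evaluation -------------------------------------------------------

    def _transition_cache(self, params: ModelParameters) -> dict[tuple, np.ndarray]:
        cache: dict[tuple, np.ndarray] = {}
        q_cache: dict[tuple, np.ndarray] = {}
        for batch in self._batches:
            for zkey, z, dt in zip(batch["zkeys"], batch["zs"], batch["dts"]):
                key = (zkey, dt)
                if key in cache:
                    continue
                if zkey not in q_cache:
                    q_cache[zkey] = build_generator(params, z, self.space)
                cache[key] = transition_matrix(q_cache[zkey], dt)
        return cache

    def subject_logliks(self, params: ModelParameters) -> np.ndarray:
        """Per-subject marginal log-likelihoods, in dataset order."""
        params.validate(self.space)
        P = self._transition_cache(params)
        out = np.empty(self.n_subjects)
        for batch in self._batches:
            mask = batch["mask"]          # (B, m+1, n)
            alpha = batch["init"] * mask[:, 0, :]
            ll = np.zeros(len(alpha))
            dead = ~np.any(alpha > 0, axis=1)
            for j, (zkey, dt) in enumerate(zip(batch["zkeys"], batch["dts"])):
                alpha = (alpha @ P[(zkey, dt)]) * mask[:, j + 1, :]
                c = alpha.sum(axis=1)
                alive = c > 0
                dead |= ~alive
                with np.errstate(divide="ignore"):
                    ll += np.where(alive, np.log(np.where(alive, c, 1.0)), 0.0)
                alpha = np.where(alive[:, None], alpha / np.where(alive, c, 1.0)[:, None], 0.0)
            ll[dead] = -np.inf
            out[batch["members"]] = ll
        return out

    def filtered_state_probs(self, params: ModelParameters) -> list[np.ndarray]:
        """Per-batch normalised forward distributions α_j at the final visit.

        The entry for state s is P(X(t_m) = s | all observed codes) — useful
        for inspecting how trailing symptom-free runs shift weight onto the
        resolved state.
        """
        params.validate(self.space)
        P = self._transition_cache(params)
        final: list[np.ndarray] = [np.empty(0)] * self.n_subjects
        for batch in self._batches:
            mask = batch["mask"]
            alpha = batch["init"] * mask[:, 0, :]
            for j, (zkey, dt) in enumerate(zip(batch["zkeys"], batch["dts"])):
                alpha = (alpha @ P[(zkey, dt)]) * mask[:, j + 1, :]
                c = alpha.sum(axis=1, keepdims=True)
                alpha = np.where(c > 0, alpha / np.where(c > 0, c, 1.0), 0.0)
            for row, i in zip(alpha, batch["members"]):
                final[i] = row
        return final

    def total(self, params: ModelParameters) -> float:
        ll = self.subject_logliks(params)
        if np.any(np.isneginf(ll)):
            bad = [self.subject_ids[i] for i in np.flatnonzero(np.isneginf(ll))[:5]]
            import logging

            logging.getLogger(__name__).warning(
                "zero-probability histories for subject(s) %s at the supplied parameters",
                ", ".join(map(str, bad)),
            )
            return -np.inf
        return float(ll.sum())


def subject_loglik_partial(
    subject: SubjectHistory,
    params: ModelParameters,
    space: StateSpace,
    ambiguous_split: tuple[float, float] | None = None,
) -> float:
    """Marginal log-likelihood of one subject, summing over latent assignments."""
    ev = PanelLikelihood([subject], space, ambiguous_split)
    return float(ev.subject_logliks(params)[0])


def subject_loglik_complete(
    subject: SubjectHistory,
    params: ModelParameters,
    space: StateSpace,
) -> float:
    """Log-likelihood with fully known latent states (every code a singleton)."""
    for obs in subject.observations:
        if len(space.censored_set(obs.code)) != 1:
            raise ValueError(
                f"subject {subject.subject_id!r}: code {obs.code!r} at t={obs.time} is "
                "ambiguous; the complete-observation likelihood needs revealed labels"
            )
    return subject_loglik_partial(subject, params, space)


def total_loglik(
    dataset: Sequence[SubjectHistory],
    params: ModelParameters,
    space: StateSpace,
    ambiguous_split: tuple[float, float] | None = None,
) -> float:
    """Sum of per-subject marginal log-likelihoods."""
    return PanelLikelihood(dataset, space, ambiguous_split).total(params)
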