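"""Model parameters: log baseline intensities and per-transition covariate effects."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .states import StateSpace

__all__ = ["ModelParameters"]

Transition = tuple[str, str]


@dataclass
class ModelParameters:
    """The parameter vector Θ of a proportional-intensity multistate model.

    Each allowed transition ``(r, s)`` carries a baseline intensity λ_rs,
    stored on the log scale so that positivity is automatic during
    optimisation, and optionally a vector of regression coefficients β_rs
    acting multiplicatively through ``λ_rs · exp(β_rs' z)``.

    ``beta`` maps a transition to an ordered ``{covariate name: coefficient}``
    dict; a transition absent from ``beta`` has no covariate effect (as for
    the resolution transition in the simulation scenarios).
    """

    log_lambda: dict[Transition, float]
    beta: dict[Transition, dict[str, float]] = field(default_factory=dict)

    @classmethod
    def from_intensities(
        cls,
        lam: dict[Transition, float],
        beta: dict[Transition, dict[str, float]] | None = None,
    ) -> "ModelParameters":
        """Build from natural-scale baseline intensities (must be > 0)."""
        for k, v in lam.items():
            if v <= 0:
                raise ValueError(f"baseline intensity for {k} must be positive, got {v}")
        return cls({k: math.log(v) for k, v in lam.items()}, dict(beta or {}))

    def validate(self, space: StateSpace) -> None:
        if set(self.log_lambda) != set(space.allowed):
            raise ValueError(
                "log_lambda keys must equal the allowed transition set; "
                f"extra={set(self.log_lambda) - set(space.allowed)}, "
                f"missing={set(space.allowed) - set(self.log_lambda)}"
            )
        stray = set(self.beta) - set(space.allowed)
        if stray:
            raise ValueError(f"beta given for non-allowed transitions {sorted(stray)}")

    @property
    def lam(self) -> dict[Transition, float]:
        """Baseline intensities on the natural scale."""
        return {k: math.exp(v) for k, v in self.log_lambda.items()}

    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for coefs in self.beta.values():
            for name in coefs:
                if name not in names:
                    names.append(name)
        return names

    # -- flat-vector view used by the optimiser ---------------------------

    def free_names(self, space: StateSpace) -> list[str]:
        """Stable labels for the free parameter vector: log-λ first, then β."""
        names = [f"loglam_{r}->{s}" for r, s in self._ordered_transitions(space)]
        for r, s in self._ordered_transitions(space):
            for cov in self.beta.get((r, s), {}):
                names.append(f"beta_{r}->{s}:{cov}")
        return names

    def _ordered_transitions(self, space: StateSpace) -> list[Transition]:
        idx = {s: i for i, s in enumerate(space.states)}
        return sorted(self.log_lambda, key=lambda t: (idx[t[0]], idx[t[1]]))

    def pack(self, space: StateSpace) -> np.ndarray:
        order = self._ordered_transitions(space)
        vec = [self.log_lambda[t] for t in order]
        for t in order:
            vec.extend(self.beta.get(t, {}).values())
        return np.asarray(vec, dtype=float)

    def unpack(self, vec: np.ndarray, space: StateSpace) -> "ModelParameters":
        """Rebuild parameters with the same structure from a flat vector."""
        order = self._ordered_transitions(space)
        vec = np.asarray(vec, dtype=float)
        log_lambda = dict(zip(order, vec[: len(order)]))
        beta: dict[Transition, dict[str, float]] = {}
        pos = len(order)
        for t in order:
            coefs = self.beta.get(t)
            if coefs:
                beta[t] = {name: float(vec[pos + i]) for i, name in enumerate(coefs)}
                pos += len(coefs)
        if pos != vec.size:
            raise ValueError(f"parameter vector has length {vec.size}, expected {pos}")
        return ModelParameters(log_lambda, beta)

    def n_free(self, space: StateSpace) -> int:
        return len(self.log_lambda) + sum(len(c) for c in self.beta.values())
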