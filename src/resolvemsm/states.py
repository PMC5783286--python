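"""State spaces for multistate disease processes with a latent resolved state.

The model partitions "no symptoms" into two latent states: an absorbing
*resolved* state ``R`` (once entered, no further symptoms ever occur) and a
transient *temporary non-disability* state ``D0``.  Increasing severity states
``D1 … Dm`` are reachable only through adjacent severity levels.  Observation
is through codes: disability codes identify their latent state exactly, while
the code ``0`` ("no disability") is ambiguous between ``R`` and ``D0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = ["StateSpace", "disability_space"]

RESOLVED = "R"
TEMP_NONDISABILITY = "D0"
AMBIGUOUS_CODE = "0"


@dataclass(frozen=True)
class StateSpace:
    """Latent state space, allowed transitions, and the observation map.

    Parameters
    ----------
    states
        Ordered latent state labels.  The first element must be the absorbing
        resolved state ``R`` and the second the temporary non-disability state
        ``D0``; all matrices produced by this package are indexed in this
        order.
    allowed
        Ordered pairs ``(r, s)`` of states with positive transition intensity.
    observable_map
        Map from observed code to the non-empty set of latent states
        consistent with it (the censored state set Ω).  The ambiguous code
        ``"0"`` maps to ``{R, D0}``; every other code is a singleton.
    """

    states: tuple[str, ...]
    allowed: frozenset[tuple[str, str]]
    observable_map: Mapping[str, frozenset[str]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError("need at least the resolved and one transient state")
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state labels")
        if self.observable_map is None:
            object.__setattr__(self, "observable_map", self._default_observable_map())
        object.__setattr__(self, "allowed", frozenset(self.allowed))
        resolved = self.states[0]
        for r, s in self.allowed:
            if r not in self.states or s not in self.states:
                raise ValueError(f"transition ({r}, {s}) uses unknown state")
            if r == s:
                raise ValueError(f"self-transition ({r}, {s}) not allowed")
            if r == resolved:
                raise ValueError(f"resolved state {resolved!r} must be absorbing")
        seen: set[str] = set()
        for code, latent in self.observable_map.items():
            if not latent:
                raise ValueError(f"code {code!r} maps to an empty state set")
            unknown = set(latent) - set(self.states)
            if unknown:
                raise ValueError(f"code {code!r} maps to unknown states {sorted(unknown)}")
            seen |= set(latent)
        missing = set(self.states) - seen
        if missing:
            raise ValueError(f"states {sorted(missing)} not reachable from any observed code")

    def _default_observable_map(self) -> dict[str, frozenset[str]]:
        mapping: dict[str, frozenset[str]] = {
            AMBIGUOUS_CODE: frozenset({self.states[0], self.states[1]})
        }
        for s in self.states:
            mapping[s] = frozenset({s})
        return mapping

    # -- indexing helpers -------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def resolved(self) -> str:
        return self.states[0]

    def index(self, state: str) -> int:
        return self.states.index(state)

    def indices(self, states: Iterable[str]) -> list[int]:
        return sorted(self.states.index(s) for s in states)

    def censored_set(self, code: str) -> frozenset[str]:
        """Return Ω(code), the latent states consistent with an observed code."""
        try:
            return self.observable_map[code]
        except KeyError:
            raise KeyError(
                f"unknown state code {code!r}; known codes: {sorted(self.observable_map)}"
            ) from None

    def drop_transition(self, r: str, s: str) -> "StateSpace":
        """A copy of the space without the (r, s) transition (for nested nulls)."""
        pair = (r, s)
        if pair not in self.allowed:
            raise ValueError(f"transition {pair} not in the allowed set")
        return StateSpace(self.states, self.allowed - {pair}, self.observable_map)


def disability_space(n_disability: int) -> StateSpace:
    """Standard severity ladder ``(R, D0, D1, …, Dm)`` with adjacent moves only.

    ``D0`` connects to ``R`` (resolution) and ``D1``; each ``Dk`` connects to
    its neighbours ``Dk-1`` and ``Dk+1``.  ``n_disability`` is the number of
    disability severity levels m (so the four-state process of the simulation
    scenarios is ``disability_space(2)``).
    """
    if n_disability < 1:
        raise ValueError("need at least one disability severity state")
    states = [RESOLVED, TEMP_NONDISABILITY] + [f"D{k}" for k in range(1, n_disability + 1)]
    allowed = {(TEMP_NONDISABILITY, RESOLVED)}
    ladder = states[1:]
    for a, b in zip(ladder, ladder[1:]):
        allowed.add((a, b))
        allowed.add((b, a))
    return StateSpace(tuple(states), frozenset(allowed))
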