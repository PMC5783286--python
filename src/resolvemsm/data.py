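"""Long-format panel data containers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .states import StateSpace

__all__ = ["PanelObservation", "SubjectHistory"]


@dataclass(frozen=True)
class PanelObservation:
    """One clinic visit: time (years since first visit), observed code, covariates."""

    time: float
    code: str
    z: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"visit time must be non-negative, got {self.time}")


@dataclass
class SubjectHistory:
    """Time-ordered visit records for one subject (at least two visits)."""

    subject_id: str
    observations: list[PanelObservation]

    def __post_init__(self) -> None:
        if len(self.observations) < 2:
            raise ValueError(
                f"subject {self.subject_id!r} has {len(self.observations)} visit(s); "
                "at least 2 are required"
            )
        times = [o.time for o in self.observations]
        for a, b in zip(times, times[1:]):
            if b <= a:
                raise ValueError(
                    f"subject {self.subject_id!r} has non-increasing visit times "
                    f"({a} followed by {b})"
                )

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[PanelObservation]:
        return iter(self.observations)

    def validate_codes(self, space: StateSpace) -> None:
        for obs in self.observations:
            space.censored_set(obs.code)
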