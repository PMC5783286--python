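"""Readers, writers, model configuration and run manifests.

Panel data travel as long-format CSV: one row per clinic visit with columns
``subject_id``, ``time`` (decimal years since the subject's first visit),
``state_code`` and one column per covariate.  Model configuration is a
small YAML (or JSON) document listing the states, the allowed transitions
with their covariates, and initial parameter values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .data import PanelObservation, SubjectHistory
from .params import ModelParameters
from .states import StateSpace

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "load_model_config",
    "RunManifest",
    "write_manifest",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "time", "state_code")


def read_panel_csv(path: str | Path, space: StateSpace) -> list[SubjectHistory]:
    """Load and validate long-format panel data.

    Codes are checked against the space's observation map (error names the
    offending row), times must be strictly increasing within a subject, and
    subjects with fewer than two visits are dropped with a warning count.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    covariates = [c for c in df.columns if c not in REQUIRED_COLUMNS]

    for rownum, code in zip(df.index, df["state_code"].astype(str)):
        if code not in space.observable_map:
            raise ValueError(
                f"{path}: unknown state code {code!r} at row {rownum + 2} "
                f"(known codes: {sorted(space.observable_map)})"
            )

    subjects: list[SubjectHistory] = []
    dropped = 0
    for sid, sub in df.groupby("subject_id", sort=False):
        if len(sub) < 2:
            dropped += 1
            continue
        times = sub["time"].to_numpy(dtype=float)
        if not (times[1:] > times[:-1]).all():
            raise ValueError(f"{path}: non-increasing visit times for subject {sid!r}")
        obs = [
            PanelObservation(
                time=float(row["time"]),
                code=str(row["state_code"]),
                z={c: float(row[c]) for c in covariates},
            )
            for _, row in sub.iterrows()
        ]
        subjects.append(SubjectHistory(str(sid), obs))
    if dropped:
        log.warning("dropped %d subject(s) with fewer than 2 visits", dropped)
    if not subjects:
        raise ValueError(f"{path}: no subjects with at least 2 visits")
    return subjects


def write_panel_csv(dataset: Sequence[SubjectHistory], path: str | Path) -> None:
    """Write panel data in the long-format CSV schema (UTF-8, '.' decimals)."""
    covariates: list[str] = []
    for subj in dataset:
        for name in subj.observations[0].z:
            if name not in covariates:
                covariates.append(name)
    rows = []
    for subj in dataset:
        for obs in subj.observations:
            row = {"subject_id": subj.subject_id, "time": obs.time, "state_code": obs.code}
            row.update({c: obs.z.get(c, "") for c in covariates})
            rows.append(row)
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + covariates).to_csv(path, index=False)


def load_model_config(path: str | Path) -> tuple[StateSpace, ModelParameters]:
    """Read a model configuration file (YAML or JSON).

    Schema::

        states: [R, D0, D1, D2]          # resolved first, then D0, D1, ...
        transitions:
          - from: D0
            to: R
            init: 0.1                    # initial baseline intensity (> 0)
          - from: D0
            to: D1
            init: 0.1
            covariates: {z: 0.0}         # covariate name -> initial beta
        ...
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in ("states", "transitions"):
        if key not in doc:
            raise ValueError(f"{path}: model config missing {key!r}")
    lam: dict = {}
    beta: dict = {}
    allowed = set()
    for tr in doc["transitions"]:
        pair = (str(tr["from"]), str(tr["to"]))
        allowed.add(pair)
        lam[pair] = float(tr.get("init", 0.1))
        if tr.get("covariates"):
            beta[pair] = {str(k): float(v) for k, v in tr["covariates"].items()}
    space = StateSpace(tuple(str(s) for s in doc["states"]), frozenset(allowed))
    params = ModelParameters.from_intensities(lam, beta)
    params.validate(space)
    return space, params


@dataclasses.dataclass
class RunManifest:
    """Provenance record written alongside every CLI output."""

    tool: str
    version: str
    command: str
    seed: int | None
    config_hash: str | None
    timestamp: str
    records: dict


def write_manifest(
    out_dir: str | Path,
    seed: int | None = None,
    config_path: str | Path | None = None,
    records: dict | None = None,
) -> Path:
    from . import __version__

    digest = None
    if config_path is not None:
        digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()[:16]
    manifest = RunManifest(
        tool="resolvemsm",
        version=__version__,
        command=" ".join(sys.argv),
        seed=seed,
        config_hash=digest,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        records=records or {},
    )
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
    return out
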