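"""File formats, configuration snapshots, and run manifests.

Feature tables travel as long-format CSV (one row per participant per
timestep) with self-describing string labels; results as JSONL or CSV;
every CLI run writes a manifest (seed, config snapshot, file digests)
sufficient to replay it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .states import (
    FEATURE_NAMES,
    BehaviorState,
    Session,
    TASK_KINDS,
    UNLABELED,
    validate_feature_matrix,
)

REQUIRED_COLUMNS = ("session_id", "timestep", "participant") + FEATURE_NAMES


def write_feature_table(sessions: Sequence[Session], path: Union[str, Path]) -> Path:
    """Write sessions as long-format CSV (UTF-8, header, comma-delimited)."""
    path = Path(path)
    rows = []
    for s in sessions:
        for participant, X, labels in (
            ("a", s.features_a, s.labels_a),
            ("b", s.features_b, s.labels_b),
        ):
            for t in range(s.timesteps):
                row = {
                    "session_id": s.session_id,
                    "task_kind": s.task_kind,
                    "timestep": t,
                    "participant": participant,
                }
                row.update({f: int(v) for f, v in zip(FEATURE_NAMES, X[t])})
                if labels is not None:
                    row["label"] = BehaviorState(int(labels[t])).label
                rows.append(row)
    df = pd.DataFrame(rows)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_feature_table(path: Union[str, Path]) -> list[Session]:
    """Load and validate sessions from long-format CSV.

    Rejects missing columns (schema error naming the column), non-binary
    feature values (with the offending CSV row), and feature-logic
    violations (naming the clause). Labels, when present, must be the
    state names.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    has_labels = "label" in df.columns and df["label"].notna().all()

    feat = df[list(FEATURE_NAMES)]
    bad = ~feat.isin((0, 1)).all(axis=1)
    if bad.any():
        # +2: header line and 1-based numbering
        raise ValidationError(
            f"non-binary feature value at file row {int(np.argmax(bad.values)) + 2}"
        )

    sessions = []
    for sid, g in df.groupby("session_id", sort=False):
        task = str(g["task_kind"].iloc[0]) if "task_kind" in g.columns else TASK_KINDS[0]
        parts = {}
        for participant, gp in g.groupby("participant"):
            gp = gp.sort_values("timestep")
            expected = np.arange(len(gp))
            if not np.array_equal(gp["timestep"].to_numpy(), expected):
                raise ValidationError(
                    f"session {sid} participant {participant}: timesteps are not 0..T-1"
                )
            X = validate_feature_matrix(gp[list(FEATURE_NAMES)].to_numpy())
            labels = None
            if has_labels:
                labels = np.array(
                    [int(BehaviorState.from_label(v)) for v in gp["label"]], dtype=np.int8
                )
            parts[str(participant)] = (X, labels)
        if set(parts) != {"a", "b"}:
            raise SchemaError(
                f"session {sid}: expected participants 'a' and 'b', got {sorted(parts)}"
            )
        (Xa, la), (Xb, lb) = parts["a"], parts["b"]
        sessions.append(
            Session(
                session_id=str(sid),
                task_kind=task,
                features_a=Xa,
                features_b=Xb,
                labels_a=la,
                labels_b=lb,
            )
        )
    return sessions


def write_jsonl(records: Iterable[dict], path: Union[str, Path]) -> Path:
    """One JSON object per line, deterministic key order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, sort_keys=True, default=_jsonable) + "\n")
    return path


def read_jsonl(path: Union[str, Path]) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, BehaviorState):
        return obj.label
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def file_digest(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record written alongside every CLI command's outputs."""

    command: str
    version: str
    seed: Optional[int]
    config: dict
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    outputs: dict[str, str] = dataclasses.field(default_factory=dict)
    timestamp: str = dataclasses.field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def add_input(self, path: Union[str, Path]) -> None:
        self.inputs[str(path)] = file_digest(path)

    def add_output(self, path: Union[str, Path]) -> None:
        self.outputs[str(path)] = file_digest(path)

    def write(self, out_dir: Union[str, Path]) -> Path:
        out = Path(out_dir) / "manifest.json"
        out.parent.mkdir(parents=True, exist_ok=True)
        with open(out, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
        return out


def load_config_file(path: Union[str, Path]) -> dict:
    """Read a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    return doc
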