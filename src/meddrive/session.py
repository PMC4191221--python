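"""Session records: the canonical on-disk form of a battery run.

A session record is a versioned JSON document holding the environment
block (frame period, viewing distance), the four task blocks of
trial-level rows, the generative profile and seed when the session is
simulated, and optionally the computed outcomes and scores.  Records are
written canonically — sorted keys, floats at six significant digits —
so identical records are byte-identical, which makes determinism
checkable with a file diff.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from .errors import (
    SchemaValidationError,
    SessionParseError,
    UnsupportedVersionError,
)

SCHEMA_VERSION = "1.0"
SUPPORTED_VERSIONS = {"1.0"}


class EnvironmentBlock(BaseModel):
    frame_ms: float = Field(gt=0)
    viewing_distance_mm: float = Field(default=600.0, gt=0)
    screen_width_mm: Optional[float] = None
    screen_height_mm: Optional[float] = None


class VisualTrialRow(BaseModel):
    task: Literal["visual_recognition"] = "visual_recognition"
    trial_number: int = Field(ge=1)
    subtask: Literal["central", "peripheral", "dual"]
    ladder_index: int = Field(ge=0)
    duration_ms: float = Field(gt=0)
    correct: bool


class RTTrialRow(BaseModel):
    task: Literal["attention", "movement"]
    trial_number: int = Field(ge=1)
    condition: str
    rt_ms: float = Field(gt=0)
    correct: Optional[bool] = None


class MemoryTrialRow(BaseModel):
    task: Literal["memory"] = "memory"
    trial_number: int = Field(ge=1)
    n_crosses: int = Field(ge=2, le=7)
    err_first_mm: float = Field(ge=0)
    err_last_mm: float = Field(ge=0)


class SessionRecord(BaseModel):
    schema_version: str = SCHEMA_VERSION
    session_id: str
    seed: Optional[int] = None
    profile: Optional[dict[str, Any]] = None
    environment: EnvironmentBlock
    visual_trials: list[VisualTrialRow] = Field(default_factory=list)
    attention_trials: list[RTTrialRow] = Field(default_factory=list)
    movement_trials: list[RTTrialRow] = Field(default_factory=list)
    memory_trials: list[MemoryTrialRow] = Field(default_factory=list)
    outcomes: Optional[dict[str, Any]] = None
    scores: Optional[dict[str, Any]] = None


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _canonicalize(obj: Any) -> Any:
    if isinstance(obj, float):
        return _round_sig(obj)
    if isinstance(obj, dict):
        return {k: _canonicalize(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_canonicalize(v) for v in obj]
    return obj


def session_to_json(record: SessionRecord) -> str:
    """Canonical JSON text for a record (sorted keys, 6-significant-digit
    floats, trailing newline)."""
    payload = _canonicalize(record.model_dump(mode="json"))
    return json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n"


def write_session(record: SessionRecord, path: str | Path) -> Path:
    """Validate and write a session record as canonical JSON."""
    if not isinstance(record, SessionRecord):
        try:
            record = SessionRecord.model_validate(record)
        except ValidationError as exc:
            raise SchemaValidationError(
                f"invalid session record: {exc}",
                fields=[".".join(str(p) for p in e["loc"]) for e in exc.errors()],
            ) from exc
    path = Path(path)
    path.write_text(session_to_json(record))
    return path


def read_session(path: str | Path) -> SessionRecord:
    """Read and validate a session record from disk."""
    path = Path(path)
    text = path.read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SessionParseError(
            f"{path}: not valid JSON at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}"
        ) from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise SchemaValidationError(f"{path}: missing schema_version")
    version = payload["schema_version"]
    if version not in SUPPORTED_VERSIONS:
        raise UnsupportedVersionError(
            f"{path}: schema_version {version!r} not supported "
            f"(supported: {sorted(SUPPORTED_VERSIONS)})"
        )
    try:
        return SessionRecord.model_validate(payload)
    except ValidationError as exc:
        raise SchemaValidationError(
            f"{path}: schema validation failed: {exc}",
            fields=[".".join(str(p) for p in e["loc"]) for e in exc.errors()],
        ) from exc


def trials_to_frame(record: SessionRecord) -> pd.DataFrame:
    """Flat one-row-per-trial table of all four task blocks."""
    rows: list[dict[str, Any]] = []
    for tr in record.visual_trials:
        rows.append(
            dict(
                session_id=record.session_id,
                task="visual_recognition",
                subtask=tr.subtask,
                trial_number=tr.trial_number,
                ladder_index=tr.ladder_index,
                duration_ms=tr.duration_ms,
                correct=tr.correct,
            )
        )
    for block in (record.attention_trials, record.movement_trials):
        for tr in block:
            rows.append(
                dict(
                    session_id=record.session_id,
                    task=tr.task,
                    condition=tr.condition,
                    trial_number=tr.trial_number,
                    rt_ms=tr.rt_ms,
                    correct=tr.correct,
                )
            )
    for tr in record.memory_trials:
        rows.append(
            dict(
                session_id=record.session_id,
                task="memory",
                trial_number=tr.trial_number,
                n_crosses=tr.n_crosses,
                err_first_mm=tr.err_first_mm,
                err_last_mm=tr.err_last_mm,
            )
        )
    return pd.DataFrame(rows)


def mm_from_arcmin(arcmin: float, viewing_distance_mm: float) -> float:
    """On-screen extent (mm) subtending ``arcmin`` minutes of visual angle
    at the given viewing distance: distance x tan(angle)."""
    return viewing_distance_mm * math.tan(math.radians(arcmin / 60.0))
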