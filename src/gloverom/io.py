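"""File formats: glove streams (CSV / JSON-lines), cohort CSV, manifests.

Glove-stream CSV: one row per sensor per frame with header
``timestamp,sensor_id,qw,qx,qy,qz`` and an optional ``is_reset`` column
(0/1) flagging the reset frame. JSON-lines: one frame object per line,
``{"timestamp": t, "is_reset": bool, "orientations": {"MAIN": [w,x,y,z],
...}}``. Both encodings parse to identical frame sequences.

Angles round-trip at 1e-6°, quaternions at 1e-9.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import ALL_SENSORS, GloveFrame, SensorId, StreamError
from .quaternions import normalize_quaternion

__all__ = [
    "write_glove_stream_csv",
    "write_glove_stream_jsonl",
    "read_glove_stream",
    "CohortSchema",
    "read_cohort",
    "write_cohort",
    "RunManifest",
]

_QUAT_FMT = "{:.12g}"


def write_glove_stream_csv(
    path, frames, reset_frame: GloveFrame | None = None
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "sensor_id", "qw", "qx", "qy", "qz", "is_reset"])
        def emit(frame: GloveFrame, is_reset: int):
            for s in ALL_SENSORS:
                q = frame.orientations[s]
                w.writerow(
                    [repr(float(frame.timestamp)), s.value]
                    + [_QUAT_FMT.format(float(v)) for v in q]
                    + [is_reset]
                )
        if reset_frame is not None:
            emit(reset_frame, 1)
        for f in frames:
            emit(f, 0)


def write_glove_stream_jsonl(
    path, frames, reset_frame: GloveFrame | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        def emit(frame: GloveFrame, is_reset: bool):
            obj = {
                "timestamp": float(frame.timestamp),
                "is_reset": is_reset,
                "orientations": {
                    s.value: [float(v) for v in frame.orientations[s]]
                    for s in ALL_SENSORS
                },
            }
            fh.write(json.dumps(obj) + "\n")
        if reset_frame is not None:
            emit(reset_frame, True)
        for f in frames:
            emit(f, False)


def _build_frame(timestamp, quats: dict, where: str) -> GloveFrame:
    missing = [s.value for s in ALL_SENSORS if s not in quats]
    if missing:
        raise StreamError(f"{where}: missing sensor(s) {', '.join(missing)}")
    return GloveFrame(
        timestamp,
        {
            s: normalize_quaternion(q, context=f"{where} sensor={s.value}")
            for s, q in quats.items()
        },
    )


def read_glove_stream(
    path, fmt: str | None = None
) -> tuple[GloveFrame | None, list[GloveFrame]]:
    """Read a glove stream; returns (reset frame or None, frames).

    The format is inferred from the suffix unless given. All frames are
    validated: 11 sensors each, unit quaternions after normalization;
    malformed rows raise errors naming the line.
    """
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix in (".jsonl", ".ndjson", ".json") else "csv"
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "jsonl":
        return _read_jsonl(path)
    raise ValueError(f"unknown glove stream format: {fmt}")


def _read_csv(path: Path):
    groups: dict[tuple[float, int], dict] = {}
    order: list[tuple[float, int]] = []
    with path.open() as fh:
        reader = csv.DictReader(fh)
        required = {"timestamp", "sensor_id", "qw", "qx", "qy", "qz"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise StreamError(f"{path}: header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                t = float(row["timestamp"])
                sensor = SensorId(row["sensor_id"])
                q = [float(row[c]) for c in ("qw", "qx", "qy", "qz")]
                is_reset = int(row.get("is_reset") or 0)
            except (ValueError, KeyError) as exc:
                raise StreamError(f"{path}:{lineno}: malformed row ({exc})") from exc
            key = (t, is_reset)
            if key not in groups:
                groups[key] = {}
                order.append(key)
            groups[key][sensor] = q
    reset = None
    frames = []
    for (t, is_reset) in order:
        frame = _build_frame(t, groups[(t, is_reset)], f"{path} t={t}")
        if is_reset:
            reset = frame
        else:
            frames.append(frame)
    return reset, frames


def _read_jsonl(path: Path):
    reset = None
    frames = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                t = float(obj["timestamp"])
                quats = {SensorId(k): v for k, v in obj["orientations"].items()}
            except (ValueError, KeyError) as exc:
                raise StreamError(f"{path}:{lineno}: malformed frame ({exc})") from exc
            frame = _build_frame(t, quats, f"{path}:{lineno}")
            if obj.get("is_reset"):
                reset = frame
            else:
                frames.append(frame)
    return reset, frames


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnSpec:
    dtype: str                      # "id" | "category" | "float" | "int"
    lo: float | None = None
    hi: float | None = None
    required: bool = True
    allowed: tuple | None = None


class CohortSchema:
    """Column names, types, units and allowed ranges for the cohort CSV."""

    columns: dict[str, ColumnSpec] = {
        "subject_id": ColumnSpec("id"),
        "timepoint": ColumnSpec("category", allowed=("T0", "T1", "T2", "T3", "T4")),
        "group": ColumnSpec("category", allowed=("impaired", "control")),
        "age_years": ColumnSpec("int", 18, 120, required=False),
        "sex": ColumnSpec("category", allowed=("m", "f"), required=False),
        "rom_finger_spread_deg": ColumnSpec("float", 0, 90, required=False),
        "rom_thumb_opposition_deg": ColumnSpec("float", 0, 180, required=False),
        "rom_fist_opening_deg": ColumnSpec("float", 0, 360, required=False),
        "vigorimeter_kpa": ColumnSpec("float", 0, 200, required=False),
        "mrc_arm": ColumnSpec("int", 0, 20, required=False),
        "incat_arm": ColumnSpec("int", 0, 5, required=False),
        "rods_logits": ColumnSpec("float", -10, 10, required=False),
        "ncv_ms": ColumnSpec("float", 0, 100, required=False),
        "csa_mm2": ColumnSpec("float", 0, 50, required=False),
    }


class CohortValidationError(ValueError):
    pass


def read_cohort(path, schema: type[CohortSchema] = CohortSchema) -> pd.DataFrame:
    """Read and validate a cohort CSV; missing cells stay missing (NaN)."""
    df = pd.read_csv(path)
    known = schema.columns
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        import warnings
        warnings.warn(f"{path}: ignoring unknown column(s) {unknown}", stacklevel=2)
    required = [c for c, s in known.items() if s.required]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required column(s) {missing}")
    for col, spec in known.items():
        if col not in df.columns:
            continue
        v = df[col]
        if spec.allowed is not None:
            bad = v.dropna()[~v.dropna().isin(spec.allowed)]
            if len(bad):
                raise CohortValidationError(
                    f"{path}: column {col} has out-of-vocabulary value "
                    f"{bad.iloc[0]!r} (row {bad.index[0] + 2})"
                )
        if spec.dtype in ("float", "int"):
            v = pd.to_numeric(v, errors="coerce")
            out_of_range = v.dropna()
            if spec.lo is not None:
                bad = out_of_range[out_of_range < spec.lo]
                if len(bad):
                    raise CohortValidationError(
                        f"{path}: {col}={bad.iloc[0]} below {spec.lo} "
                        f"(row {bad.index[0] + 2})"
                    )
            if spec.hi is not None:
                bad = out_of_range[out_of_range > spec.hi]
                if len(bad):
                    raise CohortValidationError(
                        f"{path}: {col}={bad.iloc[0]} above {spec.hi} "
                        f"(row {bad.index[0] + 2})"
                    )
            df[col] = v
    dupes = df.duplicated(subset=["subject_id", "timepoint"])
    if dupes.any():
        raise CohortValidationError(
            f"{path}: duplicated subject × timepoint row "
            f"(row {int(np.nonzero(dupes.to_numpy())[0][0]) + 2})"
        )
    return df


def write_cohort(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record: config hash, seeds and input digests.

    Re-running with an identical manifest reproduces identical outputs for
    all deterministic stages.
    """

    tool_version: str
    config: dict
    seeds: dict
    input_digests: dict

    @classmethod
    def create(cls, config: dict, seeds: dict, inputs: dict) -> "RunManifest":
        from . import __version__
        return cls(
            tool_version=__version__,
            config=config,
            seeds=dict(seeds),
            input_digests={k: _sha256(v) for k, v in inputs.items()},
        )

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {
                "tool_version": self.tool_version,
                "config_hash": self.config_hash,
                "config": self.config,
                "seeds": self.seeds,
                "input_digests": self.input_digests,
            },
            indent=2,
        ))
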