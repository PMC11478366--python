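"""Track serialization: JSON-lines and long-format CSV.

JSONL layout: one metadata header object on the first line, then one object
per frame.  Floats are written with Python's shortest round-tripping repr, so
a fixed track always serializes to identical bytes and ``read(write(t)) == t``
holds exactly.

CSV layout is long format with one row per entity::

    frame,kind,id,x,y,z,label

``kind`` is ``frame`` (one marker row per frame, carrying the label), ``point``
or ``spot``.  Track metadata is stored in ``#``-prefixed JSON header lines.

Timestamps are not stored; they are derived as ``frame_index / frame_rate``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .core import GroundTruth, ParameterError, PointCloudFrame, SchemaError, SubjectTrack

__all__ = ["read_track", "write_track"]

_SCHEMA = "pointfall-track-v1"


def _truth_to_json(truth: Optional[GroundTruth]) -> Optional[dict]:
    if truth is None:
        return None
    return {
        "body_center": truth.body_center.tolist(),
        "posture": truth.posture.tolist(),
        "fall_frame": truth.fall_frame,
        "sit_intervals": [list(iv) for iv in truth.sit_intervals],
    }


def _truth_from_json(obj: Optional[dict]) -> Optional[GroundTruth]:
    if obj is None:
        return None
    return GroundTruth(
        body_center=np.asarray(obj["body_center"], dtype=float),
        posture=np.asarray(obj["posture"], dtype=int),
        fall_frame=obj.get("fall_frame"),
        sit_intervals=[tuple(iv) for iv in obj.get("sit_intervals", [])],
    )


def _header(track: SubjectTrack) -> dict:
    return {
        "schema": _SCHEMA,
        "subject_id": track.subject_id,
        "scenario": track.scenario,
        "room": list(track.room),
        "sensor_pose": list(track.sensor_pose),
        "frame_rate": track.frame_rate,
        "n_frames": len(track.frames),
        "truth": _truth_to_json(track.truth),
    }


def _dump(obj: dict) -> str:
    # sort_keys + no spaces => stable byte output for a fixed track
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in ("jsonl", "csv"):
            raise ParameterError(f"format must be 'jsonl' or 'csv', got {format!r}")
        return format
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def write_track(track: SubjectTrack, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Serialize *track* to *path*; byte output is deterministic per track."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        _write_jsonl(track, path)
    else:
        _write_csv(track, path)


def _write_jsonl(track: SubjectTrack, path: Path) -> None:
    lines = [_dump(_header(track))]
    for frame, label in zip(track.frames, track.labels):
        lines.append(
            _dump(
                {
                    "frame": frame.frame_index,
                    "label": int(label),
                    "points": frame.points.tolist(),
                    "spots": [[sid, *xyz.tolist()] for sid, xyz in frame.spots],
                }
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_csv(track: SubjectTrack, path: Path) -> None:
    out = ["# " + _dump(_header(track)), "frame,kind,id,x,y,z,label"]
    for frame, label in zip(track.frames, track.labels):
        i = frame.frame_index
        out.append(f"{i},frame,-1,,,,{int(label)}")
        for j, (x, y, z) in enumerate(frame.points):
            out.append(f"{i},point,{j},{float(x)!r},{float(y)!r},{float(z)!r},")
        for sid, xyz in frame.spots:
            out.append(
                f"{i},spot,{sid},{float(xyz[0])!r},{float(xyz[1])!r},{float(xyz[2])!r},"
            )
    path.write_text("\n".join(out) + "\n")


def read_track(path: Union[str, Path], format: Optional[str] = None) -> SubjectTrack:
    """Parse and validate a track file written by :func:`write_track`.

    Raises :class:`SchemaError` naming the offending line for malformed
    records; timestamp monotonicity and label/frame agreement are re-checked
    at construction.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        return _read_jsonl(path)
    return _read_csv(path)


def _build(header: dict, frames: list[PointCloudFrame], labels: list[int]) -> SubjectTrack:
    return SubjectTrack(
        subject_id=header["subject_id"],
        scenario=header["scenario"],
        frames=frames,
        labels=labels,
        room=tuple(header["room"]),
        sensor_pose=tuple(header["sensor_pose"]),
        frame_rate=header["frame_rate"],
        truth=_truth_from_json(header.get("truth")),
    )


def _read_jsonl(path: Path) -> SubjectTrack:
    text = path.read_text().splitlines()
    if not text:
        raise SchemaError(f"{path}: empty file")
    try:
        header = json.loads(text[0])
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}:1: malformed header: {exc}") from exc
    if header.get("schema") != _SCHEMA:
        raise SchemaError(f"{path}:1: unknown schema {header.get('schema')!r}")
    rate = float(header["frame_rate"])
    frames: list[PointCloudFrame] = []
    labels: list[int] = []
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}:{lineno}: malformed frame record: {exc}") from exc
        try:
            idx = rec["frame"]
            frames.append(
                PointCloudFrame(
                    frame_index=idx,
                    timestamp=idx / rate,
                    points=rec["points"],
                    spots=[(s[0], s[1:4]) for s in rec.get("spots", [])],
                )
            )
            labels.append(rec["label"])
        except (KeyError, TypeError, IndexError) as exc:
            raise SchemaError(f"{path}:{lineno}: bad frame record: {exc}") from exc
    return _build(header, frames, labels)


def _read_csv(path: Path) -> SubjectTrack:
    header = None
    frames_raw: dict[int, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                try:
                    header = json.loads(line.lstrip("# "))
                except json.JSONDecodeError as exc:
                    raise SchemaError(f"{path}:{lineno}: malformed metadata: {exc}") from exc
                continue
            if line.startswith("frame,"):
                continue  # column header
            parts = line.split(",")
            if len(parts) != 7:
                raise SchemaError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
            try:
                idx, kind = int(parts[0]), parts[1]
                rec = frames_raw.setdefault(idx, {"points": [], "spots": [], "label": None})
                if kind == "frame":
                    rec["label"] = int(parts[6])
                elif kind == "point":
                    rec["points"].append([float(parts[3]), float(parts[4]), float(parts[5])])
                elif kind == "spot":
                    rec["spots"].append(
                        (int(parts[2]), [float(parts[3]), float(parts[4]), float(parts[5])])
                    )
                else:
                    raise SchemaError(f"{path}:{lineno}: unknown record kind {kind!r}")
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: malformed record: {exc}") from exc
    if header is None:
        raise SchemaError(f"{path}: missing metadata header line")
    rate = float(header["frame_rate"])
    frames, labels = [], []
    for idx in sorted(frames_raw):
        rec = frames_raw[idx]
        if rec["label"] is None:
            raise SchemaError(f"{path}: frame {idx} has no frame marker row")
        frames.append(
            PointCloudFrame(idx, idx / rate, rec["points"], rec["spots"])
        )
        labels.append(rec["label"])
    return _build(header, frames, labels)
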