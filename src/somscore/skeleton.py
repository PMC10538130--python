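"""Skeleton-sequence containers and file I/O.

A posture sequence is an ordered list of skeleton frames, each frame a flat
vector of ``3 x n_joints`` camera coordinates (19 joints, 57 values, by
default), sampled at a nominal 15 frames per second.  Two plain-text formats
are supported:

``csv_wide``
    header ``frame,j00_x,j00_y,j00_z,...``; one row per frame.
``jsonl``
    one JSON object per line: ``{"frame": k, "joints": [[x,y,z], ...]}``.

Both round-trip floats exactly (shortest-repr serialization).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

FORMATS = ("csv_wide", "jsonl")

DEFAULT_JOINTS = [
    "pelvis", "spine", "chest", "neck", "head",
    "l_shoulder", "r_shoulder", "l_elbow", "r_elbow",
    "l_wrist", "r_wrist", "l_hand", "r_hand",
    "l_hip", "r_hip", "l_knee", "r_knee", "l_ankle", "r_ankle",
]


class ParseError(ValueError):
    """Malformed skeleton file; the message names the offending line."""


@dataclass
class PostureSequence:
    """Ordered skeleton frames with optional ground-truth segment labels.

    ``frames`` is a (T, D) float array, D = 3 x n_joints.  ``segment_labels``
    (if present) gives the ground-truth posture id per frame — available for
    synthetic data, absent for real recordings.
    """

    frames: np.ndarray
    fps: float = 15.0
    joint_names: list[str] | None = None
    segment_labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.frames.size and self.frames.shape[1] % 3 != 0:
            raise ValueError(
                f"frame dimension {self.frames.shape[1]} is not a multiple of 3"
            )
        if self.joint_names is not None and self.frames.size:
            if 3 * len(self.joint_names) != self.frames.shape[1]:
                raise ValueError("joint_names length inconsistent with frame dimension")
        if self.segment_labels is not None:
            self.segment_labels = np.asarray(self.segment_labels)
            if self.segment_labels.shape[0] != self.n_frames:
                raise ValueError("segment_labels must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0]) if self.frames.size else 0

    @property
    def n_dims(self) -> int:
        return int(self.frames.shape[1])

    @property
    def n_joints(self) -> int:
        return self.n_dims // 3

    def as_joints(self) -> np.ndarray:
        """View frames as a (T, n_joints, 3) array."""
        return self.frames.reshape(self.n_frames, self.n_joints, 3)


def _joint_columns(n_joints: int) -> list[str]:
    return [
        f"j{j:02d}_{axis}" for j in range(n_joints) for axis in ("x", "y", "z")
    ]


def write_sequence(seq: PostureSequence, path, format: str = "csv_wide") -> None:
    """Write a sequence to ``path``; floats serialize via repr (lossless)."""
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {format!r}")
    if format == "csv_wide":
        n_joints = seq.n_joints if seq.n_frames else (
            len(seq.joint_names) if seq.joint_names else 19
        )
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame"] + _joint_columns(n_joints))
            for k in range(seq.n_frames):
                writer.writerow([k] + [repr(float(v)) for v in seq.frames[k]])
    else:
        with open(path, "w", encoding="utf-8") as fh:
            for k in range(seq.n_frames):
                joints = seq.frames[k].reshape(-1, 3).tolist()
                fh.write(json.dumps({"frame": k, "joints": joints}) + "\n")


def read_sequence(
    path, format: str = "csv_wide", fps: float = 15.0,
    joint_names: list[str] | None = None,
) -> PostureSequence:
    """Read a sequence written by :func:`write_sequence`.

    The joint count is inferred from the file; ragged or non-numeric rows
    raise :class:`ParseError` naming the 1-based line number.
    """
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {format!r}")
    rows: list[list[float]] = []
    if format == "csv_wide":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise ParseError(f"{path}: empty file (missing header)") from None
            if not header or header[0] != "frame":
                raise ParseError(f"{path}: line 1: expected 'frame,...' header")
            width = len(header) - 1
            if width % 3 != 0:
                raise ParseError(
                    f"{path}: line 1: {width} coordinate columns, not a multiple of 3"
                )
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) - 1 != width:
                    raise ParseError(
                        f"{path}: line {lineno}: expected {width} values, got {len(row) - 1}"
                    )
                try:
                    rows.append([float(v) for v in row[1:]])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from None
    else:
        width = None
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                    joints = np.asarray(obj["joints"], dtype=float)
                except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from None
                if joints.ndim != 2 or joints.shape[1] != 3:
                    raise ParseError(
                        f"{path}: line {lineno}: joints must be an (n, 3) list"
                    )
                flat = joints.ravel()
                if width is None:
                    width = flat.size
                elif flat.size != width:
                    raise ParseError(
                        f"{path}: line {lineno}: expected {width} values, got {flat.size}"
                    )
                rows.append(flat.tolist())
    frames = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, width if format == "csv_wide" else 0))
    )
    if rows and not np.all(np.isfinite(frames)):
        bad = int(np.flatnonzero(~np.isfinite(frames).all(axis=1))[0])
        raise ParseError(f"{path}: frame {bad}: non-finite coordinate (NaN/inf)")
    return PostureSequence(frames=frames, fps=fps, joint_names=joint_names)


def write_labels(seq: PostureSequence, path, archetype_names=None) -> None:
    """Write a ``frame,segment_id,archetype_name`` CSV of ground-truth labels."""
    if seq.segment_labels is None:
        raise ValueError("sequence carries no segment labels")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "segment_id", "archetype_name"])
        for k, lab in enumerate(seq.segment_labels):
            name = archetype_names[int(lab)] if archetype_names is not None else ""
            writer.writerow([k, int(lab), name])


def preprocess(seq: PostureSequence, mode: str = "none", root_joint: int = 0) -> np.ndarray:
    """Turn a sequence into an (N, D) data matrix of feature vectors.

    ``mode="none"`` flattens frames unchanged — the default, so every score
    acts on raw camera coordinates.  ``mode="center_root"`` subtracts the
    root joint's (x, y, z) from every joint per frame, removing global
    translation (opt-in).
    """
    if mode not in ("none", "center_root"):
        raise ValueError(f"unknown preprocessing mode {mode!r}")
    if np.any(~np.isfinite(seq.frames)):
        raise ValueError("sequence contains NaN/inf coordinates; not imputed")
    if mode == "none":
        return seq.frames.copy()
    if not 0 <= root_joint < seq.n_joints:
        raise ValueError(
            f"root joint {root_joint} out of range [0, {seq.n_joints})"
        )
    joints = seq.as_joints().copy()
    joints -= joints[:, root_joint : root_joint + 1, :]
    return joints.reshape(seq.n_frames, seq.n_dims)
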