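"""Synthetic skeleton data with known ground truth.

Real posture recordings are rarely shareable, so every stage of the toolbox
is exercised against generated data instead: a small library of canonical
19-joint poses (upright walking, leaning picking/placing, extended-hands
walking, squatting), scripted into activities as dwell segments joined by
linearly interpolated transitions, with i.i.d. Gaussian keypoint jitter and
a sinusoidal gait oscillation on the limb joints.  Coordinates are meters in
a camera-like frame (x forward, y lateral, z up); the poses differ the way
the real postures do — leaning postures move chiefly the trunk joints,
extended-hands postures chiefly the wrist/hand joints — so cosine- and
Euclidean-driven groupings can diverge qualitatively.

A separate isotropic-Gaussian-blob generator provides fully controlled
cluster-recovery studies in the native 57-dimensional feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .skeleton import DEFAULT_JOINTS, PostureSequence

TRUNK_JOINTS = ("pelvis", "spine", "chest", "neck", "head")
LIMB_JOINTS = ("l_wrist", "r_wrist", "l_hand", "r_hand", "l_ankle", "r_ankle")


@dataclass
class ArchetypeLibrary:
    """Named canonical poses, each a (19, 3) joint array sharing joint order."""

    poses: dict[str, np.ndarray]
    joint_names: list[str] = field(default_factory=lambda: list(DEFAULT_JOINTS))

    def __post_init__(self) -> None:
        for name, pose in self.poses.items():
            pose = np.asarray(pose, dtype=float)
            if pose.shape != (len(self.joint_names), 3):
                raise ValueError(
                    f"pose {name!r} has shape {pose.shape}, "
                    f"expected ({len(self.joint_names)}, 3)"
                )
            self.poses[name] = pose

    @property
    def names(self) -> list[str]:
        return list(self.poses)

    def vector(self, name: str) -> np.ndarray:
        """Flattened 57-dim feature vector of a pose."""
        return self.poses[name].ravel().copy()

    def joint_index(self, joint: str) -> int:
        return self.joint_names.index(joint)


@dataclass
class ActivityScript:
    """Recipe for one synthetic activity recording.

    ``dwell`` is frames per posture segment (int, or one int per segment);
    ``transition`` frames of linear interpolation are inserted between
    consecutive segments.  Noise is i.i.d. Gaussian per coordinate (meters);
    the gait oscillation adds an antiphase fore-aft sinusoid to the limb
    joints with the given amplitude (m) and period (frames).
    """

    archetypes: list[str]
    dwell: int | list[int] = 100
    transition: int = 10
    noise_sd: float = 0.01
    gait_amplitude: float = 0.05
    gait_period: float = 15.0
    fps: float = 15.0
    seed: int = 0

    def dwell_list(self) -> list[int]:
        if isinstance(self.dwell, int):
            return [self.dwell] * len(self.archetypes)
        if len(self.dwell) != len(self.archetypes):
            raise ValueError("one dwell per segment required")
        return list(self.dwell)

    def validate(self) -> None:
        if not self.archetypes:
            raise ValueError("empty activity script")
        if any(d <= 0 for d in self.dwell_list()):
            raise ValueError("dwell must be positive")
        if self.transition < 0:
            raise ValueError("transition must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def n_frames(self) -> int:
        d = self.dwell_list()
        return sum(d) + self.transition * (len(d) - 1)


def default_archetypes() -> ArchetypeLibrary:
    """Five canonical poses of a ~1.75 m figure, in meters.

    ``upright_walk`` is the reference stance.  ``lean_pick`` pitches the
    whole trunk deep forward with hands near the floor; ``lean_place`` is a
    moderate lean with hands at table height; ``extended_hands_walk`` keeps
    the trunk upright and extends the arms horizontally; ``squat`` lowers
    the pelvis on bent knees.  Trunk displacement therefore dominates the
    upright-vs-leaning contrasts, hand displacement the extended-hands one.
    """
    j = {name: i for i, name in enumerate(DEFAULT_JOINTS)}

    def pose(**overrides) -> np.ndarray:
        base = {
            "pelvis": (0.00, 0.00, 0.95),
            "spine": (0.00, 0.00, 1.15),
            "chest": (0.00, 0.00, 1.35),
            "neck": (0.00, 0.00, 1.50),
            "head": (0.00, 0.00, 1.65),
            "l_shoulder": (0.00, 0.20, 1.45),
            "r_shoulder": (0.00, -0.20, 1.45),
            "l_elbow": (0.00, 0.25, 1.15),
            "r_elbow": (0.00, -0.25, 1.15),
            "l_wrist": (0.00, 0.25, 0.90),
            "r_wrist": (0.00, -0.25, 0.90),
            "l_hand": (0.00, 0.25, 0.80),
            "r_hand": (0.00, -0.25, 0.80),
            "l_hip": (0.00, 0.10, 0.90),
            "r_hip": (0.00, -0.10, 0.90),
            "l_knee": (0.00, 0.10, 0.50),
            "r_knee": (0.00, -0.10, 0.50),
            "l_ankle": (0.00, 0.10, 0.10),
            "r_ankle": (0.00, -0.10, 0.10),
        }
        base.update(overrides)
        arr = np.zeros((len(DEFAULT_JOINTS), 3))
        for name, xyz in base.items():
            arr[j[name]] = xyz
        return arr

    upright_walk = pose()
    # deep forward trunk pitch (~70 deg), hands reaching the floor
    lean_pick = pose(
        spine=(0.18, 0.00, 1.08), chest=(0.36, 0.00, 1.18),
        neck=(0.50, 0.00, 1.22), head=(0.63, 0.00, 1.25),
        l_shoulder=(0.46, 0.20, 1.18), r_shoulder=(0.46, -0.20, 1.18),
        l_elbow=(0.55, 0.22, 0.85), r_elbow=(0.55, -0.22, 0.85),
        l_wrist=(0.60, 0.22, 0.50), r_wrist=(0.60, -0.22, 0.50),
        l_hand=(0.62, 0.22, 0.35), r_hand=(0.62, -0.22, 0.35),
        l_knee=(0.08, 0.10, 0.48), r_knee=(0.08, -0.10, 0.48),
    )
    # moderate lean (~30 deg), hands forward at table height
    lean_place = pose(
        spine=(0.09, 0.00, 1.13), chest=(0.19, 0.00, 1.29),
        neck=(0.26, 0.00, 1.40), head=(0.33, 0.00, 1.51),
        l_shoulder=(0.24, 0.20, 1.36), r_shoulder=(0.24, -0.20, 1.36),
        l_elbow=(0.42, 0.23, 1.15), r_elbow=(0.42, -0.23, 1.15),
        l_wrist=(0.58, 0.23, 1.00), r_wrist=(0.58, -0.23, 1.00),
        l_hand=(0.65, 0.23, 0.95), r_hand=(0.65, -0.23, 0.95),
    )
    # trunk as upright_walk; arms horizontal forward
    extended_hands_walk = pose(
        l_elbow=(0.28, 0.22, 1.45), r_elbow=(0.28, -0.22, 1.45),
        l_wrist=(0.55, 0.22, 1.45), r_wrist=(0.55, -0.22, 1.45),
        l_hand=(0.67, 0.22, 1.45), r_hand=(0.67, -0.22, 1.45),
    )
    # pelvis dropped on deeply bent knees, slight trunk lean
    squat = pose(
        pelvis=(-0.10, 0.00, 0.45), spine=(-0.04, 0.00, 0.66),
        chest=(0.04, 0.00, 0.86), neck=(0.10, 0.00, 1.00),
        head=(0.16, 0.00, 1.14),
        l_shoulder=(0.08, 0.20, 0.96), r_shoulder=(0.08, -0.20, 0.96),
        l_elbow=(0.20, 0.23, 0.72), r_elbow=(0.20, -0.23, 0.72),
        l_wrist=(0.30, 0.23, 0.52), r_wrist=(0.30, -0.23, 0.52),
        l_hand=(0.34, 0.23, 0.44), r_hand=(0.34, -0.23, 0.44),
        l_hip=(-0.08, 0.10, 0.45), r_hip=(-0.08, -0.10, 0.45),
        l_knee=(0.22, 0.12, 0.40), r_knee=(0.22, -0.12, 0.40),
        l_ankle=(0.02, 0.10, 0.10), r_ankle=(0.02, -0.10, 0.10),
    )
    return ArchetypeLibrary(poses={
        "upright_walk": upright_walk,
        "lean_pick": lean_pick,
        "lean_place": lean_place,
        "extended_hands_walk": extended_hands_walk,
        "squat": squat,
    })


def make_activity_sequence(
    script: ActivityScript, library: ArchetypeLibrary | None = None
) -> PostureSequence:
    """Render a script into a labeled skeleton sequence.

    Each segment holds its archetype for ``dwell`` frames; between segments,
    ``transition`` frames interpolate linearly from the outgoing to the
    incoming pose.  The ground-truth label switches to the incoming
    archetype at the interpolation midpoint.  Labels index into
    ``library.names`` order.
    """
    library = library or default_archetypes()
    script.validate()
    for name in script.archetypes:
        if name not in library.poses:
            raise KeyError(f"unknown archetype {name!r}")
    rng = np.random.default_rng(script.seed)
    name_to_id = {n: i for i, n in enumerate(library.names)}
    dwells = script.dwell_list()
    t_len = script.transition

    clean: list[np.ndarray] = []
    labels: list[int] = []
    for i, name in enumerate(script.archetypes):
        pose = library.vector(name)
        for _ in range(dwells[i]):
            clean.append(pose)
            labels.append(name_to_id[name])
        if i + 1 < len(script.archetypes) and t_len > 0:
            nxt = library.vector(script.archetypes[i + 1])
            nxt_id = name_to_id[script.archetypes[i + 1]]
            for s in range(t_len):
                lam = (s + 1) / (t_len + 1)
                clean.append((1 - lam) * pose + lam * nxt)
                labels.append(name_to_id[name] if s < t_len // 2 else nxt_id)
    frames = np.asarray(clean)
    T = frames.shape[0]
    assert T == script.n_frames()

    if script.gait_amplitude > 0:
        phase = 2 * np.pi * np.arange(T) / script.gait_period
        wave = script.gait_amplitude * np.sin(phase)
        joints = frames.reshape(T, -1, 3).copy()
        for i, joint in enumerate(LIMB_JOINTS):
            sign = 1.0 if joint.startswith("l_") else -1.0
            joints[:, library.joint_index(joint), 0] += sign * wave
        frames = joints.reshape(T, -1)
    if script.noise_sd > 0:
        frames = frames + rng.normal(0.0, script.noise_sd, size=frames.shape)

    return PostureSequence(
        frames=frames,
        fps=script.fps,
        joint_names=list(library.joint_names),
        segment_labels=np.asarray(labels, dtype=int),
    )


def true_boundaries(labels) -> np.ndarray:
    """Frame indices where the ground-truth segment label changes."""
    lab = np.asarray(labels)
    return np.flatnonzero(np.diff(lab) != 0) + 1


def make_gaussian_postures(
    k: int, D: int = 57, separation: float = 10.0,
    n_per_cluster: int = 100, seed: int = 0, sd: float = 1.0,
    offset: float | None = None,
):
    """k isotropic Gaussian clusters in D dimensions with known labels.

    Centroids sit at mutual Euclidean distance exactly ``separation * sd``:
    scaled orthogonal axes rotated by a random orthogonal matrix, then
    shifted by a positive offset so the cloud stays away from the origin
    (keeping cosine distances well defined).  Requires ``k <= D``.

    Returns ``(data, labels)`` with shapes (k*n_per_cluster, D) and
    (k*n_per_cluster,).
    """
    if k < 1 or D < 1 or n_per_cluster < 1:
        raise ValueError("k, D, n_per_cluster must be >= 1")
    if k > D:
        raise ValueError(
            f"cannot place {k} equidistant centroids in {D} dimensions "
            f"at the requested spacing"
        )
    if separation < 0 or sd < 0:
        raise ValueError("separation and sd must be >= 0")
    rng = np.random.default_rng(seed)
    radius = separation * sd / np.sqrt(2.0)
    C = np.zeros((k, D))
    C[np.arange(k), np.arange(k)] = radius
    Q, _ = np.linalg.qr(rng.standard_normal((D, D)))
    C = C @ Q.T
    if offset is None:
        offset = 2.0 * separation * sd
    C += offset / np.sqrt(D)

    data = np.vstack([
        C[m] + rng.normal(0.0, sd, size=(n_per_cluster, D)) for m in range(k)
    ])
    labels = np.repeat(np.arange(k), n_per_cluster)
    return data, labels
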