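"""Data model and file I/O for Kinect-v2-style motion recordings.

The camera ("skeleton space") frame is right-handed: +Y vertical (up), +Z out
of the sensor toward the subject, +X completing the triad.  Joint positions
are in meters, timestamps in seconds.  Skeleton sequences are stored on disk
as long-format CSV (one row per frame/joint pair), infrared/depth frames as
16-bit PNG pairs, camera intrinsics as JSON.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: Canonical Kinect v2 joint order (25 joints).
KINECT_JOINTS = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)

JOINT_INDEX = {name: i for i, name in enumerate(KINECT_JOINTS)}

SKELETON_CSV_COLUMNS = ("frame", "time_s", "joint", "x_m", "y_m", "z_m", "state")


class TrackingState(enum.IntEnum):
    NOT_TRACKED = 0
    INFERRED = 1
    TRACKED = 2


class SkeletonError(ValueError):
    """Malformed or invalid skeleton data."""


@dataclass(frozen=True)
class Joint3D:
    """A single joint sample: position in meters, camera frame."""

    x: float
    y: float
    z: float
    tracking_state: TrackingState = TrackingState.TRACKED

    def __post_init__(self):
        if not all(map(math.isfinite, (self.x, self.y, self.z))):
            raise SkeletonError("joint coordinates must be finite")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class SkeletonFrame:
    """One time-stamped 25-joint skeleton pose."""

    timestamp: float
    joints: dict  # joint name -> Joint3D

    def __post_init__(self):
        missing = [n for n in KINECT_JOINTS if n not in self.joints]
        if missing:
            raise SkeletonError(f"frame at t={self.timestamp}: missing joints {missing}")
        if len(self.joints) != len(KINECT_JOINTS):
            extra = set(self.joints) - set(KINECT_JOINTS)
            raise SkeletonError(f"unknown joints {sorted(extra)}")


@dataclass
class SkeletonSequence:
    """An ordered sequence of skeleton frames backed by dense arrays.

    Attributes
    ----------
    timestamps : (n,) float seconds, strictly increasing
    positions : (n, 25, 3) float meters, joint axis ordered as KINECT_JOINTS
    states : (n, 25) int tracking states
    sample_rate : nominal acquisition rate in Hz
    subject_height, lower_limb_length : anthropometrics in meters, used for
        optional feature normalisation
    frame : which reference frame positions are expressed in
        ("camera" or "subject")
    """

    timestamps: np.ndarray
    positions: np.ndarray
    states: np.ndarray = None
    sample_rate: float = 30.0
    subject_height: float = 1.70
    lower_limb_length: float = 0.90
    frame: str = "camera"

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.states is None:
            self.states = np.full(self.positions.shape[:2], int(TrackingState.TRACKED),
                                  dtype=np.int8)
        self.states = np.asarray(self.states)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (25, 3):
            raise SkeletonError(f"positions must be (n, 25, 3), got {self.positions.shape}")
        if len(self.timestamps) != len(self.positions):
            raise SkeletonError("timestamps and positions length mismatch")
        if len(self.timestamps) < 2:
            raise SkeletonError("a skeleton sequence needs at least 2 frames")
        if np.any(np.diff(self.timestamps) <= 0):
            bad = int(np.argmax(np.diff(self.timestamps) <= 0)) + 1
            raise SkeletonError(f"timestamps not strictly increasing at frame {bad + 1}")
        if self.sample_rate <= 0:
            raise SkeletonError("sample_rate must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def joint(self, name: str) -> np.ndarray:
        """(n, 3) trajectory of one named joint."""
        return self.positions[:, JOINT_INDEX[name], :]

    def frame_at(self, i: int) -> SkeletonFrame:
        joints = {
            name: Joint3D(*self.positions[i, j], TrackingState(int(self.states[i, j])))
            for j, name in enumerate(KINECT_JOINTS)
        }
        return SkeletonFrame(timestamp=float(self.timestamps[i]), joints=joints)

    def __eq__(self, other):
        if not isinstance(other, SkeletonSequence):
            return NotImplemented
        return (
            np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.states, other.states)
            and self.sample_rate == other.sample_rate
            and self.subject_height == other.subject_height
            and self.lower_limb_length == other.lower_limb_length
        )


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics of the depth/IR camera."""

    fx: float
    fy: float
    cx: float
    cy: float
    depth_scale: float = 0.001  # meters per depth unit

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")


#: Kinect v2 depth-camera defaults (512x424 sensor).
KINECT_V2_INTRINSICS = CameraIntrinsics(fx=365.0, fy=365.0, cx=256.0, cy=212.0,
                                        depth_scale=0.001)


@dataclass
class FrameSequence:
    """Paired infrared + depth frames, pixel-aligned, with timestamps."""

    infrared: np.ndarray  # (n, H, W) uint16
    depth: np.ndarray     # (n, H, W) uint16 range in depth units
    timestamps: np.ndarray

    def __post_init__(self):
        self.infrared = np.asarray(self.infrared)
        self.depth = np.asarray(self.depth)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.infrared.shape != self.depth.shape:
            raise ValueError("infrared and depth stacks must have identical shape")
        if len(self.timestamps) != len(self.infrared):
            raise ValueError("timestamps length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)


class Group(str, enum.Enum):
    HEALTHY = "healthy"
    MILD = "mild"
    MODERATE = "moderate"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class Subject:
    id: str
    group_label: Group
    side: Side
    age: float = float("nan")


# ---------------------------------------------------------------------------
# skeleton CSV

def write_skeleton_csv(seq: SkeletonSequence, path) -> None:
    """Write a sequence to long-format CSV (one row per frame/joint).

    Floats are written with repr precision so that a read/write round trip is
    exact.
    """
    if seq.n_frames < 2:
        raise SkeletonError("refusing to write a sequence with fewer than 2 frames")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(SKELETON_CSV_COLUMNS) + "\n")
        for i in range(seq.n_frames):
            t = repr(float(seq.timestamps[i]))
            for j, name in enumerate(KINECT_JOINTS):
                x, y, z = (repr(float(v)) for v in seq.positions[i, j])
                fh.write(f"{i + 1},{t},{name},{x},{y},{z},{int(seq.states[i, j])}\n")


def read_skeleton_csv(path, sample_rate: float = 30.0,
                      subject_height: float = 1.70,
                      lower_limb_length: float = 0.90) -> SkeletonSequence:
    """Read a long-format skeleton CSV into a SkeletonSequence.

    Raises SkeletonError naming the offending line / frame on malformed rows,
    missing joints, or non-monotonic timestamps.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"joint": str}, float_precision="round_trip")
    missing_cols = [c for c in SKELETON_CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SkeletonError(f"{path}: missing columns {missing_cols}")
    for col in ("frame", "time_s", "x_m", "y_m", "z_m", "state"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(np.argmax(vals.isna().to_numpy())) + 2  # 1 header + 1-based
            raise SkeletonError(f"{path}: malformed value in column '{col}' at line {line}")
        df[col] = vals

    frame_ids = np.sort(df["frame"].unique())
    n = len(frame_ids)
    if n < 2:
        raise SkeletonError(f"{path}: fewer than 2 frames")
    positions = np.empty((n, 25, 3))
    states = np.empty((n, 25), dtype=np.int8)
    timestamps = np.empty(n)
    for i, fid in enumerate(frame_ids):
        rows = df[df["frame"] == fid]
        seen = set(rows["joint"])
        missing = [j for j in KINECT_JOINTS if j not in seen]
        if missing:
            raise SkeletonError(f"{path}: frame {int(fid)} missing joint(s) {missing}")
        unknown = seen - set(KINECT_JOINTS)
        if unknown:
            raise SkeletonError(f"{path}: frame {int(fid)} has unknown joint(s) {sorted(unknown)}")
        if len(rows) != 25:
            raise SkeletonError(f"{path}: frame {int(fid)} has duplicate joint rows")
        t = rows["time_s"].unique()
        if len(t) != 1:
            raise SkeletonError(f"{path}: frame {int(fid)} has inconsistent time_s")
        timestamps[i] = t[0]
        idx = rows["joint"].map(JOINT_INDEX).to_numpy()
        positions[i, idx] = rows[["x_m", "y_m", "z_m"]].to_numpy()
        states[i, idx] = rows["state"].to_numpy().astype(np.int8)
    if np.any(np.diff(timestamps) <= 0):
        bad = int(np.argmax(np.diff(timestamps) <= 0))
        raise SkeletonError(
            f"{path}: non-monotonic time between frames {int(frame_ids[bad])} "
            f"and {int(frame_ids[bad + 1])}")
    return SkeletonSequence(timestamps=timestamps, positions=positions, states=states,
                            sample_rate=sample_rate, subject_height=subject_height,
                            lower_limb_length=lower_limb_length)


# ---------------------------------------------------------------------------
# subject reference frame

class NoDisplacementError(ValueError):
    """The subject did not move enough to estimate a walking direction."""


def walking_direction(seq: SkeletonSequence, min_displacement: float = 0.5,
                      tpose_duration: float = 1.0) -> np.ndarray:
    """Unit horizontal walking direction from net SpineBase displacement.

    The start pose is averaged over the initial quasi-static interval (the
    T-pose calibration second); gravity is assumed along -Y of the camera.
    """
    spine = seq.joint("SpineBase")
    t0 = seq.timestamps[0]
    calib = seq.timestamps <= t0 + tpose_duration
    if not np.any(calib):
        calib = np.zeros(seq.n_frames, bool)
        calib[0] = True
    start = spine[calib].mean(axis=0)
    end = spine[-5:].mean(axis=0) if seq.n_frames >= 5 else spine[-1]
    disp = end - start
    disp[1] = 0.0  # horizontal component only
    norm = np.linalg.norm(disp)
    if norm < min_displacement:
        raise NoDisplacementError(
            f"net horizontal SpineBase displacement {norm:.2f} m < {min_displacement} m; "
            "cannot estimate walking direction")
    return disp / norm


def camera_to_subject_frame(seq: SkeletonSequence, min_displacement: float = 0.5,
                            tpose_duration: float = 1.0) -> SkeletonSequence:
    """Re-express a camera-frame sequence in the subject's reference frame.

    Subject frame axes: x = forward (walking direction), y = left,
    z = up (opposite gravity).  The transform is rigid: a rotation about the
    vertical plus a translation moving the calibration-pose SpineBase to the
    origin, so all inter-joint distances are preserved.
    """
    fwd = walking_direction(seq, min_displacement, tpose_duration)
    up = np.array([0.0, 1.0, 0.0])
    left = np.cross(up, fwd)
    left /= np.linalg.norm(left)
    rot = np.stack([fwd, left, up])  # rows: subject axes in camera coords
    spine = seq.joint("SpineBase")
    t0 = seq.timestamps[0]
    calib = seq.timestamps <= t0 + tpose_duration
    origin = spine[calib].mean(axis=0) if np.any(calib) else spine[0]
    new_pos = (seq.positions - origin) @ rot.T
    return replace(seq, positions=new_pos, states=seq.states.copy(), frame="subject")


# ---------------------------------------------------------------------------
# intrinsics JSON and PNG frame pairs

def write_intrinsics_json(intr: CameraIntrinsics, path) -> None:
    with open(path, "w") as fh:
        json.dump({"fx": intr.fx, "fy": intr.fy, "cx": intr.cx, "cy": intr.cy,
                   "depth_scale": intr.depth_scale}, fh, indent=2)


def read_intrinsics_json(path) -> CameraIntrinsics:
    with open(path) as fh:
        d = json.load(fh)
    return CameraIntrinsics(**d)


def write_frame_sequence(frames: FrameSequence, out_dir, prefix: str = "frame") -> None:
    """Write IR/depth pairs as 16-bit PNGs plus a timestamps CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i in range(frames.n_frames):
        iio.imwrite(out_dir / f"{prefix}_{i:04d}_ir.png",
                    frames.infrared[i].astype(np.uint16))
        iio.imwrite(out_dir / f"{prefix}_{i:04d}_depth.png",
                    frames.depth[i].astype(np.uint16))
    pd.DataFrame({"frame": np.arange(frames.n_frames),
                  "time_s": frames.timestamps}).to_csv(
        out_dir / f"{prefix}_timestamps.csv", index=False)


def read_frame_sequence(in_dir, prefix: str = "frame") -> FrameSequence:
    in_dir = Path(in_dir)
    ir_paths = sorted(in_dir.glob(f"{prefix}_*_ir.png"))
    if not ir_paths:
        raise FileNotFoundError(f"no {prefix}_*_ir.png frames in {in_dir}")
    ir = np.stack([iio.imread(p) for p in ir_paths])
    depth = np.stack([iio.imread(str(p).replace("_ir.png", "_depth.png"))
                      for p in ir_paths])
    ts_path = in_dir / f"{prefix}_timestamps.csv"
    if ts_path.exists():
        timestamps = pd.read_csv(ts_path)["time_s"].to_numpy()
    else:
        timestamps = np.arange(len(ir)) / 30.0
    return FrameSequence(infrared=ir, depth=depth, timestamps=timestamps)
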