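"""Synthetic motion generator: skeleton walks, tapping signals, marker frames
and labeled cohorts, with exact ground truth for every quantity the
extraction pipeline estimates.

The gait generator is feature-level: trajectories are constructed directly
from target spatio-temporal/postural values (stance fraction, stride time and
length, step timing and width, trunk/neck/lateral tilts, arm-swing amplitude),
so parameter recovery by the extractor is a well-posed test.  Group-specific
parameter distributions default to published cohort statistics for healthy,
mild-PD and moderate-PD gait.

Deterministic identities are respected rather than drawn: SWp = 100 - STp,
STt/SWt partition STDt, STDc = 60/STDt, STDv = STDl/STDt, SWv = STDl/SWt and,
structurally for any alternating biped, DSp = STp_left + STp_right - 100.
The remaining features are drawn independently from truncated normals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (KINECT_JOINTS, JOINT_INDEX, CameraIntrinsics, FrameSequence,
                 SkeletonSequence, KINECT_V2_INTRINSICS)
from .gait import GaitEvents, extract_gait_features, GAIT_FEATURES
from .tapping import TapSignal, extract_tap_features, TAP_FEATURES

# ---------------------------------------------------------------------------
# group gait statistics: feature -> group -> (mean, sd)
# units as reported: percentages, seconds, strides/min, cm, m/s, degrees

GAIT_GROUP_STATS = {
    "STp":  {"healthy": (60.1, 3.3), "pd": (62.0, 3.5), "mild": (61.6, 2.6), "moderate": (62.5, 4.4)},
    "SWp":  {"healthy": (39.8, 3.3), "pd": (38.0, 3.5), "mild": (38.4, 2.6), "moderate": (37.4, 4.4)},
    "DSp":  {"healthy": (18.6, 5.2), "pd": (22.9, 5.2), "mild": (21.8, 3.7), "moderate": (24.2, 6.6)},
    "STt":  {"healthy": (0.8, 0.1), "pd": (0.8, 0.1), "mild": (0.9, 0.1), "moderate": (0.8, 0.1)},
    "SWt":  {"healthy": (0.5, 0.1), "pd": (0.5, 0.1), "mild": (0.6, 0.1), "moderate": (0.5, 0.1)},
    "STDt": {"healthy": (1.3, 0.1), "pd": (1.4, 0.2), "mild": (1.5, 0.2), "moderate": (1.3, 0.2)},
    "STDc": {"healthy": (45.0, 5.2), "pd": (44.9, 8.3), "mild": (41.8, 5.1), "moderate": (48.9, 10.0)},
    "STDl": {"healthy": (71.3, 11.0), "pd": (56.9, 15.1), "mild": (57.3, 15.3), "moderate": (50.3, 19.8)},
    "SPl":  {"healthy": (35.8, 6.2), "pd": (28.4, 7.8), "mild": (28.6, 7.9), "moderate": (25.1, 10.0)},
    "SPw":  {"healthy": (8.8, 2.6), "pd": (9.7, 1.9), "mild": (9.6, 1.9), "moderate": (10.1, 2.0)},
    "STDv": {"healthy": (0.5, 0.1), "pd": (0.4, 0.1), "mild": (0.4, 0.1), "moderate": (0.4, 0.1)},
    "SWv":  {"healthy": (1.2, 0.3), "pd": (1.0, 0.2), "mild": (1.0, 0.2), "moderate": (0.9, 0.3)},
    "TFlex": {"healthy": (5.4, 2.2), "pd": (5.6, 2.9), "mild": (5.6, 2.9), "moderate": (4.7, 3.8)},
    "NFlex": {"healthy": (7.9, 2.2), "pd": (8.1, 2.9), "mild": (8.0, 2.9), "moderate": (7.2, 3.8)},
    "PS":   {"healthy": (0.1, 1.2), "pd": (-0.2, 0.8), "mild": (-0.2, 0.8), "moderate": (-0.1, 0.7)},
    "ASrom": {"healthy": (16.1, 7.8), "pd": (11.0, 6.3), "mild": (10.7, 5.3), "moderate": (10.9, 8.9)},
}

#: Features whose values the generator draws directly from the group marginals.
DRAWN_FEATURES = ("STp", "STDt", "STDl", "SPl", "SPw", "TFlex", "NFlex", "PS", "ASrom")
#: Drawn features whose marginal survives unconstrained: SPl is re-expressed as
#: a step phase and clipped to the interval the stance fraction admits, so its
#: realised distribution is mildly narrowed relative to the group marginal.
UNCONSTRAINED_DRAWS = ("STp", "STDt", "STDl", "SPw", "TFlex", "NFlex", "PS", "ASrom")
#: Features derived from the drawn ones through deterministic gait identities.
DERIVED_FEATURES = ("SWp", "DSp", "STt", "SWt", "STDc", "STDv", "SWv")


@dataclass
class GaitProfile:
    """Group-conditional gait parameter distributions (mean, sd per feature)."""

    group: str
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    @classmethod
    def for_group(cls, group: str) -> "GaitProfile":
        if group not in ("healthy", "pd", "mild", "moderate"):
            raise ValueError(f"unknown group {group!r}")
        mean = {f: GAIT_GROUP_STATS[f][group][0] for f in GAIT_GROUP_STATS}
        sd = {f: GAIT_GROUP_STATS[f][group][1] for f in GAIT_GROUP_STATS}
        return cls(group=group, mean=mean, sd=sd)


@dataclass
class WalkParameters:
    """One subject-walk's injected kinematic parameters (drawn or explicit)."""

    stance_pct: float = 60.1       # STp, %
    stride_time: float = 1.3       # STDt, s
    stride_length: float = 0.713   # STDl, m
    step_phase: float = 0.502      # contralateral HS phase within the cycle
    step_width: float = 0.088      # SPw, m
    trunk_flexion: float = 5.4     # TFlex, deg
    neck_flexion: float = 7.9      # NFlex, deg
    lateral_lean: float = 0.1      # PS, deg (positive = toward left)
    arm_swing_rom: float = 16.1    # ASrom, deg peak-to-peak
    noise_sd: float = 0.003        # m, per-joint Gaussian jitter
    n_strides: int = 5
    sample_rate: float = 30.0
    lead_in: float = 1.0           # T-pose calibration interval, s
    subject_height: float = 1.70
    heading_deg: float = 0.0       # walking direction vs camera -Z, about vertical

    def validate(self):
        leg = 0.53 * self.subject_height
        if not (50.0 < self.stance_pct < 75.0):
            raise ValueError("stance fraction must be in (50%, 75%)")
        if self.stride_length >= 2 * leg:
            raise ValueError("stride length must be < 2 * leg length")
        s = self.stance_pct / 100.0
        if not (1 - s < self.step_phase < s):
            raise ValueError("step phase incompatible with stance fraction")

    @property
    def injected_features(self) -> dict:
        """The 16 gait features implied by these parameters (cm / m/s / deg)."""
        s = self.stance_pct / 100.0
        T, L = self.stride_time, self.stride_length
        return {
            "STp": self.stance_pct, "SWp": 100.0 * (1 - s),
            "DSp": 100.0 * (2 * s - 1),
            "STt": s * T, "SWt": (1 - s) * T, "STDt": T, "STDc": 60.0 / T,
            "STDl": 100.0 * L, "SPl": 100.0 * self.step_phase * L,
            "SPw": 100.0 * self.step_width,
            "STDv": L / T, "SWv": L / ((1 - s) * T),
            "TFlex": self.trunk_flexion, "NFlex": self.neck_flexion,
            "PS": self.lateral_lean, "ASrom": self.arm_swing_rom,
        }


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=100):
    if sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def draw_walk_parameters(profile: GaitProfile, rng: np.random.Generator,
                         **overrides) -> WalkParameters:
    """Draw one physically feasible parameter set from a group profile.

    STp, STDt, STDl, SPw, TFlex, NFlex, PS and ASrom come from truncated
    normals on the group marginals; the contralateral step phase is SPl/STDl
    clipped to the range the stance fraction admits.
    """
    m, s = profile.mean, profile.sd
    stp = _truncated_normal(rng, m["STp"], s["STp"], 52.0, 74.0)
    stdt = _truncated_normal(rng, m["STDt"], s["STDt"], 0.7, 2.5)
    height = overrides.get("subject_height", 1.70)
    max_stride = 2 * 0.53 * height * 0.95
    stdl = _truncated_normal(rng, m["STDl"], s["STDl"], 20.0, 100.0 * max_stride) / 100.0
    spl = _truncated_normal(rng, m["SPl"], s["SPl"], 5.0, 100.0 * stdl) / 100.0
    frac = stp / 100.0
    # the contralateral HS phase must lie strictly inside (1 - s, s); shrink
    # the margin for near-50% stance draws so the interval stays non-empty
    margin = min(0.05, 0.4 * (2 * frac - 1))
    phase = float(np.clip(spl / stdl, 1 - frac + margin, frac - margin))
    params = WalkParameters(
        stance_pct=stp, stride_time=stdt, stride_length=stdl, step_phase=phase,
        step_width=_truncated_normal(rng, m["SPw"], s["SPw"], 2.0, 25.0) / 100.0,
        trunk_flexion=_truncated_normal(rng, m["TFlex"], s["TFlex"], -25.0, 25.0),
        neck_flexion=_truncated_normal(rng, m["NFlex"], s["NFlex"], -25.0, 25.0),
        lateral_lean=_truncated_normal(rng, m["PS"], s["PS"], -15.0, 15.0),
        arm_swing_rom=_truncated_normal(rng, m["ASrom"], s["ASrom"], 0.0, 60.0),
    )
    for k, v in overrides.items():
        params = replace(params, **{k: v})
    params.validate()
    return params


@dataclass
class WalkTruth:
    """Ground truth accompanying a generated walk."""

    params: WalkParameters
    events: GaitEvents
    features: dict  # the 16 injected feature values


def _swing_profile(tau, a=0.45):
    """Smooth 0->1 swing advance whose rate stays above (1 - a) > 0.

    The ankle keeps moving forward right up to foot contact and accelerates
    immediately at toe off (as a real foot does), so the extrema of the
    ankle-minus-pelvis forward coordinate coincide exactly with HS and TO.
    """
    return tau - a * np.sin(2 * np.pi * tau) / (2 * np.pi)


def generate_walk(source, seed=None, rng=None, **overrides):
    """Generate a camera-frame 25-joint walking sequence plus ground truth.

    ``source`` is either a GaitProfile (parameters are drawn) or an explicit
    WalkParameters.  The subject stands in place for the lead-in second, then
    walks straight toward the camera (placed 0.75 m high, 3.5 m away): the
    pelvis advances at stride_length/stride_time, each ankle alternates
    stance (anchored to its foot placement) and a smooth swing honoring the
    stance fraction, arms swing sinusoidally in anti-phase with the
    ipsilateral leg, constant trunk/neck/lateral tilts are injected and
    Gaussian jitter (noise_sd) is added to every joint.

    Returns (SkeletonSequence, WalkTruth) with exact HS/TO times.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(source, GaitProfile):
        params = draw_walk_parameters(source, rng, **overrides)
    else:
        params = replace(source, **overrides) if overrides else source
        params.validate()

    p = params
    fs, T, L = p.sample_rate, p.stride_time, p.stride_length
    s = p.stance_pct / 100.0
    phi = p.step_phase
    h0 = p.lead_in + 0.05                     # nominal first (virtual) left HS
    hs = {"left": h0 + np.arange(p.n_strides + 1) * T,
          "right": h0 + (phi + np.arange(p.n_strides + 1)) * T}
    to = {side: hs[side] + s * T for side in hs}
    # run on past the last (contralateral) heel strike so every truth event
    # is interior to the record and detectable
    t_end = hs["right"][-1] + 0.5 * T
    n = int(np.floor(t_end * fs)) + 1
    t = np.arange(n) / fs

    height = p.subject_height
    pelvis_h = 0.55 * height
    ankle_h = 0.05 * height
    trunk_len = 0.26 * height
    placements = {"left": (np.arange(p.n_strides + 1) * L, +p.step_width / 2),
                  "right": (phi * L + np.arange(p.n_strides + 1) * L, -p.step_width / 2)}

    def ankle_xyz(side):
        x_pl, y_lat = placements[side]
        x = np.full(n, x_pl[0])
        z = np.full(n, ankle_h)
        clearance = 0.03 + 0.03 * L
        for k in range(p.n_strides):
            m_st = (t >= hs[side][k]) & (t < to[side][k])
            x[m_st] = x_pl[k]
            m_sw = (t >= to[side][k]) & (t < hs[side][k + 1])
            tau = (t[m_sw] - to[side][k]) / (hs[side][k + 1] - to[side][k])
            x[m_sw] = x_pl[k] + L * _swing_profile(tau)
            z[m_sw] = ankle_h + clearance * np.sin(np.pi * tau)
        x[t >= hs[side][-1]] = x_pl[-1]
        x[t < hs[side][0]] = x_pl[0]
        return x, np.full(n, y_lat), z

    # pelvis advances at the mean gait speed once walking starts
    v = L / T
    pel_x = np.where(t < p.lead_in, 0.0, v * (t - p.lead_in))
    pel_x = pel_x - v * (hs["left"][1] - p.lead_in) + L * 1.0  # center over feet
    pel = np.column_stack([pel_x, np.zeros(n), np.full(n, pelvis_h)])

    tf, ll, nf = map(np.radians, (p.trunk_flexion, p.lateral_lean, p.neck_flexion))
    d_trunk = np.array([np.tan(tf), np.tan(ll), 1.0])
    d_trunk /= np.linalg.norm(d_trunk)
    d_neck = np.array([np.tan(nf), 0.0, 1.0])
    d_neck /= np.linalg.norm(d_neck)

    J = {}
    J["SpineBase"] = pel
    J["SpineMid"] = pel + 0.5 * trunk_len * d_trunk
    J["SpineShoulder"] = pel + trunk_len * d_trunk
    J["Neck"] = pel + 1.1 * trunk_len * d_trunk
    J["Head"] = J["Neck"] + 0.10 * height * d_neck

    amp = np.radians(p.arm_swing_rom / 2.0)
    ua, fa = 0.165 * height, 0.15 * height
    for side, lat_sign in (("left", 1.0), ("right", -1.0)):
        cap = side.capitalize()
        shoulder = J["SpineShoulder"] + np.array([0.0, lat_sign * 0.115 * height, -0.02])
        alpha = -amp * np.cos(2 * np.pi * (t - hs[side][1]) / T)
        arm_dir = np.column_stack([np.sin(alpha), np.zeros(n), -np.cos(alpha)])
        J[f"Shoulder{cap}"] = np.broadcast_to(shoulder, (n, 3)).copy()
        J[f"Elbow{cap}"] = J[f"Shoulder{cap}"] + ua * arm_dir
        J[f"Wrist{cap}"] = J[f"Elbow{cap}"] + fa * arm_dir
        J[f"Hand{cap}"] = J[f"Wrist{cap}"] + 0.05 * arm_dir
        J[f"HandTip{cap}"] = J[f"Hand{cap}"] + 0.04 * arm_dir
        J[f"Thumb{cap}"] = J[f"Hand{cap}"] + np.array([0.0, lat_sign * 0.03, 0.0])

        ax, ay, az = ankle_xyz(side)
        ankle = np.column_stack([ax, ay, az])
        hip = pel + np.array([0.0, lat_sign * 0.053 * height, -0.04 * height])
        J[f"Hip{cap}"] = hip
        J[f"Knee{cap}"] = 0.5 * (hip + ankle) + np.array([0.03, 0.0, 0.0])
        J[f"Ankle{cap}"] = ankle
        J[f"Foot{cap}"] = ankle + np.array([0.07 * height, 0.0, -0.5 * ankle_h])

    positions = np.stack([J[name] for name in KINECT_JOINTS], axis=1)
    positions += rng.normal(0.0, p.noise_sd, positions.shape)

    # subject frame (x fwd, y left, z up) -> camera frame (right-handed, Y up,
    # Z out of the sensor); subject starts 3.5 m from the camera (0.75 m high)
    th = np.radians(p.heading_deg)
    c, sn = np.cos(th), np.sin(th)
    xs = positions[..., 0] * c - positions[..., 1] * sn
    ys = positions[..., 0] * sn + positions[..., 1] * c
    cam = np.empty_like(positions)
    cam[..., 0] = -ys
    cam[..., 1] = positions[..., 2] - 0.75
    cam[..., 2] = 3.5 - xs
    seq = SkeletonSequence(timestamps=t, positions=cam, sample_rate=fs,
                           subject_height=height,
                           lower_limb_length=0.53 * height, frame="camera")
    events = GaitEvents(
        heel_strikes={side: hs[side][1:] for side in hs},
        toe_offs={side: to[side][:-1] for side in hs})
    return seq, WalkTruth(params=p, events=events, features=p.injected_features)


# ---------------------------------------------------------------------------
# tapping signals

@dataclass
class TapProfile:
    """Controls for a ten-repetition tapping signal.

    Periods and raw amplitudes (meters) vary per trial; tremor bumps are small
    extra peaks added in the inter-trial valleys; hesitations are mid-rise
    velocity plateaus produced by time-warping individual trials.
    """

    n_taps: int = 10
    period_mean: float = 0.40      # s
    period_sd: float = 0.0
    amplitude_mean: float = 0.10   # m
    amplitude_sd: float = 0.0
    duty: float = 0.7              # fraction of the period spent moving
    tremor_bumps: int = 0
    bump_amplitude: float = 0.06   # fraction of the mean amplitude
    hesitations: int = 0
    hesitation_hold: float = 0.3   # s added mid-rise dwell per hesitating tap
    noise_sd: float = 0.0          # m
    sample_rate: float = 30.0
    kind: str = "finger"

    def validate(self):
        if self.n_taps < 2:
            raise ValueError("need at least 2 taps")
        if self.period_mean <= 0:
            raise ValueError("period must be positive")


@dataclass
class TapTruth:
    durations: np.ndarray       # s, valley-to-valley per trial
    amplitudes: np.ndarray      # normalised peak amplitude per trial
    raw_amplitudes: np.ndarray  # m
    bump_times: np.ndarray
    plateau_trials: np.ndarray


def generate_tap_signal(profile: TapProfile, seed=None, rng=None):
    """Raised-cosine tap train with controllable variability.

    Each tap is a raised-cosine pulse occupying ``duty`` of its period,
    centred in the period so the inter-trial valleys have a short rest dwell
    (as real taps do).  Hesitating taps dwell mid-rise for
    ``hesitation_hold`` seconds, which lengthens their period and splits the
    rise-phase speed peak in two.  Tremor bumps are small Gaussian peaks
    placed in the rest dwells.  Returns (TapSignal normalised to [0, 1],
    TapTruth with per-trial durations/amplitudes and injection times).
    """
    profile.validate()
    if rng is None:
        rng = np.random.default_rng(seed)
    p = profile
    periods = np.array([_truncated_normal(rng, p.period_mean, p.period_sd,
                                          0.12, 3.0) for _ in range(p.n_taps)])
    amps = np.array([_truncated_normal(rng, p.amplitude_mean, p.amplitude_sd,
                                       0.005, 1.0) for _ in range(p.n_taps)])
    plateau_trials = np.sort(rng.choice(p.n_taps, size=min(p.hesitations, p.n_taps),
                                        replace=False)) if p.hesitations else np.array([], int)
    periods[plateau_trials] += p.hesitation_hold

    lead, tail = 0.25, 0.25
    bounds = lead + np.concatenate([[0.0], np.cumsum(periods)])
    total = bounds[-1] + tail
    n = int(np.floor(total * p.sample_rate)) + 1
    t = np.arange(n) / p.sample_rate
    d = np.zeros(n)

    for i in range(p.n_taps):
        width = p.duty * periods[i]
        start = bounds[i] + 0.5 * (periods[i] - width)
        m = (t >= start) & (t < start + width)
        tau = (t[m] - start) / width
        if i in plateau_trials:
            tau = _warp_with_plateau(tau, hold_fraction=p.hesitation_hold / width)
        d[m] = amps[i] * 0.5 * (1 - np.cos(2 * np.pi * tau))

    # tremor bumps centred on inter-trial rest dwells (locally flat, d ~ 0)
    valley_slots = list(bounds[1:-1]) + [lead / 2, total - tail / 2]
    n_bumps = min(p.tremor_bumps, len(valley_slots))
    pick = sorted(rng.choice(len(valley_slots), n_bumps, replace=False))
    bump_times = np.array([valley_slots[i] for i in pick])
    for tb in bump_times:
        d += p.bump_amplitude * p.amplitude_mean * np.exp(-0.5 * ((t - tb) / 0.045) ** 2)

    if p.noise_sd > 0:
        d += rng.normal(0.0, p.noise_sd, n)
    dmin, dmax = d.min(), d.max()
    signal = TapSignal(t=t, d=(d - dmin) / (dmax - dmin), kind=p.kind,
                       sample_rate=p.sample_rate)
    truth = TapTruth(durations=periods,
                     amplitudes=(amps - dmin) / (dmax - dmin),
                     raw_amplitudes=amps, bump_times=bump_times,
                     plateau_trials=plateau_trials)
    return signal, truth


def _warp_with_plateau(tau, hold_fraction=0.5, center=0.3, depth=0.97):
    """Monotone phase re-map that dwells near mid-rise (a velocity plateau).

    The rate dips to (1 - depth) inside a Gaussian window whose width is set
    from the requested hold fraction of the pulse, then the phase is
    re-normalised to end at 1.
    """
    width = max(hold_fraction / 2.355, 0.02)  # FWHM ~ hold duration
    grid = np.linspace(0, 1, 1025)
    rate = 1.0 - depth * np.exp(-0.5 * ((grid - center) / width) ** 2)
    phase = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(grid))])
    phase /= phase[-1]
    return np.interp(tau, grid, phase)


# ---------------------------------------------------------------------------
# marker frame rendering

def project(points: np.ndarray, intrinsics: CameraIntrinsics) -> np.ndarray:
    """Pinhole projection, the exact inverse of tapping.backproject."""
    pts = np.atleast_2d(points)
    if np.any(pts[:, 2] <= 0):
        raise ValueError("marker behind camera (Z <= 0)")
    u = intrinsics.cx + intrinsics.fx * pts[:, 0] / pts[:, 2]
    v = intrinsics.cy + intrinsics.fy * pts[:, 1] / pts[:, 2]
    return np.column_stack([u, v])


def render_marker_frames(positions: np.ndarray, timestamps: np.ndarray,
                         intrinsics: CameraIntrinsics = KINECT_V2_INTRINSICS,
                         shape=(424, 512), blob_sigma: float = 3.0,
                         peak: int = 50000, background: int = 400,
                         saturation: float = 2.0,
                         salt_fraction: float = 0.0, seed=None,
                         rng=None) -> FrameSequence:
    """Render IR/depth frame pairs showing Gaussian-profile marker blobs.

    ``positions`` is (n_frames, n_markers, 3) in the camera frame (meters,
    Z = depth).  Blobs have a saturated (flat-top) core, as retroreflective
    markers do in a real IR stream.  Depth frames carry the marker range
    inside each blob disk and a far background elsewhere; optional salt noise
    adds isolated hot pixels that the blob pipeline's morphology/area filter
    must reject.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    positions = np.asarray(positions, float)
    n, k, _ = positions.shape
    h, w = shape
    ir = np.full((n, h, w), background, dtype=np.uint16)
    far = int(round(2.5 / intrinsics.depth_scale))
    depth = np.full((n, h, w), far, dtype=np.uint16)
    rad = int(np.ceil(4 * blob_sigma))
    for i in range(n):
        uv = project(positions[i], intrinsics)
        for m in range(k):
            u, v = uv[m]
            z = positions[i, m, 2]
            r0, r1 = int(v) - rad, int(v) + rad + 1
            c0, c1 = int(u) - rad, int(u) + rad + 1
            rr0, cc0 = max(r0, 0), max(c0, 0)
            rr1, cc1 = min(r1, h), min(c1, w)
            if rr0 >= rr1 or cc0 >= cc1:
                continue
            vv, uu = np.mgrid[rr0:rr1, cc0:cc1]
            g = np.exp(-0.5 * (((uu - u) ** 2 + (vv - v) ** 2) / blob_sigma ** 2))
            patch = ir[i, rr0:rr1, cc0:cc1].astype(float) \
                + peak * np.minimum(1.0, saturation * g)
            ir[i, rr0:rr1, cc0:cc1] = np.clip(patch, 0, 65535).astype(np.uint16)
            disk = ((uu - u) ** 2 + (vv - v) ** 2) <= (3 * blob_sigma) ** 2
            dpatch = depth[i, rr0:rr1, cc0:cc1]
            dpatch[disk] = int(round(z / intrinsics.depth_scale))
            depth[i, rr0:rr1, cc0:cc1] = dpatch
        if salt_fraction > 0:
            n_salt = int(salt_fraction * h * w)
            rs = rng.integers(0, h, n_salt)
            cs = rng.integers(0, w, n_salt)
            ir[i, rs, cs] = min(65535, int(1.2 * peak))
    return FrameSequence(infrared=ir, depth=depth, timestamps=np.asarray(timestamps))


def finger_marker_trajectories(profile: TapProfile, seed=None, rng=None,
                               center=(0.0, 0.0, 0.8), closed_gap=0.03):
    """3D thumb/index marker trajectories for a finger-tapping trial.

    The thumb marker stays put; the index marker opens and closes along a
    fixed direction with aperture closed_gap + d(t).  Returns (positions
    (n, 2, 3), timestamps, TapSignal truth pair).
    """
    signal, truth = generate_tap_signal(profile, seed=seed, rng=rng)
    # reconstruct the raw (meter) aperture from the normalised signal
    raw = signal.d * (truth.raw_amplitudes.max())
    direction = np.array([0.6, -0.8, 0.0])
    thumb = np.broadcast_to(np.asarray(center, float), (len(signal.t), 3)).copy()
    index = thumb + (closed_gap + raw)[:, None] * direction
    positions = np.stack([thumb, index], axis=1)
    return positions, signal.t, (signal, truth)


# ---------------------------------------------------------------------------
# tapping group profiles (no published group statistics exist for these
# features; defaults separate the groups moderately and are generator-owned)

TAP_GROUP_DEFAULTS = {
    # kind -> group -> dict of TapProfile overrides
    "finger": {
        "healthy": dict(period_mean=0.35, period_sd=0.02, amplitude_mean=0.10,
                        amplitude_sd=0.008, tremor_bumps=0, hesitations=0),
        "mild": dict(period_mean=0.45, period_sd=0.05, amplitude_mean=0.07,
                     amplitude_sd=0.015, tremor_bumps=2, hesitations=1),
        "moderate": dict(period_mean=0.55, period_sd=0.08, amplitude_mean=0.05,
                         amplitude_sd=0.020, tremor_bumps=4, hesitations=3),
    },
    "foot": {
        "healthy": dict(period_mean=0.45, period_sd=0.03, amplitude_mean=0.08,
                        amplitude_sd=0.006, tremor_bumps=0, hesitations=0),
        "mild": dict(period_mean=0.60, period_sd=0.06, amplitude_mean=0.055,
                     amplitude_sd=0.012, tremor_bumps=2, hesitations=1),
        "moderate": dict(period_mean=0.75, period_sd=0.10, amplitude_mean=0.04,
                         amplitude_sd=0.016, tremor_bumps=3, hesitations=3),
    },
}

#: subject-level spread applied to the group period/amplitude means
TAP_BETWEEN_SUBJECT_SD = {"period_mean": 0.05, "amplitude_mean": 0.012}


def draw_tap_profile(kind: str, group: str, rng: np.random.Generator,
                     noise_sd: float = 0.001) -> TapProfile:
    base = dict(TAP_GROUP_DEFAULTS[kind][group])
    base["period_mean"] = _truncated_normal(
        rng, base["period_mean"], TAP_BETWEEN_SUBJECT_SD["period_mean"], 0.15, 2.0)
    base["amplitude_mean"] = _truncated_normal(
        rng, base["amplitude_mean"], TAP_BETWEEN_SUBJECT_SD["amplitude_mean"], 0.01, 0.3)
    bumps = rng.poisson(base.pop("tremor_bumps")) if base.get("tremor_bumps") is not None else 0
    hes = rng.poisson(base.pop("hesitations"))
    return TapProfile(kind=kind, tremor_bumps=int(bumps), hesitations=int(hes),
                      noise_sd=noise_sd, **base)


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortConfig:
    """Study cohort layout: counts per group, each subject contributing a left
    and a right instance (sides are treated as independent instances)."""

    n_healthy: int = 14
    n_mild: int = 9
    n_moderate: int = 7
    seed: int = 0
    sample_rate: float = 30.0
    joint_noise_sd: float = 0.003
    tap_noise_sd: float = 0.001
    n_strides: int = 5
    include_tapping: bool = True

    @property
    def n_instances(self) -> int:
        return 2 * (self.n_healthy + self.n_mild + self.n_moderate)


def case_config(case: str, seed: int = 0, **overrides) -> CohortConfig:
    """Default study cohorts: case A = 14 healthy + 16 PD subjects
    (60 instances), case B = 9 mild + 7 moderate (32 instances)."""
    if case.upper() == "A":
        cfg = CohortConfig(n_healthy=14, n_mild=9, n_moderate=7, seed=seed)
    elif case.upper() == "B":
        cfg = CohortConfig(n_healthy=0, n_mild=9, n_moderate=7, seed=seed)
    else:
        raise ValueError("case must be 'A' or 'B'")
    return replace(cfg, **overrides) if overrides else cfg


def generate_cohort(config: CohortConfig, max_attempts: int = 5):
    """Synthesize a labeled cohort and run the full extraction pipeline.

    Per subject: draw gait parameters from the group profile, generate one
    walk, extract the 16 gait features for each side; per side, draw finger
    and foot tapping profiles, generate the signals and extract the 8+8
    tapping features.  Returns (features DataFrame, truth DataFrame); both
    are deterministic functions of the config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    groups = (["healthy"] * config.n_healthy + ["mild"] * config.n_mild
              + ["moderate"] * config.n_moderate)
    rows, truth_rows = [], []
    for sid, (group, child) in enumerate(zip(groups, ss.spawn(len(groups))), start=1):
        rng = np.random.default_rng(child)
        profile = GaitProfile.for_group(group)
        for attempt in range(max_attempts):
            try:
                seq, truth = generate_walk(profile, rng=rng,
                                           noise_sd=config.joint_noise_sd,
                                           n_strides=config.n_strides,
                                           sample_rate=config.sample_rate)
                feats = {side: extract_gait_features(seq, side=side).to_dict()
                         for side in ("left", "right")}
                break
            except ValueError:
                if attempt == max_attempts - 1:
                    raise
        for side in ("left", "right"):
            row = {"subject": f"S{sid:02d}", "side": side, "group": group}
            row.update(feats[side])
            if config.include_tapping:
                for kind, prefix in (("finger", "fit"), ("foot", "fot")):
                    prof = draw_tap_profile(kind, group, rng, config.tap_noise_sd)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        sig, _ = generate_tap_signal(prof, rng=rng)
                        tf = extract_tap_features(sig)
                    row.update({f"{prefix}_{k}": v for k, v in tf.to_dict().items()})
            rows.append(row)
            trow = {"subject": f"S{sid:02d}", "side": side, "group": group}
            trow.update(truth.features)
            truth_rows.append(trow)
    features = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return features, truth
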