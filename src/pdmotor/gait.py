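"""Gait cycle segmentation and postural / spatio-temporal / angular features.

A gait cycle runs from one heel strike (HS) of a foot to the next HS of the
same foot; stance ends at that foot's toe off (TO).  Events are detected from
the ankle position relative to the pelvis along the walking direction: the
ankle is maximally ahead of the pelvis at heel strike and maximally behind at
toe off, so HS/TO are the extrema of that relative forward coordinate (the
kinematic event proxy of Zeni-style detection).

Sixteen features are computed per (sequence, side):

temporal   STp, SWp, DSp [%], STt, SWt, STDt [s], STDc [strides/min]
spatial    STDl, SPl, SPw [cm], STDv, SWv [m/s]
angular    TFlex, NFlex, PS, ASrom [deg]

All computations are done in the subject reference frame (x forward, y left,
z up); camera-frame input is converted automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ._filters import lowpass
from .io import SkeletonSequence, camera_to_subject_frame

SIDES = ("left", "right")
OTHER = {"left": "right", "right": "left"}

GAIT_FEATURES = ("STp", "SWp", "DSp", "STt", "SWt", "STDt", "STDc",
                 "STDl", "SPl", "SPw", "STDv", "SWv",
                 "TFlex", "NFlex", "PS", "ASrom")

#: Gait-cycle phase names in order (stance: LR..PSW, swing: ISW..TSW).
PHASES = ("LR", "MST", "TST", "PSW", "ISW", "MSW", "TSW")


class NoCompleteCycleError(ValueError):
    """Fewer than one full ipsilateral HS-to-HS cycle in the recording."""


@dataclass
class GaitEvents:
    """Per-side heel-strike and toe-off times, seconds."""

    heel_strikes: dict  # side -> sorted ndarray of times
    toe_offs: dict      # side -> sorted ndarray of times


@dataclass
class GaitCycle:
    """One HS-to-HS cycle of a side with its internal event times."""

    side: str
    start_hs: float
    end_hs: float
    toe_off: float
    contra_hs: float
    contra_to: float

    @property
    def duration(self) -> float:
        return self.end_hs - self.start_hs

    @property
    def stance_time(self) -> float:
        return self.toe_off - self.start_hs

    @property
    def swing_time(self) -> float:
        return self.end_hs - self.toe_off

    @property
    def double_support_time(self) -> float:
        # initial DS: ipsi HS -> contra TO; terminal DS: contra HS -> ipsi TO
        return (self.contra_to - self.start_hs) + (self.toe_off - self.contra_hs)

    @property
    def phases(self) -> dict:
        """Boundaries of the seven conventional phases, (start, end) seconds.

        LR and PSW are fixed by the contralateral events; the MST/TST split is
        placed at 30% of the cycle and the swing is split into equal thirds
        (conventional percentages -- no feature depends on these inner bounds).
        """
        t0, t1 = self.start_hs, self.end_hs
        mst_end = max(self.contra_to, t0 + 0.30 * self.duration)
        mst_end = min(mst_end, self.contra_hs)
        sw = (self.toe_off, self.end_hs)
        third = (sw[1] - sw[0]) / 3.0
        return {
            "LR": (t0, self.contra_to),
            "MST": (self.contra_to, mst_end),
            "TST": (mst_end, self.contra_hs),
            "PSW": (self.contra_hs, self.toe_off),
            "ISW": (sw[0], sw[0] + third),
            "MSW": (sw[0] + third, sw[0] + 2 * third),
            "TSW": (sw[0] + 2 * third, t1),
        }


@dataclass
class GaitFeatureVector:
    STp: float
    SWp: float
    DSp: float
    STt: float
    SWt: float
    STDt: float
    STDc: float
    STDl: float
    SPl: float
    SPw: float
    STDv: float
    SWv: float
    TFlex: float
    NFlex: float
    PS: float
    ASrom: float
    normalized: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in GAIT_FEATURES}
        d.update(self.normalized)
        return d


def _ensure_subject_frame(seq: SkeletonSequence) -> SkeletonSequence:
    return seq if seq.frame == "subject" else camera_to_subject_frame(seq)


def _relative_forward(seq: SkeletonSequence, side: str, cutoff: float = 6.0):
    ankle = seq.joint(f"Ankle{side.capitalize()}")
    pelvis = seq.joint("SpineBase")
    rel = ankle[:, 0] - pelvis[:, 0]
    fs = seq.sample_rate
    return lowpass(rel, fs, cutoff)


def detect_gait_events(seq: SkeletonSequence, min_excursion: float = 0.08,
                       smooth_cutoff: float = 6.0) -> GaitEvents:
    """Detect heel strikes and toe offs for both sides.

    HS = local maxima, TO = local minima of the ankle-minus-pelvis forward
    coordinate; peak times are refined to sub-frame precision by parabolic
    interpolation.  If two HS candidates fall within 0.2 s the one with the
    lower ankle height wins.
    """
    seq = _ensure_subject_frame(seq)
    fs = seq.sample_rate
    t = seq.timestamps
    hs, to = {}, {}
    for side in SIDES:
        rel = _relative_forward(seq, side, smooth_cutoff)
        span = rel.max() - rel.min()
        if span < min_excursion:
            hs[side] = np.array([])
            to[side] = np.array([])
            continue
        dist = max(1, int(round(0.4 * fs)))
        prom = 0.25 * span
        hs_idx, _ = find_peaks(rel, prominence=prom, distance=dist)
        to_idx, _ = find_peaks(-rel, prominence=prom, distance=dist)
        hs_idx = _dedupe_heel_strikes(seq, side, hs_idx, fs)
        raw = _relative_forward(seq, side, cutoff=np.inf)
        hs[side] = np.array(sorted(_refine_corner(t, raw, i, swing_side="left")
                                   for i in hs_idx))
        to[side] = np.array(sorted(_refine_corner(t, -raw, i, swing_side="right")
                                   for i in to_idx))
    if all(len(hs[s]) < 2 for s in SIDES):
        raise NoCompleteCycleError("no complete cycle: fewer than 2 heel strikes per side")
    return GaitEvents(heel_strikes=hs, toe_offs=to)


def _refine_corner(t, y, idx, swing_side: str, swing_window: int = 4,
                   stance_window: int = 5) -> float:
    """Sub-frame timing of a foot-contact extremum of y (a maximum).

    Foot contact is a slope break, not a smooth parabola: on the stance side
    the ankle-minus-pelvis coordinate recedes linearly at the gait speed,
    while on the swing side it approaches along a curve.  The event time is
    the intersection of a straight-line fit on the stance side with a local
    quadratic fit on the swing side (corner sample included in the latter).
    Falls back to the discrete peak when the fit windows are truncated.
    """
    # recentre on the unfiltered peak: the rough index came from a smoothed trace
    lo = max(idx - 3, 0)
    idx = lo + int(np.argmax(y[lo:min(idx + 4, len(y))]))
    w = max(swing_window, stance_window)
    if idx - w < 0 or idx + w >= len(y):
        return float(t[idx])
    if swing_side == "left":
        qs = slice(idx - swing_window, idx + 1)
        ls = slice(idx + 1, idx + stance_window + 1)
    else:
        qs = slice(idx, idx + swing_window + 1)
        ls = slice(idx - stance_window, idx)
    t0 = t[idx]
    cq = np.polyfit(t[qs] - t0, y[qs], 2)
    a, b = np.polyfit(t[ls] - t0, y[ls], 1)
    coeffs = [cq[0], cq[1] - a, cq[2] - b]
    roots = np.roots(coeffs)
    roots = roots[np.isreal(roots)].real
    if len(roots) == 0:
        return float(t0)
    tc = roots[np.argmin(np.abs(roots))]
    dt = t[1] - t[0]
    return float(np.clip(t0 + tc, t0 - 2 * dt, t0 + 2 * dt))


def _dedupe_heel_strikes(seq, side, idx, fs):
    """Among HS candidates closer than 0.2 s keep the one with lower ankle."""
    if len(idx) < 2:
        return idx
    height = seq.joint(f"Ankle{side.capitalize()}")[:, 2]
    keep = [idx[0]]
    for i in idx[1:]:
        if (i - keep[-1]) / fs < 0.2:
            if height[i] < height[keep[-1]]:
                keep[-1] = i
        else:
            keep.append(i)
    return np.array(keep)


def segment_cycles(events: GaitEvents) -> list:
    """Build one GaitCycle per ipsilateral HS->HS interval, both sides.

    Cycles lacking exactly one ipsilateral TO, one contralateral HS and one
    contralateral TO in the expected sub-intervals are discarded with a
    warning.
    """
    cycles = []
    for side in SIDES:
        hs = events.heel_strikes.get(side, np.array([]))
        to = events.toe_offs.get(side, np.array([]))
        chs = events.heel_strikes.get(OTHER[side], np.array([]))
        cto = events.toe_offs.get(OTHER[side], np.array([]))
        for k in range(len(hs) - 1):
            t0, t1 = hs[k], hs[k + 1]
            ipsi_to = to[(to > t0) & (to < t1)]
            c_hs = chs[(chs > t0) & (chs < t1)]
            if len(ipsi_to) != 1 or len(c_hs) != 1:
                warnings.warn(f"{side} cycle [{t0:.2f}, {t1:.2f}] s discarded: "
                              "missing/extra internal events")
                continue
            c_to = cto[(cto > t0) & (cto < ipsi_to[0])]
            if len(c_to) != 1 or not (c_hs[0] < ipsi_to[0]):
                warnings.warn(f"{side} cycle [{t0:.2f}, {t1:.2f}] s discarded: "
                              "contralateral events out of order")
                continue
            cycles.append(GaitCycle(side=side, start_hs=float(t0), end_hs=float(t1),
                                    toe_off=float(ipsi_to[0]), contra_hs=float(c_hs[0]),
                                    contra_to=float(c_to[0])))
    return cycles


# ---------------------------------------------------------------------------
# features

def temporal_features(cycles: list) -> dict:
    """STp, SWp, DSp [%], STt, SWt, STDt [s], STDc [strides/min].

    Percentages are ratios of mean durations, so STp + SWp = 100 exactly and
    STDc * STDt = 60 exactly.
    """
    if not cycles:
        raise NoCompleteCycleError("no complete cycle")
    stt = float(np.mean([c.stance_time for c in cycles]))
    swt = float(np.mean([c.swing_time for c in cycles]))
    stdt = float(np.mean([c.duration for c in cycles]))
    ds = float(np.mean([c.double_support_time for c in cycles]))
    return {
        "STt": stt, "SWt": swt, "STDt": stdt,
        "STp": 100.0 * stt / stdt, "SWp": 100.0 * swt / stdt,
        "DSp": 100.0 * ds / stdt, "STDc": 60.0 / stdt,
    }


def _interp_traj(seq: SkeletonSequence, joint: str):
    traj = seq.joint(joint)
    t = seq.timestamps

    def at(times, axis):
        return np.interp(times, t, traj[:, axis])

    return at


def spatial_features(seq: SkeletonSequence, cycles: list) -> dict:
    """STDl, SPl, SPw [cm], STDv, SWv [m/s] averaged over cycles.

    STDl = forward ankle travel between the two ipsilateral heel strikes;
    SPl = forward inter-ankle distance at the contralateral heel strike;
    SPw = mediolateral distance between the ankle placements at the two heel
    strikes of the cycle; STDv = STDl / STDt; SWv = mean forward ankle speed
    during swing.
    """
    seq = _ensure_subject_frame(seq)
    if not cycles:
        raise NoCompleteCycleError("no complete cycle")
    stdl, spl, spw, stdv, swv = [], [], [], [], []
    for c in cycles:
        ipsi = _interp_traj(seq, f"Ankle{c.side.capitalize()}")
        contra = _interp_traj(seq, f"Ankle{OTHER[c.side].capitalize()}")
        length = abs(ipsi(c.end_hs, 0) - ipsi(c.start_hs, 0))
        stdl.append(length)
        spl.append(abs(contra(c.contra_hs, 0) - ipsi(c.contra_hs, 0)))
        spw.append(abs(ipsi(c.start_hs, 1) - contra(c.contra_hs, 1)))
        stdv.append(length / c.duration)
        swv.append(abs(ipsi(c.end_hs, 0) - ipsi(c.toe_off, 0)) / c.swing_time)
    stdl_m = float(np.mean(stdl))
    if stdl_m < 0.05:
        warnings.warn("near-zero stride length: stepping in place?")
    return {"STDl": 100.0 * stdl_m, "SPl": 100.0 * float(np.mean(spl)),
            "SPw": 100.0 * float(np.mean(spw)), "STDv": float(np.mean(stdv)),
            "SWv": float(np.mean(swv))}


def _segment_angles(seq: SkeletonSequence, top: str, bottom: str):
    """Sagittal and frontal angles (deg) of the bottom->top segment vs vertical."""
    vec = seq.joint(top) - seq.joint(bottom)
    sag = np.degrees(np.arctan2(vec[:, 0], vec[:, 2]))
    front = np.degrees(np.arctan2(vec[:, 1], vec[:, 2]))
    return sag, front


def _harmonic_rom(t: np.ndarray, angle: np.ndarray, period: float) -> float:
    """Range of motion as twice the fundamental-harmonic amplitude.

    A least-squares sinusoid at the stride frequency is fitted to the angle
    trace; its peak-to-peak excursion equals max-min for sinusoidal swing and
    is unbiased under additive joint noise, unlike a raw max-min.
    """
    if len(t) < 4:
        return float("nan")
    w = 2 * np.pi / period
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(design, angle, rcond=None)
    return 2.0 * float(np.hypot(coef[1], coef[2]))


def angular_features(seq: SkeletonSequence, cycles: list, side: str) -> dict:
    """TFlex, NFlex, PS, ASrom in degrees, averaged over the side's cycles.

    TFlex / NFlex: mean sagittal inclination of the trunk (SpineBase ->
    SpineShoulder) and neck (Neck -> Head) segments vs the vertical, forward
    lean positive.  PS: mean frontal-plane trunk inclination, positive toward
    the analysed side.  ASrom: per-cycle range of motion of the sagittal
    shoulder-to-elbow angle.
    """
    seq = _ensure_subject_frame(seq)
    side_cycles = [c for c in cycles if c.side == side]
    if not side_cycles:
        raise NoCompleteCycleError(f"no complete {side} cycle")
    t = seq.timestamps
    trunk_sag, trunk_front = _segment_angles(seq, "SpineShoulder", "SpineBase")
    neck_sag, _ = _segment_angles(seq, "Head", "Neck")
    arm = seq.joint(f"Elbow{side.capitalize()}") - seq.joint(f"Shoulder{side.capitalize()}")
    arm_sag = np.degrees(np.arctan2(arm[:, 0], -arm[:, 2]))  # vs vertical-down

    tflex, nflex, ps, rom = [], [], [], []
    for c in side_cycles:
        m = (t >= c.start_hs) & (t <= c.end_hs)
        if m.sum() < 4:
            continue
        tflex.append(np.mean(trunk_sag[m]))
        nflex.append(np.mean(neck_sag[m]))
        ps.append(np.mean(trunk_front[m]))
        rom.append(_harmonic_rom(t[m], arm_sag[m], c.duration))
    sign = 1.0 if side == "left" else -1.0  # +y is the subject's left
    return {"TFlex": float(np.mean(tflex)), "NFlex": float(np.mean(nflex)),
            "PS": sign * float(np.mean(ps)), "ASrom": float(np.mean(rom))}


def extract_gait_features(seq: SkeletonSequence, side: str = "left",
                          normalize: bool = False,
                          events: GaitEvents | None = None) -> GaitFeatureVector:
    """All 16 gait features for one side of a walk.

    Spatial lengths are reported raw in cm (velocities in m/s); with
    ``normalize=True`` dimensionless height-normalised copies (widths by
    lower-limb length) are added under ``<name>_norm`` keys.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    seq = _ensure_subject_frame(seq)
    if events is None:
        events = detect_gait_events(seq)
    cycles = segment_cycles(events)
    side_cycles = [c for c in cycles if c.side == side]
    if not side_cycles:
        raise NoCompleteCycleError(f"no complete cycle for side {side}")
    feats = temporal_features(side_cycles)
    feats.update(spatial_features(seq, side_cycles))
    feats.update(angular_features(seq, cycles, side))
    normalized = {}
    if normalize:
        h_cm = 100.0 * seq.subject_height
        normalized = {
            "STDl_norm": feats["STDl"] / h_cm,
            "SPl_norm": feats["SPl"] / h_cm,
            "SPw_norm": feats["SPw"] / (100.0 * seq.lower_limb_length),
        }
    return GaitFeatureVector(**feats, normalized=normalized)
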