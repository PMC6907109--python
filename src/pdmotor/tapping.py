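"""Marker tracking and finger/foot tapping feature extraction.

Reflective markers appear as bright blobs in the infrared stream.  The blob
pipeline segments them (threshold -> blur+threshold -> morphological opening
-> closing -> contour/label -> area filter -> centroid), the centroid plus the
aligned depth frame is back-projected through the pinhole intrinsics to a 3D
point, and the marker trajectories yield two scalar signals:

* d1(t) - distance between the index and thumb markers (finger tapping);
* d2(t) - distance of the toe marker from its on-ground rest position
  (foot tapping).

Both are min-max normalised to [0, 1].  The ten tap trials are segmented
valley-to-valley around the dominant peaks and eight features are computed:
meanTime, varTime, meanAmplitude, varAmplitude, tremors, hesitations,
periodicity, AxF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage import measure, morphology

from ._filters import lowpass
from .io import CameraIntrinsics

TAP_FEATURES = ("meanTime", "varTime", "meanAmplitude", "varAmplitude",
                "tremors", "hesitations", "periodicity", "AxF")


class UninformativeFrameError(ValueError):
    """More than half the frame is above threshold: no marker segmentation."""


class ZeroDynamicRangeError(ValueError):
    """The distance signal has no usable dynamic range."""


class InsufficientSignalError(ValueError):
    """Too little overlapping track support to build a signal."""


class CannotSegmentError(ValueError):
    """Too few dominant peaks to delimit tap trials."""


@dataclass
class BlobConfig:
    """Tunable parameters of the marker blob pipeline.

    The threshold is relative to the frame maximum (reflective markers
    saturate the IR image); blur and structuring-element sizes follow common
    defaults since only the operations, not their parameters, are dictated by
    the acquisition protocol.
    """

    rel_threshold: float = 0.8
    blur_sigma: float = 1.0          # ~5x5 Gaussian kernel
    selem_radius: int = 1            # 3x3 disk structuring element
    max_bright_fraction: float = 0.5


@dataclass
class MarkerTrack:
    """Per-frame 3D positions of one marker; NaN rows mark detection gaps."""

    timestamps: np.ndarray
    positions: np.ndarray        # (n, 3) meters, NaN where lost
    pixels: np.ndarray = None    # (n, 2) (u, v), NaN where lost
    areas: np.ndarray = None     # (n,) px^2

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, float)
        self.positions = np.asarray(self.positions, float)
        if self.pixels is None:
            self.pixels = np.full((len(self.timestamps), 2), np.nan)
        if self.areas is None:
            self.areas = np.full(len(self.timestamps), np.nan)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.positions).any(axis=1)


@dataclass
class TapSignal:
    """Uniformly sampled normalised distance signal in [0, 1]."""

    t: np.ndarray
    d: np.ndarray
    kind: str = "finger"
    sample_rate: float = 30.0

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.d = np.asarray(self.d, float)


@dataclass
class TapTrial:
    start: float
    end: float
    peak_time: float
    peak_amplitude: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TapFeatureVector:
    meanTime: float
    varTime: float
    meanAmplitude: float
    varAmplitude: float
    tremors: int
    hesitations: int
    periodicity: float
    AxF: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in TAP_FEATURES}


# ---------------------------------------------------------------------------
# vision stage

def detect_marker_blobs(ir_frame: np.ndarray, size_range=(20, 2000),
                        config: BlobConfig | None = None) -> list:
    """Segment reflective-marker blobs in one IR frame.

    Returns [(centroid (u, v), area), ...] ordered by area descending; the
    centroid is the binary center of mass of the connected component.  An
    empty list means no blob survived; a frame with more than half its pixels
    above threshold raises UninformativeFrameError.
    """
    cfg = config or BlobConfig()
    frame = np.asarray(ir_frame, dtype=float)
    peak = frame.max()
    if peak <= 0:
        return []
    thr = cfg.rel_threshold * peak
    mask = frame > thr
    if mask.mean() > cfg.max_bright_fraction:
        raise UninformativeFrameError(
            f"{mask.mean():.0%} of pixels above threshold: uninformative frame")
    # blur + re-threshold rejects isolated hot pixels that survive the raw cut
    blurred = ndimage.gaussian_filter(frame, cfg.blur_sigma)
    mask &= blurred > thr
    selem = morphology.disk(cfg.selem_radius)
    mask = ndimage.binary_opening(mask, structure=selem)
    mask = ndimage.binary_closing(mask, structure=selem)
    labels = measure.label(mask, connectivity=2)
    out = []
    for region in measure.regionprops(labels):
        if size_range[0] <= region.area <= size_range[1]:
            v, u = region.centroid  # row, col -> v, u
            out.append(((float(u), float(v)), float(region.area)))
    out.sort(key=lambda b: -b[1])
    return out


def backproject(centroid, depth_frame: np.ndarray,
                intrinsics: CameraIntrinsics):
    """Pinhole back-projection of a pixel centroid to a 3D camera point.

    X = (u - cx) z / fx, Y = (v - cy) z / fy, Z = z = depth * depth_scale.
    Invalid (zero) depth at the centroid falls back to the median of the
    valid 3x3 neighborhood; if none is valid, returns None (a gap).
    """
    u, v = centroid
    depth = np.asarray(depth_frame)
    r, c = int(round(v)), int(round(u))
    h, w = depth.shape
    if not (0 <= r < h and 0 <= c < w):
        return None
    z_raw = float(depth[r, c])
    if z_raw <= 0:
        patch = depth[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
        valid = patch[patch > 0]
        if valid.size == 0:
            return None
        z_raw = float(np.median(valid))
    z = z_raw * intrinsics.depth_scale
    x = (u - intrinsics.cx) * z / intrinsics.fx
    y = (v - intrinsics.cy) * z / intrinsics.fy
    return np.array([x, y, z])


def track_markers(frames, intrinsics: CameraIntrinsics, n_markers: int,
                  size_range=(20, 2000), config: BlobConfig | None = None) -> list:
    """Detect and identify markers across a FrameSequence.

    Identity is assigned by blob area on the first detection (largest first:
    the thumb thimble is assumed the larger marker) and by nearest-neighbor
    pixel distance thereafter; d1 is symmetric so an identity swap is
    harmless.  Returns a list of n_markers MarkerTrack with NaN gaps.
    """
    n = frames.n_frames
    positions = np.full((n_markers, n, 3), np.nan)
    pixels = np.full((n_markers, n, 2), np.nan)
    areas = np.full((n_markers, n), np.nan)
    prev = [None] * n_markers
    for i in range(n):
        try:
            blobs = detect_marker_blobs(frames.infrared[i], size_range, config)
        except UninformativeFrameError:
            continue
        blobs = blobs[:n_markers]
        if any(p is not None for p in prev) and blobs:
            order = _assign_by_distance(prev, [b[0] for b in blobs])
        else:
            order = list(range(len(blobs)))  # area-descending initial identity
        for slot, bi in zip(order, range(len(blobs))):
            (u, v), area = blobs[bi]
            p = backproject((u, v), frames.depth[i], intrinsics)
            if p is None:
                continue
            positions[slot, i] = p
            pixels[slot, i] = (u, v)
            areas[slot, i] = area
            prev[slot] = (u, v)
    return [MarkerTrack(frames.timestamps, positions[m], pixels[m], areas[m])
            for m in range(n_markers)]


def _assign_by_distance(prev, centroids):
    """Greedy nearest-neighbor assignment of detections to track slots."""
    slots = [i for i, p in enumerate(prev) if p is not None]
    free = [i for i, p in enumerate(prev) if p is None]
    order = [-1] * len(centroids)
    used = set()
    for bi, c in enumerate(centroids):
        best, best_d = None, np.inf
        for s in slots:
            if s in used:
                continue
            d = np.hypot(c[0] - prev[s][0], c[1] - prev[s][1])
            if d < best_d:
                best, best_d = s, d
        if best is None and free:
            best = free.pop(0)
        if best is None:
            best = bi
        used.add(best)
        order[bi] = best
    return order


# ---------------------------------------------------------------------------
# signal stage

def _fill_gaps(values: np.ndarray, max_gap: int = 3) -> np.ndarray:
    """Linearly interpolate NaN runs of length <= max_gap; longer runs stay NaN."""
    out = values.copy()
    isnan = np.isnan(out)
    if not isnan.any():
        return out
    idx = np.arange(len(out))
    runs = _nan_runs(isnan)
    for start, stop in runs:
        if stop - start <= max_gap and start > 0 and stop < len(out):
            out[start:stop] = np.interp(idx[start:stop],
                                        [start - 1, stop], [out[start - 1], out[stop]])
    return out


def _nan_runs(isnan):
    runs, start = [], None
    for i, flag in enumerate(isnan):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(isnan)))
    return runs


def _normalize(t, d, kind, sample_rate, min_range=1e-3):
    valid = ~np.isnan(d)
    if valid.sum() < 2:
        raise InsufficientSignalError("no valid samples")
    t, d = t[valid], d[valid]
    rng = d.max() - d.min()
    if rng < min_range:
        raise ZeroDynamicRangeError(
            f"signal dynamic range {rng:.2e} m below {min_range} m")
    d = (d - d.min()) / rng
    return TapSignal(t=t, d=d, kind=kind, sample_rate=sample_rate)


def build_finger_signal(track_a: MarkerTrack, track_b: MarkerTrack,
                        max_gap: int = 3, min_overlap: float = 2.0) -> TapSignal:
    """d1(t): Euclidean inter-marker distance, gap-filled and normalised."""
    if len(track_a.timestamps) != len(track_b.timestamps):
        raise ValueError("tracks must share a common frame grid")
    t = track_a.timestamps
    both = track_a.valid & track_b.valid
    if both.sum() < 2 or t[both][-1] - t[both][0] < min_overlap:
        raise InsufficientSignalError(
            f"overlapping track support shorter than {min_overlap} s")
    pa = np.column_stack([_fill_gaps(track_a.positions[:, k], max_gap) for k in range(3)])
    pb = np.column_stack([_fill_gaps(track_b.positions[:, k], max_gap) for k in range(3)])
    d = np.linalg.norm(pa - pb, axis=1)
    fs = 1.0 / np.median(np.diff(t))
    return _normalize(t, d, "finger", fs)


def build_foot_signal(track: MarkerTrack, max_gap: int = 3,
                      min_rest: float = 0.3) -> TapSignal:
    """d2(t): distance from the marker's on-ground rest position.

    The rest reference is the median position over the lowest-decile-height
    frames (image convention: larger v/Y is closer to the floor).
    """
    t = track.timestamps
    pos = np.column_stack([_fill_gaps(track.positions[:, k], max_gap) for k in range(3)])
    valid = ~np.isnan(pos).any(axis=1)
    if valid.sum() < 2:
        raise InsufficientSignalError("no valid samples")
    height = pos[:, 1]  # +Y is down in the image frame
    cutoff = np.nanpercentile(height, 90)
    rest = valid & (height >= cutoff)
    fs = 1.0 / np.median(np.diff(t))
    if rest.sum() / fs < min_rest:
        raise InsufficientSignalError("no rest interval (toes on ground) detected")
    ref = np.median(pos[rest], axis=0)
    d = np.linalg.norm(pos - ref, axis=1)
    return _normalize(t, d, "foot", fs)


def segment_trials(signal: TapSignal, prominence: float = 0.3,
                   min_separation: float = 0.15, max_trials: int = 10) -> list:
    """Delimit tap trials valley-to-valley around the dominant peaks.

    Dominant peaks have prominence >= 0.3 (normalised units) and are at least
    0.15 s apart; only the first ``max_trials`` are kept (the protocol asks
    for ten taps) and fewer than ten raises a warning.
    """
    d, t = signal.d, signal.t
    dist = max(1, int(round(min_separation * signal.sample_rate)))
    peaks, _ = find_peaks(d, prominence=prominence, distance=dist)
    if len(peaks) < 2:
        raise CannotSegmentError(
            f"cannot segment: {len(peaks)} dominant peak(s) found")
    if len(peaks) > max_trials:
        peaks = peaks[:max_trials]
    elif len(peaks) < max_trials:
        warnings.warn(f"only {len(peaks)} tap trials found (expected {max_trials})")
    # interior boundaries: centre of the (possibly tied) minimum run between
    # adjacent peaks; edge boundaries mirror the adjacent half-trial so the
    # first/last trials get full valley-to-valley durations
    inner = [_valley_center(d, a, b) for a, b in zip(peaks[:-1], peaks[1:])]
    first = max(0.0, 2 * peaks[0] - inner[0])
    last = min(len(d) - 1.0, 2 * peaks[-1] - inner[-1])
    bounds = [first] + inner + [last]
    trials = []
    for i, p in enumerate(peaks):
        trials.append(TapTrial(start=float(np.interp(bounds[i], np.arange(len(t)), t)),
                               end=float(np.interp(bounds[i + 1], np.arange(len(t)), t)),
                               peak_time=float(t[p]), peak_amplitude=float(d[p])))
    return trials


def _valley_center(d, a, b, tol=1e-12):
    """Centre index (float) of the run of minimal samples in d[a:b]."""
    seg = d[a:b + 1]
    m = seg.min()
    idx = np.flatnonzero(seg <= m + tol)
    return a + float(idx.mean())


def tap_features(signal: TapSignal, trials: list,
                 tremor_prominence: float = 0.02,
                 hesitation_rel_prominence: float = 0.05,
                 velocity_cutoff: float = 5.0) -> TapFeatureVector:
    """The eight tapping features from a normalised signal and its trials.

    tremors counts *all* local maxima of d(t) with prominence >= 0.02 over the
    acquisition (each tap's main peak included, so tremors >= n trials);
    hesitations counts local maxima of |d'(t)| (central differences after a
    5 Hz low-pass) with prominence >= 5% of the peak speed; periodicity is the
    height of the first non-zero-lag peak of the unbiased normalised
    autocorrelation (1 = perfectly periodic); AxF averages peak amplitude over
    trial duration.
    """
    if len(trials) < 2:
        raise CannotSegmentError("need at least 2 trials")
    durations = np.array([tr.duration for tr in trials])
    amplitudes = np.array([tr.peak_amplitude for tr in trials])
    d = signal.d
    tremor_peaks, _ = find_peaks(d, prominence=tremor_prominence)
    vel = np.gradient(lowpass(d, signal.sample_rate, velocity_cutoff), signal.t)
    speed = np.abs(vel)
    hes_peaks, _ = find_peaks(speed, prominence=hesitation_rel_prominence * speed.max())
    # periodicity over the trial-covering span only: rest before the first and
    # after the last tap is protocol dead time, not part of the rhythm
    span = (signal.t >= trials[0].start) & (signal.t <= trials[-1].end)
    core = TapSignal(t=signal.t[span], d=d[span], kind=signal.kind,
                     sample_rate=signal.sample_rate)
    return TapFeatureVector(
        meanTime=float(durations.mean()),
        varTime=float(durations.var()),
        meanAmplitude=float(amplitudes.mean()),
        varAmplitude=float(amplitudes.var()),
        tremors=int(len(tremor_peaks)),
        hesitations=int(len(hes_peaks)),
        periodicity=periodicity(core),
        AxF=float(np.mean(amplitudes / durations)),
    )


def periodicity(signal: TapSignal, max_lag_fraction: float = 0.5) -> float:
    """First-peak height of the unbiased normalised autocorrelation of d(t).

    The lag axis is restricted to half the record so the unbiased estimator
    stays stable; the result is clipped to [0, 1].  A perfectly periodic
    signal scores 1.
    """
    x = signal.d - signal.d.mean()
    n = len(x)
    full = np.correlate(x, x, mode="full")[n - 1:]
    lags = np.arange(n)
    max_lag = max(3, int(max_lag_fraction * n))
    ac = full[:max_lag] / (n - lags[:max_lag])
    if ac[0] <= 0:
        return 0.0
    ac = ac / ac[0]
    peaks, props = find_peaks(ac, prominence=0.05)
    if len(peaks) == 0:
        return 0.0
    return float(np.clip(ac[peaks[0]], 0.0, 1.0))


def extract_tap_features(signal: TapSignal, **kwargs) -> TapFeatureVector:
    """Convenience: segment trials then compute the eight features."""
    trials = segment_trials(signal)
    return tap_features(signal, trials, **kwargs)
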