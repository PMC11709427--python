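"""Skeleton-level behavioural features, QC, stimulus windows, well aggregation.

Operates on midline skeletons (ordered head-to-tail coordinates in µm plus a
per-point width profile).  The minimal named feature set covers the three
axes a tracking assay reports on — morphology (length, width), posture (body
curvature) and motion (centroid speed, motion-mode fractions) — including
the core triplet used for screen hit calling: curvature, speed and fraction
of paused worms during blue-light stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .synthetic_data import StimulusSchedule, Track, TrackSet

__all__ = [
    "Skeleton",
    "QCThresholds",
    "WindowSpec",
    "skeleton_length",
    "skeleton_width",
    "skeleton_curvature",
    "track_lengths",
    "track_curvatures",
    "centroid_speed",
    "signed_speed",
    "motion_mode",
    "qc_filter",
    "window_frames",
    "window_features",
    "track_features",
    "aggregate_well",
    "PAUSE_THRESHOLD_UM_S",
    "feature_manifest",
]

#: |signed speed| below this (µm/s) counts as paused.
PAUSE_THRESHOLD_UM_S = 10.0


@dataclass(frozen=True)
class Skeleton:
    """A single-frame midline: points (P, 2) µm head-to-tail, widths (P,) µm."""

    points: np.ndarray
    widths: np.ndarray | None = None
    frame_index: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("skeleton needs >= 3 (x, y) points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("skeleton coordinates must be finite")
        object.__setattr__(self, "points", pts)
        if self.widths is not None:
            w = np.asarray(self.widths, dtype=float)
            if w.shape != (pts.shape[0],) or np.any(w < 0):
                raise ValueError("widths must be per-point and non-negative")
            object.__setattr__(self, "widths", w)


@dataclass(frozen=True)
class QCThresholds:
    """Skeleton retention gates (inclusive bounds), in micrometres."""

    min_length: float = 700.0
    max_length: float = 1300.0
    min_width: float = 20.0
    max_width: float = 200.0

    def __post_init__(self) -> None:
        if not (self.min_length < self.max_length and self.min_width < self.max_width):
            raise ValueError("QC thresholds require min < max")


@dataclass(frozen=True)
class WindowSpec:
    """Stimulus-locked analysis windows.

    Windows of ``window_width`` seconds centred ``offsets`` seconds from each
    pulse start: defaults −5 / +10 / +20 s, i.e. [t0−10, t0], [t0+5, t0+15]
    and [t0+15, t0+25] for pulse start t0.
    """

    offsets: tuple[float, ...] = (-5.0, 10.0, 20.0)
    window_width: float = 10.0

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")


# --------------------------------------------------------------------------- #
# per-skeleton geometry
# --------------------------------------------------------------------------- #

def skeleton_length(points: np.ndarray | Skeleton) -> float:
    """Arc length: sum of inter-point Euclidean segment lengths (µm).

    Returns NaN for degenerate inputs (< 2 points).
    """
    pts = points.points if isinstance(points, Skeleton) else np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        return float("nan")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def skeleton_width(widths: np.ndarray | Skeleton) -> float:
    """Representative body width: mean over the middle third of the profile."""
    w = widths.widths if isinstance(widths, Skeleton) else np.asarray(widths, float)
    if w is None or w.size < 3:
        return float("nan")
    third = w.size // 3
    return float(w[third:w.size - third].mean())


def skeleton_curvature(points: np.ndarray | Skeleton,
                       smooth_sigma: float = 1.0) -> tuple[np.ndarray, float]:
    """Per-point curvature (rad/µm) and mean absolute curvature.

    Curvature is the derivative of the tangent angle with respect to arc
    length on a lightly Gaussian-smoothed midline (sigma in points).  Points
    coincident with their neighbours yield NaN and are excluded from the
    summary.
    """
    pts = points.points if isinstance(points, Skeleton) else np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] < 5:
        raise ValueError("curvature requires >= 5 points")
    if smooth_sigma > 0:
        pts = gaussian_filter1d(pts, smooth_sigma, axis=0, mode="nearest")
    d = np.gradient(pts, axis=0)
    ds = np.linalg.norm(d, axis=1)
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.gradient(theta) / ds
    kappa = np.where(ds > 0, kappa, np.nan)
    # endpoints use one-sided differences and bias the summary; trim them
    inner = kappa[2:-2]
    valid = np.isfinite(inner)
    mean_abs = float(np.abs(inner[valid]).mean()) if valid.any() else float("nan")
    return kappa, mean_abs


def track_lengths(coords: np.ndarray) -> np.ndarray:
    """Per-frame arc lengths for a (T, P, 2) coordinate array."""
    return np.linalg.norm(np.diff(coords, axis=1), axis=2).sum(axis=1)


def track_curvatures(coords: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Per-frame mean |curvature| for a (T, P, 2) coordinate array."""
    pts = gaussian_filter1d(coords, smooth_sigma, axis=1, mode="nearest") \
        if smooth_sigma > 0 else coords
    d = np.gradient(pts, axis=1)
    ds = np.linalg.norm(d, axis=2)
    theta = np.unwrap(np.arctan2(d[..., 1], d[..., 0]), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.gradient(theta, axis=1) / ds
    kappa = np.where(ds > 0, kappa, np.nan)[:, 2:-2]
    return np.nanmean(np.abs(kappa), axis=1)


# --------------------------------------------------------------------------- #
# motion
# --------------------------------------------------------------------------- #

def centroid_speed(coords: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Per-frame centroid speed (µm/s); first frame repeats the second.

    ``coords`` is (T, P, 2); ``times`` must be strictly increasing.
    """
    times = np.asarray(times, float)
    if coords.shape[0] < 2:
        raise ValueError("speed requires >= 2 frames")
    if np.any(np.diff(times) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    c = coords.mean(axis=1)
    v = np.linalg.norm(np.diff(c, axis=0), axis=1) / np.diff(times)
    return np.concatenate([[v[0]], v])


def signed_speed(coords: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Centroid speed signed by head-ward projection (head = point 0).

    Positive when the centroid moves toward the head, negative when it
    retreats from it.
    """
    times = np.asarray(times, float)
    c = coords.mean(axis=1)
    head = coords[:, 0, :]
    u = head - c
    norm = np.linalg.norm(u, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(norm > 0, u / norm, 0.0)
    dv = np.diff(c, axis=0) / np.diff(times)[:, None]
    speed = np.linalg.norm(dv, axis=1)
    sign = np.sign(np.einsum("ij,ij->i", dv, u[:-1]))
    s = speed * np.where(sign == 0, 1.0, sign)
    return np.concatenate([[s[0]], s])


def motion_mode(signed: np.ndarray,
                pause_threshold: float = PAUSE_THRESHOLD_UM_S
                ) -> tuple[np.ndarray, dict[str, float]]:
    """Per-frame labels {forward, paused, backward} and their fractions.

    Paused means |signed speed| below ``pause_threshold``; the three
    fractions sum to 1.
    """
    signed = np.asarray(signed, float)
    labels = np.where(np.abs(signed) < pause_threshold, "paused",
                      np.where(signed > 0, "forward", "backward"))
    n = len(labels)
    fr = {m: float((labels == m).sum()) / n for m in ("forward", "paused", "backward")}
    return labels, fr


# --------------------------------------------------------------------------- #
# QC
# --------------------------------------------------------------------------- #

def qc_filter(skeletons: Iterable[Skeleton] | Track,
              thresholds: QCThresholds = QCThresholds()
              ) -> tuple[np.ndarray, dict[str, int]]:
    """Skeleton retention mask under the length/width gates (inclusive).

    Accepts a :class:`Track` (per-frame mask) or an iterable of
    :class:`Skeleton`.  Returns (mask, log) where log counts retained and
    rejected skeletons by cause.
    """
    if isinstance(skeletons, Track):
        lengths = track_lengths(skeletons.coords)
        widths = np.apply_along_axis(skeleton_width, 1, skeletons.widths)
    else:
        sk = list(skeletons)
        lengths = np.array([skeleton_length(s) for s in sk])
        widths = np.array([skeleton_width(s) if s.widths is not None else np.nan
                           for s in sk])
    ok_len = (lengths >= thresholds.min_length) & (lengths <= thresholds.max_length)
    ok_wid = (widths >= thresholds.min_width) & (widths <= thresholds.max_width)
    mask = ok_len & ok_wid
    log = {
        "n_total": int(mask.size),
        "n_retained": int(mask.sum()),
        "n_rejected_length": int((~ok_len).sum()),
        "n_rejected_width": int((~ok_wid).sum()),
    }
    return mask, log


# --------------------------------------------------------------------------- #
# stimulus windows
# --------------------------------------------------------------------------- #

def window_frames(pulse_start_s: float, spec: WindowSpec, frame_rate: float,
                  n_frames: int | None = None) -> list[tuple[int, int]]:
    """Frame ranges [f0, f1) of each analysis window around one pulse.

    Times are relative to the start of the recording the pulse belongs to.
    For a pulse at 60 s at 25 fps the defaults give (1250, 1500),
    (1625, 1875) and (1875, 2125).  Ranges are clipped to the recording.
    """
    out = []
    for off in spec.offsets:
        t0 = pulse_start_s + off - spec.window_width / 2.0
        t1 = pulse_start_s + off + spec.window_width / 2.0
        f0 = int(round(t0 * frame_rate))
        f1 = int(round(t1 * frame_rate))
        if n_frames is not None:
            f0, f1 = max(f0, 0), min(f1, n_frames)
        out.append((f0, f1))
    return out


def _summarise(coords, widths, times, qc_mask, pause_threshold) -> dict[str, float]:
    feats: dict[str, float] = {}
    if qc_mask.sum() >= 1:
        feats["length_mean"] = float(track_lengths(coords[qc_mask]).mean())
        feats["width_mean"] = float(np.mean(
            [skeleton_width(w) for w in widths[qc_mask]]))
    else:
        feats["length_mean"] = feats["width_mean"] = float("nan")
    if qc_mask.sum() >= 1 and coords.shape[1] >= 5:
        feats["curvature_mean"] = float(np.nanmean(track_curvatures(coords[qc_mask])))
    else:
        feats["curvature_mean"] = float("nan")
    if coords.shape[0] >= 2:
        sgn = signed_speed(coords, times)
        feats["speed_mean"] = float(np.abs(sgn).mean())
        _, fr = motion_mode(sgn, pause_threshold)
        feats["fraction_forward"] = fr["forward"]
        feats["fraction_paused"] = fr["paused"]
        feats["fraction_backward"] = fr["backward"]
    else:
        for k in ("speed_mean", "fraction_forward", "fraction_paused",
                  "fraction_backward"):
            feats[k] = float("nan")
    return feats


def window_features(track: Track, schedule: StimulusSchedule,
                    spec: WindowSpec = WindowSpec(),
                    thresholds: QCThresholds = QCThresholds(),
                    pause_threshold: float = PAUSE_THRESHOLD_UM_S
                    ) -> dict[str, float]:
    """Blue-light window features, averaged over the pulses.

    Feature names gain a ``_w{k}`` suffix for the k-th window (1-based:
    pre-pulse, during/after-pulse, post-pulse).
    """
    qc_mask, _ = qc_filter(track, thresholds)
    blue0 = schedule.period_start("bluelight")
    n_frames = track.coords.shape[0]
    per_window: dict[str, list[float]] = {}
    for t0 in schedule.pulse_starts:
        frames = window_frames(blue0 + t0, spec, schedule.frame_rate, n_frames)
        for k, (f0, f1) in enumerate(frames, start=1):
            if f1 - f0 < 2:
                continue
            sl = slice(f0, f1)
            feats = _summarise(track.coords[sl], track.widths[sl],
                               track.times[sl], qc_mask[sl], pause_threshold)
            for name, val in feats.items():
                per_window.setdefault(f"{name}_w{k}", []).append(val)
    return {k: float(np.nanmean(v)) for k, v in per_window.items()}


def track_features(track: Track, schedule: StimulusSchedule,
                   thresholds: QCThresholds = QCThresholds(),
                   window_spec: WindowSpec | None = WindowSpec(),
                   pause_threshold: float = PAUSE_THRESHOLD_UM_S
                   ) -> dict[str, dict[str, float]]:
    """Per-period feature dictionaries for one track.

    Returns {period: {feature: value}}; the bluelight period additionally
    carries window-tagged variants when ``window_spec`` is given.
    """
    qc_mask, _ = qc_filter(track, thresholds)
    labels = schedule.period_of(track.times)
    out: dict[str, dict[str, float]] = {}
    for period in schedule.periods:
        sel = labels == period
        if sel.sum() < 2:
            continue
        feats = _summarise(track.coords[sel], track.widths[sel],
                           track.times[sel], qc_mask[sel], pause_threshold)
        if period == "bluelight" and window_spec is not None:
            feats.update(window_features(track, schedule, window_spec,
                                         thresholds, pause_threshold))
        out[period] = feats
    return out


def aggregate_well(per_track: Sequence[Mapping[str, float]]
                   ) -> dict[str, float]:
    """Collapse track-level features to one well vector by unweighted mean.

    Zero tracks yields an empty dict (the well should be flagged upstream).
    NaN entries are ignored per feature; a feature undefined in every track
    stays NaN.
    """
    if not per_track:
        return {}
    names: list[str] = []
    for d in per_track:
        for k in d:
            if k not in names:
                names.append(k)
    out = {}
    for name in names:
        vals = np.array([d.get(name, np.nan) for d in per_track], float)
        out[name] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return out


def feature_manifest(names: Sequence[str], period: str | None = None) -> dict:
    """Manifest entries (units, period, window tag) for the named features."""
    units = {
        "length_mean": "um", "width_mean": "um", "curvature_mean": "rad/um",
        "speed_mean": "um/s", "fraction_forward": "1", "fraction_paused": "1",
        "fraction_backward": "1",
    }
    manifest = {}
    for name in names:
        base = name
        window = None
        if "_w" in name and name.rsplit("_w", 1)[-1].isdigit():
            base, wtag = name.rsplit("_w", 1)
            window = int(wtag)
        manifest[name] = {
            "units": units.get(base, "a.u."),
            "period": period,
            "window": window,
        }
    return manifest
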