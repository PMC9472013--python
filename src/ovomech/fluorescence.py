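"""Cortical-granule exocytosis quantification from fluorescence images.

FITC-LCA binds the alpha-mannose residues released into the perivitelline
space (PVS) during cortical-granule exocytosis, so the PVS appears as a ring
whose intensity tracks the instantaneous release. Quantification follows the
line-profile procedure: draw line profiles across the cell, integrate the
background-subtracted area under the PVS peak, average five profiles per
cell per timepoint, and normalize longitudinal series to their first value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import profile_line

__all__ = [
    "LineProfile",
    "PvsSignal",
    "extract_profile",
    "pvs_peak_area",
    "find_peak_window",
    "aggregate_signal",
    "normalize_series",
    "stack_cg_series",
    "detect_onset",
]

MIN_PROFILE_SAMPLES = 32


@dataclass
class LineProfile:
    """Intensity profile along a line (positions in µm, intensities in ADU)."""

    s: np.ndarray
    I: np.ndarray
    p0: tuple[float, float]  # (row, col) image coordinates
    p1: tuple[float, float]

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if len(self.s) != len(self.I):
            raise ValueError("s and I must have equal length")
        if len(self.s) < MIN_PROFILE_SAMPLES:
            raise ValueError(f"profile needs >= {MIN_PROFILE_SAMPLES} samples")
        if np.any(self.I < 0):
            raise ValueError("intensities must be >= 0")


@dataclass
class PvsSignal:
    """Background-subtracted PVS peak area (ADU·µm), possibly replicate-averaged."""

    area: float
    background_level: float  # ADU
    n_profiles: int = 1
    t: float | None = None  # acquisition time (h or min, caller's convention)
    se: float = 0.0  # standard error over replicate profiles


def extract_profile(
    image: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    pixel_size: float = 1.0,
) -> LineProfile:
    """Bilinear line profile between two (row, col) points, <= 1 px spacing."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be single-channel 2-D")
    for p in (p0, p1):
        if not (0 <= p[0] <= img.shape[0] - 1 and 0 <= p[1] <= img.shape[1] - 1):
            raise ValueError(f"endpoint {p} outside image of shape {img.shape}")
    vals = profile_line(img, p0, p1, order=1, mode="reflect")
    length_px = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
    s = np.linspace(0.0, length_px * pixel_size, len(vals))
    return LineProfile(s=s, I=np.clip(vals, 0.0, None), p0=tuple(p0), p1=tuple(p1))


def pvs_peak_area(
    profile: LineProfile,
    window: tuple[float, float],
    flank_fraction: float = 0.25,
    t: float | None = None,
) -> PvsSignal:
    """Background-subtracted area under the PVS peak within ``window``.

    Background is the median of the flanking samples (the nearest
    ``flank_fraction`` of each side); the area is the clipped excess
    intensity integrated over the window, floored at 0.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    inside = (profile.s >= lo) & (profile.s <= hi)
    if inside.all() or not inside.any():
        raise ValueError("window must be a strict interior subset of the profile")
    left = np.flatnonzero(profile.s < lo)
    right = np.flatnonzero(profile.s > hi)
    if len(left) == 0 or len(right) == 0:
        raise ValueError("flanking samples required on both sides of the window")
    n_l = max(int(np.ceil(flank_fraction * len(left))), 1)
    n_r = max(int(np.ceil(flank_fraction * len(right))), 1)
    flank = np.concatenate([profile.I[left[-n_l:]], profile.I[right[:n_r]]])
    background = float(np.median(flank))
    s_in, i_in = profile.s[inside], profile.I[inside]
    excess = np.clip(i_in - background, 0.0, None)
    ds = np.gradient(s_in) if len(s_in) > 1 else np.array([0.0])
    area = max(float(np.sum(excess * ds)), 0.0)
    return PvsSignal(area=area, background_level=background, n_profiles=1, t=t)


def find_peak_window(
    profile: LineProfile, flank_fraction: float = 0.25, k_sd: float = 2.0
) -> tuple[float, float]:
    """Default window: widest interior run with I > background + k_sd × flank SD."""
    n = len(profile.I)
    n_f = max(int(flank_fraction * n), 4)
    flank = np.concatenate([profile.I[:n_f], profile.I[-n_f:]])
    bg, sd = float(np.median(flank)), float(np.std(flank))
    above = profile.I > bg + k_sd * max(sd, 1e-12)
    above[0] = above[-1] = False
    best = None
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            if best is None or (i - start) > (best[1] - best[0]):
                best = (start, i)
            start = None
    if best is None:
        raise ValueError("no interior peak found above background")
    i0, i1 = best
    return float(profile.s[max(i0 - 1, 0)]), float(profile.s[min(i1, n - 1)])


def aggregate_signal(signals: list[PvsSignal], t: float | None = None) -> PvsSignal:
    """Average single-profile areas from one cell and timepoint (target n=5)."""
    if len(signals) == 0:
        raise ValueError("empty list of profile signals")
    areas = np.array([s.area for s in signals], dtype=float)
    se = float(areas.std(ddof=1) / np.sqrt(len(areas))) if len(areas) > 1 else 0.0
    return PvsSignal(
        area=float(areas.mean()),
        background_level=float(np.mean([s.background_level for s in signals])),
        n_profiles=len(signals),
        t=t if t is not None else signals[0].t,
        se=se,
    )


def normalize_series(values) -> np.ndarray:
    """Divide a longitudinal series by its first value (first element -> 1.0).

    Accepts an array of numbers or a list of :class:`PvsSignal`.
    """
    if len(values) and isinstance(values[0], PvsSignal):
        values = [v.area for v in values]
    arr = np.asarray(values, dtype=float)
    if len(arr) == 0:
        raise ValueError("empty series")
    if not arr[0] > 0:
        raise ValueError("first value must be > 0 for normalization")
    return arr / arr[0]


def _centroid(image: np.ndarray) -> tuple[float, float]:
    img = np.clip(np.asarray(image, dtype=float) - np.median(image), 0.0, None)
    total = img.sum()
    if total <= 0:
        return ((image.shape[0] - 1) / 2.0, (image.shape[1] - 1) / 2.0)
    rows = np.arange(image.shape[0])
    cols = np.arange(image.shape[1])
    return (float((img.sum(axis=1) @ rows) / total), float((img.sum(axis=0) @ cols) / total))


def stack_cg_series(
    stack: np.ndarray,
    pixel_size: float,
    times=None,
    n_profiles: int = 5,
    center: tuple[float, float] | None = None,
    window: tuple[float, float] | None = None,
) -> list[PvsSignal]:
    """PVS signal per frame of an image stack.

    For each frame, ``n_profiles`` radial lines at equally spaced angles are
    drawn from the cell centroid to the image border, the PVS peak area of
    each is computed, and the replicates are averaged. The peak window is
    located once on the first frame (the cell does not move between frames)
    and reused.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    n_frames, n_rows, n_cols = stack.shape
    if center is None:
        center = _centroid(stack[0])
    radius = 0.9 * min(center[0], center[1], n_rows - 1 - center[0], n_cols - 1 - center[1])
    angles = np.linspace(0.0, 2.0 * np.pi, n_profiles, endpoint=False)
    ends = [
        (center[0] + radius * np.sin(a), center[1] + radius * np.cos(a)) for a in angles
    ]
    if window is None:
        prof0 = extract_profile(stack[0], center, ends[0], pixel_size)
        window = find_peak_window(prof0)
    out: list[PvsSignal] = []
    for i in range(n_frames):
        t_i = None if times is None else float(times[i])
        sigs = [
            pvs_peak_area(extract_profile(stack[i], center, e, pixel_size), window)
            for e in ends
        ]
        out.append(aggregate_signal(sigs, t=t_i))
    return out


def detect_onset(series: list[PvsSignal] | np.ndarray, n_baseline: int = 5, k_sd: float = 3.0) -> int:
    """First frame where the aggregated signal exceeds baseline mean + k_sd × SD.

    The baseline is the first ``n_baseline`` frames. Returns the frame index,
    or raises if the series never rises.
    """
    if len(series) and isinstance(series[0], PvsSignal):
        series = np.array([s.area for s in series])
    arr = np.asarray(series, dtype=float)
    base = arr[:n_baseline]
    thresh = base.mean() + k_sd * max(base.std(ddof=1), 1e-12)
    hits = np.flatnonzero(arr > thresh)
    hits = hits[hits >= n_baseline]
    if len(hits) == 0:
        raise ValueError("no onset detected above baseline")
    return int(hits[0])
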