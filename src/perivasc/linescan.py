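"""Diameter extraction from x-t linescan stacks.

Replaces the interactive threshold tool used on the original recordings
with a programmatic equivalent: thresholds are given as (time, value)
control points linearly interpolated across the scan (constant beyond the
ends), or derived automatically per frame from robust background and
foreground percentiles.  Edges are the outermost threshold crossings of
each frame's intensity profile, localized to sub-sample precision by
linear interpolation; frames with no crossing are flagged missing and
never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from perivasc.synth import LinescanStack


@dataclass
class ThresholdSpec:
    """Threshold control points for one channel.

    ``control_points`` is a list of (t_s, threshold) pairs ordered in
    time; the per-frame threshold is their linear interpolation with
    constant extrapolation beyond the first/last point.
    """

    channel: str  # "red" | "green"
    control_points: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.control_points:
            raise ValueError("at least one threshold control point required")
        ts = [t for t, _ in self.control_points]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("control points must be ordered in time")

    def thresholds(self, t: np.ndarray) -> np.ndarray:
        ts = np.array([p[0] for p in self.control_points])
        vs = np.array([p[1] for p in self.control_points])
        return np.interp(t, ts, vs)


@dataclass
class EdgeTrace:
    """Left/right edge positions (um) and diameter per frame."""

    t: np.ndarray
    left_edge: np.ndarray
    right_edge: np.ndarray
    diameter: np.ndarray
    missing: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.t,
            "left_um": self.left_edge,
            "right_um": self.right_edge,
            "diameter_um": self.diameter,
            "missing": self.missing,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def downsample_factors(fs: float, dx: float, fs_target: float = 100.0,
                       density_target: float = 20.0, k_max: int = 100
                       ) -> tuple[int, int]:
    """Integer block sizes bringing fs toward ``fs_target`` Hz and the
    spatial density toward ``density_target`` samples/um.

    Each factor minimizes the absolute deviation of the downsampled rate
    from the target over k = 1..k_max; ties break toward the smaller
    factor.
    """
    def best(rate: float, target: float) -> int:
        ks = np.arange(1, k_max + 1)
        err = np.abs(rate / ks - target)
        return int(ks[np.argmin(err)])  # argmin takes first -> smaller k

    return best(fs, fs_target), best(1.0 / dx, density_target)


def _block_mean(a: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Non-overlapping block means of size k along axis (remainder dropped)."""
    if k == 1:
        return a
    n = (a.shape[axis] // k) * k
    a = np.take(a, np.arange(n), axis=axis)
    shape = list(a.shape)
    shape[axis:axis + 1] = [n // k, k]
    return a.reshape(shape).mean(axis=axis + 1)


def spatiotemporal_downsample(stack: LinescanStack,
                              fs_target: float = 100.0,
                              density_target: float = 20.0) -> LinescanStack:
    """Block-average the stack toward 100 Hz and 20 samples/um."""
    k_t, k_x = downsample_factors(stack.fs, stack.dx, fs_target,
                                  density_target)
    if k_t == 1 and k_x == 1:
        return stack
    red = _block_mean(_block_mean(stack.red, k_x, axis=0), k_t, axis=1)
    green = _block_mean(_block_mean(stack.green, k_x, axis=0), k_t, axis=1)
    truth = None
    if stack.truth is not None:
        truth = {k: _block_mean(np.asarray(v, dtype=float), k_t, axis=0)
                 for k, v in stack.truth.items()}
    return LinescanStack(red=red, green=green, dx=stack.dx * k_x,
                         fs=stack.fs / k_t, truth=truth)


def auto_threshold_spec(stack: LinescanStack, channel: str = "red",
                        lo_pct: float = 10.0, hi_pct: Optional[float] = None,
                        n_points: int = 9) -> ThresholdSpec:
    """Automated default thresholds: per-window half-maximum between
    robust background and foreground percentiles.

    The foreground percentile defaults to 90 for the red channel (the
    dextran-filled lumen covers a large fraction of the scan) and 99 for
    the green channel, whose two thin endfoot bands cover only a few
    percent of the scan line.
    """
    if hi_pct is None:
        hi_pct = 90.0 if channel == "red" else 99.0
    img = getattr(stack, channel)
    n_t = img.shape[1]
    t = np.arange(n_t) / stack.fs
    idx = np.linspace(0, n_t - 1, min(n_points, n_t)).astype(int)
    pts = []
    for i in idx:
        w0, w1 = max(0, i - 50), min(n_t, i + 50)
        win = img[:, w0:w1]
        # initial split from robust percentiles, then refine on each side
        # of the split: the background median is immune to the noise bias
        # of extreme percentiles; the foreground quantile compensates for
        # the flank samples included in the above-split set (the thin
        # green bands are mostly flank, so they need a higher quantile)
        thr0 = 0.5 * (np.percentile(win, lo_pct)
                      + np.percentile(win, hi_pct))
        fg_q = 75.0 if channel == "red" else 90.0
        bg = np.median(win[win < thr0])
        fg = np.percentile(win[win >= thr0], fg_q)
        pts.append((float(t[i]), float(0.5 * (bg + fg))))
    return ThresholdSpec(channel=channel, control_points=pts)


def trace_edges(stack: LinescanStack, spec: ThresholdSpec) -> EdgeTrace:
    """Outermost threshold crossings per frame, sub-sample interpolated.

    For the red channel the bright dextran core gives one above-threshold
    run whose outer flanks are the lumen edges; for the green channel the
    outermost crossings of the two flanking endfoot bands bound the
    endfoot tube.  Both reduce to the outermost crossings of the
    thresholded profile.  Frames with no crossing are flagged missing.
    """
    img = np.asarray(getattr(stack, spec.channel), dtype=float)
    n_x, n_t = img.shape
    t = np.arange(n_t) / stack.fs
    thr = spec.thresholds(t)
    x = (np.arange(n_x) - (n_x - 1) / 2) * stack.dx

    above = img >= thr[None, :]
    any_above = above.any(axis=0)
    # outermost above-threshold samples
    first = np.argmax(above, axis=0)
    last = n_x - 1 - np.argmax(above[::-1, :], axis=0)

    left = np.full(n_t, np.nan)
    right = np.full(n_t, np.nan)
    cols = np.nonzero(any_above)[0]
    for j in cols:
        i0, i1 = first[j], last[j]
        left[j] = _cross_left(x, img[:, j], i0, thr[j])
        right[j] = _cross_right(x, img[:, j], i1, thr[j])
    missing = ~any_above
    diameter = right - left
    return EdgeTrace(t=t, left_edge=left, right_edge=right,
                     diameter=diameter, missing=missing)


def _cross_left(x: np.ndarray, prof: np.ndarray, i: int, thr: float) -> float:
    """Sub-sample position of the rising crossing at the left flank of i."""
    if i == 0:
        return x[0]
    y0, y1 = prof[i - 1], prof[i]
    if y1 == y0:
        return x[i]
    frac = (thr - y0) / (y1 - y0)
    return x[i - 1] + frac * (x[i] - x[i - 1])


def _cross_right(x: np.ndarray, prof: np.ndarray, i: int, thr: float) -> float:
    """Sub-sample position of the falling crossing at the right flank of i."""
    if i == len(x) - 1:
        return x[-1]
    y0, y1 = prof[i], prof[i + 1]
    if y1 == y0:
        return x[i]
    frac = (thr - y0) / (y1 - y0)
    return x[i] + frac * (x[i + 1] - x[i])


@dataclass
class PVSWidth:
    """Total and per-side PVS widths with a QC flag for negative values."""

    t: np.ndarray
    total: np.ndarray
    left: np.ndarray
    right: np.ndarray
    missing: np.ndarray
    negative_flag: bool


def compute_pvs_width(lumen: EdgeTrace, endfoot: EdgeTrace) -> PVSWidth:
    """PVS width = endfoot diameter - lumen diameter, plus per-side widths.

    Negative values are retained but flagged for QC; frames missing in
    either trace are missing in the output.
    """
    if len(lumen.t) != len(endfoot.t) or not np.allclose(lumen.t, endfoot.t):
        raise ValueError("lumen and endfoot traces must share a time base")
    total = endfoot.diameter - lumen.diameter
    left = lumen.left_edge - endfoot.left_edge
    right = endfoot.right_edge - lumen.right_edge
    missing = lumen.missing | endfoot.missing
    valid = total[~missing]
    negative = bool(np.any(valid < 0))
    return PVSWidth(t=lumen.t.copy(), total=total, left=left, right=right,
                    missing=missing, negative_flag=negative)
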