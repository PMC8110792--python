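"""Neurite length summaries and time-lapse extension-rate estimation.

Fixed-culture outgrowth is summarized as the mean of the twenty longest
neurites per neurosphere. Live outgrowth is estimated from leading-edge
positions sampled at fixed intervals (5 min by default): per-interval
displacements are summed and converted to µm/hr, with single very large
retractions capped at 30 µm per interval so one catastrophic retraction
does not dominate the estimate. When a treatment time is annotated, pre-
and post-treatment rates are computed separately and their ratio reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stripe_guidance import NeuriteTrace


@dataclass
class TimeLapseTrack:
    """Leading-edge positions of one neurite over time.

    ``positions`` is either a 1-D array (µm along the growth axis) or an
    (n, 2) array of (x, y) µm coordinates. Times must be strictly
    increasing; intervals need not be uniform.
    """

    track_id: int | str
    t_min: np.ndarray
    positions: np.ndarray
    treatment_time_min: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValueError("a track needs at least two frames")
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if p.shape[0] != len(t):
            raise ValueError("positions and times must align")
        if p.ndim not in (1, 2) or (p.ndim == 2 and p.shape[1] != 2):
            raise ValueError("positions must be 1-D or (n, 2)")
        self.t_min = t
        self.positions = p

    @property
    def n_frames(self) -> int:
        return len(self.t_min)


@dataclass
class RateEstimate:
    rate_um_per_hr: float
    n_intervals: int
    capped_intervals: int
    rate_pre: float | None = None
    rate_post: float | None = None
    normalized_rate: float | None = None  # post / pre
    normalization_flag: str | None = None


# --------------------------------------------------------------------------
# Fixed-culture lengths
# --------------------------------------------------------------------------

def measure_neurite_length(trace: NeuriteTrace) -> float:
    """Path length of a traced neurite (sum of consecutive vertex distances)."""
    v = trace.vertices
    return float(np.hypot(np.diff(v[:, 0]), np.diff(v[:, 1])).sum())


def longest_k_summary(
    lengths_by_sphere: pd.DataFrame,
    k: int = 20,
    sphere_col: str = "sphere_id",
    length_col: str = "length_um",
) -> pd.DataFrame:
    """Per-sphere mean of the k longest neurites.

    Spheres with fewer than k neurites contribute the mean of all their
    neurites and are flagged; empty spheres are excluded with a warning.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    rows = []
    for sphere, grp in lengths_by_sphere.groupby(sphere_col, sort=True):
        vals = np.sort(np.asarray(grp[length_col], dtype=float))[::-1]
        if len(vals) == 0:
            warnings.warn(f"sphere {sphere!r} has no neurites: excluded", stacklevel=2)
            continue
        used = vals[:k]
        rows.append(
            {
                sphere_col: sphere,
                "mean_length_um": float(used.mean()),
                "n_neurites": len(vals),
                "n_used": len(used),
                "fewer_than_k": len(vals) < k,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Extension rates
# --------------------------------------------------------------------------

def _project_displacements(p: np.ndarray, window: int = 5) -> np.ndarray:
    """Signed per-interval displacement of 2-D positions along the growth axis.

    The axis for interval i is the first principal (total-least-squares)
    direction of the positions in a rolling window centered on the interval,
    oriented along the track's net displacement.
    """
    n = p.shape[0]
    net = p[-1] - p[0]
    out = np.empty(n - 1)
    half = window // 2
    for i in range(n - 1):
        lo = max(0, i - half + 1)
        hi = min(n, i + half + 1)
        seg = p[lo:hi]
        if seg.shape[0] < 2:
            seg = p[i : i + 2]
        centered = seg - seg.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        if np.dot(axis, net) < 0:
            axis = -axis
        out[i] = float(np.dot(p[i + 1] - p[i], axis))
    return out


def interval_displacements(track: TimeLapseTrack) -> np.ndarray:
    """Signed per-interval displacements (µm); 2-D tracks are projected."""
    p = track.positions
    if p.ndim == 1:
        return np.diff(p)
    return _project_displacements(p)


def extension_rate(
    track: TimeLapseTrack,
    retraction_cap_um: float = 30.0,
) -> RateEstimate:
    """Extension rate in µm/hr with per-interval retraction capping.

    Displacements below ``-retraction_cap_um`` are replaced by the cap value
    (and counted), then summed and divided by the elapsed time. With an
    infinite cap the estimate equals net displacement over elapsed time
    exactly. If the track carries a treatment time, pre- and post-treatment
    rates are estimated on the intervals ending at or before / starting at
    or after it, and ``normalized_rate`` is post/pre.
    """
    d = interval_displacements(track)
    t = track.t_min
    capped = d < -retraction_cap_um
    dc = np.where(capped, -retraction_cap_um, d)
    rate = 60.0 * float(dc.sum()) / float(t[-1] - t[0])
    est = RateEstimate(
        rate_um_per_hr=rate,
        n_intervals=len(d),
        capped_intervals=int(capped.sum()),
    )
    tt = track.treatment_time_min
    if tt is None:
        return est

    pre = t[1:] <= tt      # a prefix of intervals (times are increasing)
    post = t[:-1] >= tt    # a suffix of intervals
    if pre.sum() < 1:
        est.normalization_flag = "pre-treatment window shorter than 2 frames"
        return est
    if post.sum() < 1:
        est.normalization_flag = "no post-treatment intervals"
        return est
    last_pre_end = int(np.flatnonzero(pre)[-1]) + 1
    est.rate_pre = 60.0 * float(dc[pre].sum()) / float(t[last_pre_end] - t[0])
    i0 = int(np.flatnonzero(post)[0])
    est.rate_post = 60.0 * float(dc[post].sum()) / float(t[-1] - t[i0])
    if est.rate_pre == 0:
        est.normalization_flag = "zero pre-treatment rate"
    else:
        est.normalized_rate = est.rate_post / est.rate_pre
    return est


def rates_table(
    tracks: list[TimeLapseTrack],
    retraction_cap_um: float = 30.0,
    conditions: dict | None = None,
) -> pd.DataFrame:
    """Tidy per-track rate table for a list of tracks."""
    rows = []
    for tr in tracks:
        est = extension_rate(tr, retraction_cap_um=retraction_cap_um)
        rows.append(
            {
                "track_id": tr.track_id,
                "condition": (conditions or {}).get(tr.track_id, ""),
                "rate_um_per_hr": est.rate_um_per_hr,
                "n_intervals": est.n_intervals,
                "capped_intervals": est.capped_intervals,
                "rate_pre": est.rate_pre,
                "rate_post": est.rate_post,
                "normalized_rate": est.normalized_rate,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Variance comparison
# --------------------------------------------------------------------------

def variance_comparison(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-sided F-test for equality of variances (ratio var_a / var_b)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator group")
    f = va / vb
    dfn, dfd = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.cdf(f, dfn, dfd), stats.f.sf(f, dfn, dfd))
    return float(f), float(min(p, 1.0))
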