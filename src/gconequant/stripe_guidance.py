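"""Quantification of axon guidance on striped substrata.

Neurospheres plated on alternating lanes of a repulsive cue (plus laminin)
and laminin alone extend radial neurites; guidance is quantified two ways:

* a modified Sholl profile — neurite crossings of concentric circles spaced
  every 10 µm beyond the sphere rim, binned into quadrants whose sectors run
  parallel vs. perpendicular to the stripe direction;
* a substratum-preference score — thresholded neurite area per unit available
  area on cue lanes divided by the same density on laminin-only lanes, so
  1 means no preference and values below 1 mean avoidance of the cue.

Conventions used throughout the package: the canvas origin is the top-left
pixel corner, x runs rightward, y downward, and physical coordinates are
``pixel * scale`` in µm. "Vertical" stripes are lanes that are constant
along y (the lane label varies with x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereGeometry:
    """Neurosphere position: center (x, y) and radius, in µm.

    All radial quantities (Sholl rings, exclusion zones) are measured from
    the sphere *rim*, not its center.
    """

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")


@dataclass
class NeuriteTrace:
    """Ordered polyline of one neurite in µm, first vertex at the sphere rim."""

    trace_id: int | str
    vertices: np.ndarray  # (n, 2) float, columns (x_um, y_um)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("a trace needs at least two (x, y) vertices")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise ValueError("consecutive vertices must be distinct")
        self.vertices = v


@dataclass
class StripePattern:
    """Binary periodic substratum map: cue lanes vs. laminin-only lanes.

    ``orientation`` is the unit vector along the lanes; the lane label varies
    along the perpendicular axis with period ``2 * stripe_width``.
    """

    cue_mask: np.ndarray           # (H, W) bool, True on cue lanes
    orientation: np.ndarray        # (2,) unit vector along lanes
    scale: float                   # µm per pixel
    stripe_width: float | None = None  # µm; None for non-periodic custom maps

    def __post_init__(self) -> None:
        self.cue_mask = np.asarray(self.cue_mask, dtype=bool)
        o = np.asarray(self.orientation, dtype=float)
        n = np.hypot(o[0], o[1])
        if n == 0:
            raise ValueError("orientation vector must be nonzero")
        self.orientation = o / n
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cue_mask.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """Canvas size (width_um, height_um)."""
        h, w = self.cue_mask.shape
        return (w * self.scale, h * self.scale)

    def cue_fraction(self) -> float:
        return float(self.cue_mask.mean())

    def is_cue(self, x_um: float, y_um: float) -> bool:
        """Substratum label at a continuous µm coordinate.

        Periodic patterns are evaluated analytically so points outside the
        rasterized canvas still carry a well-defined label; custom maps fall
        back to a clipped pixel lookup.
        """
        if self.stripe_width is not None:
            ox, oy = self.orientation
            # axis across the lanes: perpendicular to the lane direction
            across = x_um * oy + y_um * (-ox)
            lane = int(np.floor(across / self.stripe_width))
            return lane % 2 == 0
        col = int(np.clip(x_um / self.scale, 0, self.cue_mask.shape[1] - 1))
        row = int(np.clip(y_um / self.scale, 0, self.cue_mask.shape[0] - 1))
        return bool(self.cue_mask[row, col])


@dataclass
class ShollProfile:
    """Quadrant-binned crossing counts per concentric ring.

    ``ring_radii`` are distances from the sphere rim (10, 20, ... µm);
    per ring, parallel + perpendicular equals the total crossing count.
    """

    ring_radii: np.ndarray            # µm beyond the rim
    crossings_parallel: np.ndarray    # int counts per ring
    crossings_perpendicular: np.ndarray

    @property
    def totals(self) -> np.ndarray:
        return self.crossings_parallel + self.crossings_perpendicular


@dataclass
class PreferenceResult:
    """Neurite-area densities on each substratum and their ratio.

    ``normalized_preference`` = (cue area / available cue area) divided by
    (LN area / available LN area); exactly 1 for equal coverage density.
    ``valid`` is False when the laminin density is zero or the analysis
    region contains no laminin pixels (the ratio is then NaN, not an error).
    """

    area_on_cue: float
    area_on_ln: float
    available_cue_area: float
    available_ln_area: float
    normalized_preference: float
    valid: bool = True


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------

def segment_neurites(
    factin_image: np.ndarray,
    scale: float,
    threshold_method: str = "otsu",
    fixed_value: float | None = None,
    min_object_area_um2: float = 5.0,
) -> np.ndarray:
    """Threshold the F-actin channel into a neurite mask.

    Components smaller than ``min_object_area_um2`` are removed. A blank
    (zero-variance) image yields an empty mask with a warning rather than an
    exception, so batch runs survive failed fields.
    """
    img = np.asarray(factin_image, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")
    if img.ndim != 2:
        raise ValueError("expected a single-channel image")
    if np.ptp(img) == 0:
        warnings.warn("zero-variance image: returning empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    if threshold_method == "otsu":
        thr = threshold_otsu(img)
    elif threshold_method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed threshold_method requires fixed_value")
        thr = float(fixed_value)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    mask = img > thr
    min_px = int(np.ceil(min_object_area_um2 / scale**2))
    if min_px > 1:
        # remove components strictly smaller than min_px
        mask = remove_small_objects(mask, max_size=min_px - 1)
    return mask


# --------------------------------------------------------------------------
# Quadrant geometry
# --------------------------------------------------------------------------

def quadrant_is_parallel(
    points: np.ndarray,
    sphere: SphereGeometry,
    stripe_orientation: np.ndarray,
) -> np.ndarray:
    """Label points as lying in a parallel (True) or perpendicular sector.

    The plane around the sphere is split into four 90° sectors by the ±45°
    diagonals relative to the stripe direction through the sphere center. The
    two sectors bisected by the stripe axis are "parallel". Boundaries are
    half-open: a point at exactly +45° from the stripe axis belongs to the
    perpendicular sector, one at −45° to the parallel sector.
    """
    o = np.asarray(stripe_orientation, dtype=float)
    n = np.hypot(o[0], o[1])
    if n == 0:
        raise ValueError("orientation vector must be nonzero")
    p = np.atleast_2d(np.asarray(points, dtype=float))
    vx = p[:, 0] - sphere.center[0]
    vy = p[:, 1] - sphere.center[1]
    theta = np.arctan2(vy, vx)
    phi = np.arctan2(o[1], o[0])
    # fold the angle difference onto the stripe axis: range [-pi/2, pi/2)
    d = np.mod(theta - phi + np.pi / 2, np.pi) - np.pi / 2
    out = (d >= -np.pi / 4) & (d < np.pi / 4)
    return out


def assign_quadrants(sphere: SphereGeometry, stripe_orientation: np.ndarray):
    """Return a vectorized labeling function point(s) -> parallel? bool."""
    o = np.asarray(stripe_orientation, dtype=float)
    if np.hypot(o[0], o[1]) == 0:
        raise ValueError("orientation vector must be nonzero")

    def labeler(points: np.ndarray) -> np.ndarray:
        return quadrant_is_parallel(points, sphere, o)

    return labeler


# --------------------------------------------------------------------------
# Modified Sholl profile
# --------------------------------------------------------------------------

def sholl_quadrant_profile(
    traces: list[NeuriteTrace],
    sphere: SphereGeometry,
    stripe_orientation: np.ndarray,
    ring_spacing: float = 10.0,
    n_rings: int | None = None,
) -> ShollProfile:
    """Count neurite crossings of concentric rings, binned by quadrant.

    Ring k has radius ``sphere.radius + k * ring_spacing``. Each polyline
    segment is intersected with each ring circle exactly (quadratic root
    solving); every transversal intersection with parameter t in [0, 1)
    along the segment counts as one crossing, assigned to the quadrant of
    the intersection point. Tangencies count zero; the half-open t-interval
    means a vertex lying exactly on a ring belongs to the outgoing segment.

    A trace entirely inside the sphere contributes zero crossings.
    """
    if ring_spacing <= 0:
        raise ValueError("ring_spacing must be positive")
    cx, cy = sphere.center
    if n_rings is None:
        rmax = 0.0
        for tr in traces:
            v = tr.vertices
            d = np.hypot(v[:, 0] - cx, v[:, 1] - cy)
            rmax = max(rmax, float(d.max()))
        n_rings = max(0, int(np.floor((rmax - sphere.radius) / ring_spacing)))
    radii = sphere.radius + ring_spacing * np.arange(1, n_rings + 1)
    par = np.zeros(n_rings, dtype=int)
    perp = np.zeros(n_rings, dtype=int)
    if n_rings == 0:
        return ShollProfile(ring_spacing * np.arange(1, 1), par, perp)

    for tr in traces:
        v = tr.vertices
        ax = v[:-1, 0] - cx
        ay = v[:-1, 1] - cy
        dx = np.diff(v[:, 0])
        dy = np.diff(v[:, 1])
        A = dx * dx + dy * dy
        B = 2.0 * (ax * dx + ay * dy)
        C0 = ax * ax + ay * ay
        for k, r in enumerate(radii):
            C = C0 - r * r
            disc = B * B - 4.0 * A * C
            ok = (disc > 0) & (A > 0)
            if not np.any(ok):
                continue
            s = np.sqrt(disc[ok])
            for sign in (-1.0, 1.0):
                t = (-B[ok] + sign * s) / (2.0 * A[ok])
                hit = (t >= 0.0) & (t < 1.0)
                if not np.any(hit):
                    continue
                idx = np.flatnonzero(ok)[hit]
                tt = t[hit]
                px = cx + ax[idx] + tt * dx[idx]
                py = cy + ay[idx] + tt * dy[idx]
                lab = quadrant_is_parallel(
                    np.column_stack([px, py]), sphere, stripe_orientation
                )
                par[k] += int(lab.sum())
                perp[k] += int((~lab).sum())

    return ShollProfile(ring_spacing * np.arange(1, n_rings + 1), par, perp)


# --------------------------------------------------------------------------
# Substratum preference
# --------------------------------------------------------------------------

def substratum_preference(
    neurite_mask: np.ndarray,
    stripes: StripePattern,
    sphere: SphereGeometry,
    exclusion_radius_um: float = 100.0,
    restrict_to_parallel_quadrants: bool = True,
) -> PreferenceResult:
    """Normalized neurite-area preference for cue vs. laminin lanes.

    Analysis is confined to pixels at least ``exclusion_radius_um`` beyond
    the sphere rim, intersected with the parallel quadrants when the flag is
    set. Mask areas on each substratum are divided by the available area of
    that substratum in the region (density correction), and the score is the
    ratio of the two densities, so unequal lane availability does not bias
    the result.
    """
    mask = np.asarray(neurite_mask, dtype=bool)
    if mask.shape != stripes.cue_mask.shape:
        raise ValueError("mask and stripe pattern must share the pixel grid")
    s = stripes.scale
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    xc = (xx + 0.5) * s
    yc = (yy + 0.5) * s
    dist = np.hypot(xc - sphere.center[0], yc - sphere.center[1])
    region = dist >= sphere.radius + exclusion_radius_um
    if restrict_to_parallel_quadrants:
        pts = np.column_stack([xc.ravel(), yc.ravel()])
        par = quadrant_is_parallel(pts, sphere, stripes.orientation)
        region &= par.reshape(h, w)

    px_area = s * s
    cue_avail = region & stripes.cue_mask
    ln_avail = region & ~stripes.cue_mask
    a_cue_avail = cue_avail.sum() * px_area
    a_ln_avail = ln_avail.sum() * px_area
    a_cue = (mask & cue_avail).sum() * px_area
    a_ln = (mask & ln_avail).sum() * px_area

    if a_ln_avail == 0 or a_ln == 0:
        return PreferenceResult(
            a_cue, a_ln, a_cue_avail, a_ln_avail, float("nan"), valid=False
        )
    if a_cue_avail == 0:
        return PreferenceResult(
            a_cue, a_ln, a_cue_avail, a_ln_avail, float("nan"), valid=False
        )
    pref = (a_cue / a_cue_avail) / (a_ln / a_ln_avail)
    return PreferenceResult(a_cue, a_ln, a_cue_avail, a_ln_avail, pref, valid=True)


# --------------------------------------------------------------------------
# Sphere auto-estimation (approximate helper)
# --------------------------------------------------------------------------

def estimate_sphere(factin_image: np.ndarray, scale: float) -> SphereGeometry:
    """Approximate the neurosphere as the largest bright blob's enclosing circle.

    Intended for runs without an annotated sphere; the estimate is marked
    approximate by construction (centroid + maximum boundary distance) and
    should be replaced by a curated geometry whenever one exists.
    """
    img = np.asarray(factin_image, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("cannot estimate sphere from a zero-variance image")
    mask = img > threshold_otsu(img)
    lab = cc_label(mask)
    if lab.max() == 0:
        raise ValueError("no foreground found")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    blob = lab == sizes.argmax()
    ys, xs = np.nonzero(blob)
    cx = (xs.mean() + 0.5) * scale
    cy = (ys.mean() + 0.5) * scale
    r = np.hypot((xs + 0.5) * scale - cx, (ys + 0.5) * scale - cy).max()
    return SphereGeometry(center=(cx, cy), radius=float(r))
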