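"""Growth-cone segmentation, ROI fluorescence, filopodia, and collapse calls.

A spread growth cone has a flat lamellipodial veil with filopodia radiating
from its rim; after an inhibitory cue the veil disassembles, leaving a thin
shaft with at most a couple of short filopodia. Collapse is scored by a
deterministic morphometric rule: veil area at or below a minimum AND no more
than two filopodia AND every filopodium shorter than 10 µm. All three
sub-criteria are carried on each call so alternate rules can be recomputed
without re-segmenting.

Fluorescence quantification follows the standard masked-ROI recipe: the ROI
is a thresholded F-actin mask, the immunolabel channel is averaged inside
it, and a background estimate (median of a surrounding annulus, or a global
low percentile) is subtracted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk, opening, skeletonize

# Analysis-eligibility distances (µm): growth cones closer than this to the
# neurosphere rim are excluded from all assays; local-protein-synthesis
# intensity runs additionally require growth cones far from their cell bodies.
MIN_GROWTHCONE_DISTANCE_UM = 100.0
MIN_LPS_DISTANCE_UM = 300.0


@dataclass
class Filopodium:
    length_um: float
    base: tuple[float, float]  # (x_um, y_um)


@dataclass
class GrowthConeSegmentation:
    veil_mask: np.ndarray
    veil_area_um2: float
    filopodia: list[Filopodium]
    shaft_axis: np.ndarray  # (2,) unit vector, major axis of the mask
    scale: float

    @property
    def n_filopodia(self) -> int:
        return len(self.filopodia)

    @property
    def max_filopodium_length_um(self) -> float:
        return max((f.length_um for f in self.filopodia), default=0.0)


@dataclass
class IntensityMeasurement:
    mean_intensity: float      # background-subtracted mean inside the mask
    background: float
    mask_area_um2: float
    raw_mean: float
    clipped: bool = False      # True if the subtracted mean was floored at 0
    normalized_value: float | None = None


@dataclass
class CollapseCall:
    collapsed: bool
    veil_area_um2: float
    n_filopodia: int
    max_filopodium_length_um: float


# --------------------------------------------------------------------------
# Masking and intensity
# --------------------------------------------------------------------------

def make_factin_mask(
    factin_image: np.ndarray,
    scale: float,
    threshold_method: str = "otsu",
    fixed_value: float | None = None,
    min_object_area_um2: float = 2.0,
) -> np.ndarray:
    """Growth-cone ROI: largest thresholded component, holes filled."""
    img = np.asarray(factin_image, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")
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
    lab = cc_label(mask)
    if lab.max() == 0:
        return np.zeros(img.shape, dtype=bool)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    if sizes.max() < min_px:
        return np.zeros(img.shape, dtype=bool)
    mask = lab == sizes.argmax()
    return ndimage.binary_fill_holes(mask)


def measure_roi_intensity(
    label_image: np.ndarray,
    roi_mask: np.ndarray,
    scale: float,
    background_mode: str = "annulus",
    annulus_width_um: float = 2.0,
    global_percentile: float = 5.0,
) -> IntensityMeasurement:
    """Mean immunolabel intensity inside the ROI minus a background estimate.

    ``annulus`` mode takes the median in a ring formed by dilating the ROI by
    ``annulus_width_um``; ``global_percentile`` takes a low percentile of the
    whole field. The subtracted mean is floored at zero with a flag.
    """
    img = np.asarray(label_image, dtype=float)
    mask = np.asarray(roi_mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("label image and ROI mask must share the pixel grid")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    raw_mean = float(img[mask].mean())
    if background_mode == "annulus":
        r = max(1, int(round(annulus_width_um / scale)))
        ring = dilation(mask, disk(r)) & ~mask
        if not ring.any():  # ROI fills the field
            bg = 0.0
        else:
            bg = float(np.median(img[ring]))
    elif background_mode == "global_percentile":
        bg = float(np.percentile(img, global_percentile))
    else:
        raise ValueError(f"unknown background_mode {background_mode!r}")
    val = raw_mean - bg
    clipped = val < 0
    if clipped:
        val = 0.0
    return IntensityMeasurement(
        mean_intensity=val,
        background=bg,
        mask_area_um2=float(mask.sum()) * scale**2,
        raw_mean=raw_mean,
        clipped=clipped,
    )


def normalize_to_control(
    measurements: pd.DataFrame,
    control_label: str,
    value_col: str = "value",
    condition_col: str = "condition",
    out_col: str = "normalized_value",
) -> pd.DataFrame:
    """Divide every value by the control-group mean (control mean becomes 1)."""
    if condition_col not in measurements or value_col not in measurements:
        raise ValueError("measurements must carry value and condition columns")
    ctrl = measurements.loc[measurements[condition_col] == control_label, value_col]
    if ctrl.empty:
        raise ValueError(f"control condition {control_label!r} has no rows")
    m = float(ctrl.mean())
    if m <= 0:
        raise ValueError("control-group mean must be positive")
    out = measurements.copy()
    out[out_col] = out[value_col] / m
    return out


# --------------------------------------------------------------------------
# Skeleton branch machinery
# --------------------------------------------------------------------------

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_adjacency(skel: np.ndarray) -> dict[tuple[int, int], list[tuple[int, int]]]:
    pts = set(zip(*np.nonzero(skel)))
    adj: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pts}
    for (r, c) in pts:
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if q in pts:
                adj[(r, c)].append(q)
    return adj


def _skeleton_branches(skel: np.ndarray) -> list[list[tuple[int, int]]]:
    """Decompose a skeleton into simple branches (endpoint/junction to next).

    Branches are walked from degree-1 endpoints through degree-2 chains until
    a junction (degree >= 3) or another endpoint. Each endpoint-to-endpoint
    path is reported once. Pure cycles (no endpoints) are ignored: they do
    not occur for filopodium-like structures.
    """
    adj = _skeleton_adjacency(skel)
    endpoints = [p for p, nb in adj.items() if len(nb) == 1]
    isolated = [p for p, nb in adj.items() if len(nb) == 0]
    branches: list[list[tuple[int, int]]] = [[p] for p in isolated]
    seen_edges: set[frozenset] = set()
    for e in endpoints:
        if not adj[e]:
            continue
        first = adj[e][0]
        if frozenset((e, first)) in seen_edges:
            continue
        path = [e]
        prev, cur = e, first
        seen_edges.add(frozenset((e, first)))
        while True:
            path.append(cur)
            nbs = adj[cur]
            if len(nbs) != 2:  # junction or endpoint
                break
            nxt = nbs[0] if nbs[0] != prev else nbs[1]
            seen_edges.add(frozenset((cur, nxt)))
            prev, cur = cur, nxt
        branches.append(path)
    return branches


def _path_length_um(path: list[tuple[int, int]], scale: float) -> float:
    total = 0.0
    for (r0, c0), (r1, c1) in zip(path[:-1], path[1:]):
        total += math.hypot(r1 - r0, c1 - c0)
    return total * scale


def _mask_major_axis(mask: np.ndarray) -> np.ndarray:
    ys, xs = np.nonzero(mask)
    if len(xs) < 2:
        return np.array([1.0, 0.0])
    pts = np.column_stack([xs - xs.mean(), ys - ys.mean()]).astype(float)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    v = vt[0]
    return v / np.hypot(v[0], v[1])


# --------------------------------------------------------------------------
# Filopodia extraction and collapse classification
# --------------------------------------------------------------------------

def extract_filopodia(
    mask: np.ndarray,
    scale: float,
    r_open_um: float = 1.5,
    min_filopodium_um: float = 1.0,
    border_margin_um: float = 2.5,
    veil_contact_um: float = 1.0,
) -> GrowthConeSegmentation:
    """Split a growth-cone mask into a veil and individual filopodia.

    The veil is the morphological opening of the mask by a disk of radius
    ``r_open_um`` (thin protrusions are removed); filopodia are skeleton
    branches of the residual (mask minus veil). When a veil exists, a branch
    must touch the veil boundary (within ``veil_contact_um``) to count; with
    no veil, residual branches near the shaft tip count instead. Branches
    with a free end within ``border_margin_um`` of the image border are
    treated as the axon shaft entering the field, not filopodia, and branches shorter than ``min_filopodium_um`` are pruned as
    skeletonization spurs. Filopodium length is the geodesic skeleton length.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return GrowthConeSegmentation(
            veil_mask=np.zeros_like(mask),
            veil_area_um2=0.0,
            filopodia=[],
            shaft_axis=np.array([1.0, 0.0]),
            scale=scale,
        )
    border_margin_px = max(1, int(round(border_margin_um / scale)))
    r_px = max(1, int(round(r_open_um / scale)))
    veil = opening(mask, disk(r_px))
    veil_area = float(veil.sum()) * scale**2
    residual = mask & ~veil
    skel = skeletonize(residual)
    h, w = mask.shape

    if veil.any():
        contact_px = max(1, int(round(veil_contact_um / scale))) + 1
        veil_zone = dilation(veil, disk(contact_px))
    else:
        veil_zone = None

    adj = _skeleton_adjacency(skel)
    filopodia: list[Filopodium] = []
    for path in _skeleton_branches(skel):
        # free ends = degree <= 1 nodes of this branch
        free_ends = [p for p in (path[0], path[-1]) if len(adj.get(p, [])) <= 1]
        if not free_ends:
            continue
        on_border = any(
            r < border_margin_px or c < border_margin_px
            or r >= h - border_margin_px or c >= w - border_margin_px
            for (r, c) in free_ends
        )
        if on_border:
            continue  # axon shaft entering the field
        if veil_zone is not None and not any(veil_zone[r, c] for r, c in path):
            continue
        length = _path_length_um(path, scale)
        if length < min_filopodium_um:
            continue
        # base = branch end nearest the veil (or the non-free end)
        if veil_zone is not None:
            base_px = min(
                (path[0], path[-1]),
                key=lambda p: 0 if veil_zone[p[0], p[1]] else 1,
            )
        else:
            non_free = [p for p in (path[0], path[-1]) if p not in free_ends]
            base_px = non_free[0] if non_free else path[0]
        base = ((base_px[1] + 0.5) * scale, (base_px[0] + 0.5) * scale)
        filopodia.append(Filopodium(length_um=length, base=base))

    return GrowthConeSegmentation(
        veil_mask=veil,
        veil_area_um2=veil_area,
        filopodia=filopodia,
        shaft_axis=_mask_major_axis(mask),
        scale=scale,
    )


def classify_collapse(
    seg: GrowthConeSegmentation,
    veil_min_area_um2: float = 5.0,
    filopodia_max_count: int = 2,
    filopodia_max_length_um: float = 10.0,
) -> CollapseCall:
    """Rule-based collapse call.

    Collapsed requires all three: veil area at or below ``veil_min_area_um2``
    (veil disassembled), at most ``filopodia_max_count`` filopodia, and every
    filopodium strictly shorter than ``filopodia_max_length_um``.
    """
    n = seg.n_filopodia
    mx = seg.max_filopodium_length_um
    collapsed = (
        seg.veil_area_um2 <= veil_min_area_um2
        and n <= filopodia_max_count
        and mx < filopodia_max_length_um
    )
    return CollapseCall(
        collapsed=collapsed,
        veil_area_um2=seg.veil_area_um2,
        n_filopodia=n,
        max_filopodium_length_um=mx,
    )


def classify_collapse_image(
    factin_image: np.ndarray,
    scale: float,
    **kwargs,
) -> CollapseCall:
    """Convenience: mask -> filopodia -> collapse call from a raw image."""
    seg_kwargs = {
        k: kwargs.pop(k)
        for k in ("r_open_um", "min_filopodium_um", "border_margin_um", "veil_contact_um")
        if k in kwargs
    }
    mask = make_factin_mask(factin_image, scale)
    seg = extract_filopodia(mask, scale, **seg_kwargs)
    return classify_collapse(seg, **kwargs)


def collapse_table(
    calls: pd.DataFrame,
    condition_col: str = "condition",
    collapsed_col: str = "collapsed",
) -> pd.DataFrame:
    """Per-condition collapse counts and percentages (feeds the stats module).

    Returns one row per condition with columns ``n``, ``collapsed``,
    ``not_collapsed`` and ``percent_collapsed``. Conditions with zero calls
    cannot arise from a groupby; callers passing an explicit category list
    should drop empty conditions beforehand.
    """
    if calls.empty:
        raise ValueError("no collapse calls provided")
    rows = []
    for cond, grp in calls.groupby(condition_col, sort=True):
        n = len(grp)
        c = int(grp[collapsed_col].sum())
        rows.append(
            {
                condition_col: cond,
                "n": n,
                "collapsed": c,
                "not_collapsed": n - c,
                "percent_collapsed": 100.0 * c / n,
            }
        )
    return pd.DataFrame(rows)


def filter_eligible(
    manifest: pd.DataFrame,
    distance_col: str = "distance_from_sphere_um",
    min_distance_um: float = MIN_GROWTHCONE_DISTANCE_UM,
) -> pd.DataFrame:
    """Drop growth cones closer to the neurosphere than the eligibility cutoff.

    Use ``min_distance_um=MIN_LPS_DISTANCE_UM`` for local-protein-synthesis
    intensity runs, which require growth cones far from their cell bodies.
    """
    if distance_col not in manifest:
        raise ValueError(f"manifest lacks column {distance_col!r}")
    return manifest.loc[manifest[distance_col] >= min_distance_um].copy()


def skeleton_to_polylines(mask: np.ndarray, scale: float) -> list[np.ndarray]:
    """Optional utility: skeletonize a mask and return branch polylines in µm.

    Provided for exploratory use only; crossing counts in this package are
    defined on traced polylines, and this conversion is not validated as a
    substitute for tracing.
    """
    skel = skeletonize(np.asarray(mask, dtype=bool))
    out = []
    for path in _skeleton_branches(skel):
        if len(path) < 2:
            continue
        arr = np.array([[(c + 0.5) * scale, (r + 0.5) * scale] for r, c in path])
        out.append(arr)
    return out
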