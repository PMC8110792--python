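"""Acceptor-photobleaching FRET efficiency and G-LISA fold activity.

FRET efficiency of a donor/acceptor biosensor is estimated by donor
dequenching: bleach the acceptor (YFP) in a region of interest and compare
donor (CFP) emission before and after. With background-subtracted ROI means
I_pre and I_post, the efficiency estimator is

    E = 1 - I_pre / I_post,

which recovers the true efficiency exactly when the acceptor is fully
bleached. The raw pre/post means and the achieved acceptor bleach fraction
are always reported, and a result is marked invalid (not an error) when the
bleach was too incomplete for the estimator to be meaningful.

G-LISA plate absorbances are corrected for protein loading (absorbance per
mg/mL) and expressed as fold activity relative to the mean of a control
condition, whose mean fold is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.morphology import dilation, disk


@dataclass
class FRETPair:
    """Congruent donor/acceptor image pairs around an acceptor bleach."""

    donor_pre: np.ndarray
    donor_post: np.ndarray
    acceptor_pre: np.ndarray
    acceptor_post: np.ndarray
    bleach_roi: np.ndarray  # bool mask of the bleached region
    scale: float            # µm per pixel

    def __post_init__(self) -> None:
        shape = np.asarray(self.donor_pre).shape
        for name in ("donor_post", "acceptor_pre", "acceptor_post", "bleach_roi"):
            if np.asarray(getattr(self, name)).shape != shape:
                raise ValueError("all images and the ROI must be congruent")
        self.bleach_roi = np.asarray(self.bleach_roi, dtype=bool)
        if not self.bleach_roi.any():
            raise ValueError("bleach ROI is empty")


@dataclass
class EfficiencyResult:
    efficiency: float
    donor_pre_mean: float
    donor_post_mean: float
    acceptor_bleach_fraction: float
    valid: bool
    invalid_reason: str | None = None


def _roi_background(img: np.ndarray, roi: np.ndarray, scale: float,
                    mode: str, annulus_width_um: float = 2.0) -> float:
    if mode == "none":
        return 0.0
    if mode == "annulus":
        r = max(1, int(round(annulus_width_um / scale)))
        ring = dilation(roi, disk(r)) & ~roi
        if not ring.any():
            return 0.0
        return float(np.median(img[ring]))
    if mode == "global_percentile":
        return float(np.percentile(img, 5.0))
    raise ValueError(f"unknown background_mode {mode!r}")


def fret_efficiency(
    pair: FRETPair,
    min_bleach_fraction: float = 0.7,
    background_mode: str = "annulus",
) -> EfficiencyResult:
    """Donor-dequenching FRET efficiency over the bleach ROI.

    Background-subtracted donor means inside the ROI give
    E = 1 - pre/post; the acceptor bleach fraction is
    1 - acceptor_post/acceptor_pre over the same ROI. The result is invalid
    (rather than raising) when the bleach fraction falls below
    ``min_bleach_fraction`` or the post-bleach donor mean is nonpositive.
    Noise can carry the estimate slightly below 0 for a non-transferring
    sensor; such values are reported as-is so group means stay unbiased.
    """
    roi = pair.bleach_roi
    d_pre = np.asarray(pair.donor_pre, dtype=float)
    d_post = np.asarray(pair.donor_post, dtype=float)
    a_pre = np.asarray(pair.acceptor_pre, dtype=float)
    a_post = np.asarray(pair.acceptor_post, dtype=float)

    pre = float(d_pre[roi].mean()) - _roi_background(d_pre, roi, pair.scale, background_mode)
    post = float(d_post[roi].mean()) - _roi_background(d_post, roi, pair.scale, background_mode)
    ap = float(a_pre[roi].mean()) - _roi_background(a_pre, roi, pair.scale, background_mode)
    apost = float(a_post[roi].mean()) - _roi_background(a_post, roi, pair.scale, background_mode)

    if ap <= 0:
        bleach = float("nan")
    else:
        bleach = 1.0 - apost / ap

    if post <= 0:
        return EfficiencyResult(float("nan"), pre, post, bleach, False,
                                "nonpositive post-bleach donor signal")
    e = 1.0 - pre / post
    if not np.isfinite(bleach) or bleach < min_bleach_fraction:
        return EfficiencyResult(e, pre, post, bleach, False,
                                "acceptor bleach below minimum fraction")
    return EfficiencyResult(e, pre, post, bleach, True)


def glisa_fold_activity(
    plate: pd.DataFrame,
    control_condition: str,
    absorbance_col: str = "absorbance",
    protein_col: str = "protein_conc",
    condition_col: str = "condition",
) -> pd.DataFrame:
    """Protein-normalized fold activity relative to a control condition.

    Each absorbance is divided by its sample's protein concentration
    (loading correction), then by the mean protein-corrected absorbance of
    the control condition. The control-condition mean fold is exactly 1, and
    the result is invariant to the global absorbance unit.
    """
    for col in (absorbance_col, protein_col, condition_col):
        if col not in plate:
            raise ValueError(f"plate lacks column {col!r}")
    if (plate[protein_col] <= 0).any():
        raise ValueError("protein concentrations must be positive")
    if (plate[absorbance_col] < 0).any():
        raise ValueError("absorbances must be nonnegative")
    ctrl = plate[plate[condition_col] == control_condition]
    if ctrl.empty:
        raise ValueError(f"control condition {control_condition!r} has no rows")
    out = plate.copy()
    out["corrected"] = out[absorbance_col] / out[protein_col]
    denom = float(out.loc[out[condition_col] == control_condition, "corrected"].mean())
    if denom <= 0:
        raise ValueError("control-condition corrected absorbance mean must be positive")
    out["fold_activity"] = out["corrected"] / denom
    return out
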