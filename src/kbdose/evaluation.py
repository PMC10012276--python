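"""Quantitative evaluation of predicted dose maps.

Voxel metrics are expressed as percent of prescription dose: for one case
and one region of interest,

    ME  = mean_i (D_pred(i) - D_gt(i)) / Rx * 100
    MAE = mean_i |D_pred(i) - D_gt(i)| / Rx * 100

and cohort values average the per-case values (unweighted over cases, not
pooled over voxels).  With two prescription levels the denominator Rx is
ambiguous; the default policy uses the boost prescription (69.96 Gy) for
the body, whole normal tissue and organs at risk, and each target's own
prescription for target metrics.  This choice rescales every percentage
and is therefore configurable.

Isodose agreement uses the Dice similarity coefficient of the volumes
receiving at least a dose level (``>=``, a closed lower bound):

    DSC_level = 2 |A ∩ B| / (|A| + |B|),   A = {pred >= level}, B = {gt >= level}

evaluated on the 1..60 Gy range with the 5..55 Gy (5 Gy step) + 60 Gy
subset used for statistics.  When both isodose volumes are empty the DSC
is defined as 1.0 (perfect agreement on absence) and flagged.

DVH curves are cumulative (fraction of the structure receiving at least
each dose), from which the mean dose and Dx% (minimum dose to the hottest
x% of the volume, x = 5 by convention) are read.  Model pairs are compared
with two-sided paired t-tests; p < 0.05 is the conventional significance
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import DoseMap, ROISet

__all__ = [
    "mean_error",
    "mean_absolute_error",
    "isodose_dsc",
    "dsc_curve",
    "DSC_STAT_LEVELS_GY",
    "dvh",
    "dose_at_volume",
    "mean_dose",
    "paired_comparison",
    "DVHCurve",
    "PairedResult",
    "prescription_for",
    "case_voxel_metrics",
    "cohort_report",
]

#: isodose levels extracted for statistics: 5..55 Gy in 5 Gy steps plus the
#: 60 Gy prescription level (12 levels)
DSC_STAT_LEVELS_GY: tuple[float, ...] = tuple(float(v) for v in range(5, 60, 5)) + (60.0,)


def _masked(pred: DoseMap, gt: DoseMap, mask: np.ndarray):
    pred.require_same_grid(gt, "dose pair")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pred.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {pred.shape}")
    if not mask.any():
        raise ValueError("empty evaluation mask")
    return pred.values[mask], gt.values[mask]


def mean_error(pred: DoseMap, gt: DoseMap, mask: np.ndarray, prescription: float) -> float:
    """Signed voxel mean error over ``mask``, percent of ``prescription``."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    p, g = _masked(pred, gt, mask)
    return float(np.mean(p - g) / prescription * 100.0)


def mean_absolute_error(pred: DoseMap, gt: DoseMap, mask: np.ndarray, prescription: float) -> float:
    """Voxel mean absolute error over ``mask``, percent of ``prescription``."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    p, g = _masked(pred, gt, mask)
    return float(np.mean(np.abs(p - g)) / prescription * 100.0)


@dataclass(frozen=True)
class IsodoseDSC:
    level_gy: float
    dsc: float
    both_empty: bool = False


def isodose_dsc(pred: DoseMap, gt: DoseMap, level: float) -> IsodoseDSC:
    """Dice coefficient of the two isodose volumes at ``level`` Gy."""
    if level <= 0:
        raise ValueError("isodose level must be positive")
    pred.require_same_grid(gt, "dose pair")
    a = pred.values >= level
    b = gt.values >= level
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return IsodoseDSC(level, 1.0, both_empty=True)
    return IsodoseDSC(level, 2.0 * int((a & b).sum()) / (na + nb))


def dsc_curve(pred: DoseMap, gt: DoseMap, levels=None) -> list[IsodoseDSC]:
    """DSC at each level; default 1..60 Gy in 1 Gy steps."""
    if levels is None:
        levels = np.arange(1.0, 61.0)
    return [isodose_dsc(pred, gt, float(lv)) for lv in levels]


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure.

    ``edges_gy[k]`` -> ``volume_pct[k]`` = percent of the structure
    receiving at least ``edges_gy[k]``; starts at 100% at 0 Gy and falls
    to 0% above the maximum dose.
    """

    edges_gy: np.ndarray
    volume_pct: np.ndarray
    roi_name: str = ""
    bin_width_gy: float = 0.1


def dvh(dose: DoseMap, mask: np.ndarray, bin_width: float = 0.1, roi_name: str = "") -> DVHCurve:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ValueError("mask shape does not match dose grid")
    if not mask.any():
        raise ValueError("empty DVH mask")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = dose.values[mask]
    top = float(d.max())
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    # fraction receiving >= edge; vectorized via the sorted sample
    ds = np.sort(d)
    frac = 1.0 - np.searchsorted(ds, edges, side="left") / d.size
    return DVHCurve(edges, frac * 100.0, roi_name=roi_name, bin_width_gy=bin_width)


def dose_at_volume(curve: DVHCurve, x: float) -> float:
    """Dx%: the largest dose received by at least x% of the structure.

    Linearly interpolated inside the bin where the cumulative curve crosses
    ``x``; exact to within one bin width.
    """
    if not (0 < x < 100):
        raise ValueError("x must be in (0, 100)")
    v = np.asarray(curve.volume_pct, dtype=float)
    e = np.asarray(curve.edges_gy, dtype=float)
    if v.size != e.size or v.size < 1 or np.any(np.diff(v) > 1e-9):
        raise ValueError("malformed DVH curve")
    above = np.nonzero(v >= x)[0]
    if above.size == 0:
        return float(e[0])
    i = above[-1]
    if i + 1 >= v.size or v[i] <= v[i + 1]:
        return float(e[i])
    frac = (v[i] - x) / (v[i] - v[i + 1])
    return float(e[i] + frac * (e[i + 1] - e[i]))


def mean_dose(dose: DoseMap, mask: np.ndarray) -> float:
    """Arithmetic mean dose (Gy) over the mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.shape:
        raise ValueError("mask shape does not match dose grid")
    if not mask.any():
        raise ValueError("empty mask")
    return float(dose.values[mask].mean())


@dataclass(frozen=True)
class PairedResult:
    mean_difference: float
    p_value: float
    n: int
    degenerate: bool = False


def paired_comparison(values_a, values_b) -> PairedResult:
    """Two-sided paired t-test on per-case differences (a - b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        # identical-difference degenerate case: the t statistic is 0/0
        return PairedResult(float(diff.mean()), 1.0, a.size, degenerate=True)
    t = stats.ttest_rel(a, b)
    return PairedResult(float(diff.mean()), float(t.pvalue), a.size)


# ---------------------------------------------------------------------------
# cohort-level reporting


def prescription_for(roi_name: str, rois: ROISet, policy: str = "boost") -> float:
    """Denominator for voxel metrics of one ROI under the given policy.

    ``"boost"`` (default): the boost prescription everywhere except targets,
    which use their own prescription.  ``"ptv"``: the PTV-level prescription
    for non-targets instead.
    """
    if roi_name in rois.prescriptions_gy:
        return rois.prescriptions_gy[roi_name]
    ordered = [rois.prescriptions_gy[t] for t in rois.targets]
    if policy == "boost":
        return max(ordered)
    if policy == "ptv":
        return min(ordered)
    raise ValueError(f"unknown denominator policy {policy!r}")


def _eval_regions(rois: ROISet) -> dict[str, np.ndarray]:
    regions = {"Body": rois.body_mask, "NormalTissue": rois.normal_tissue()}
    for name in rois.targets + rois.oars:
        m = rois.masks[name]
        if m.any():
            regions[name] = m
    return regions


def case_voxel_metrics(
    pred: DoseMap, gt: DoseMap, rois: ROISet, policy: str = "boost"
) -> pd.DataFrame:
    """ME/MAE for body, whole normal tissue and every ROI of one case."""
    rows = []
    for name, mask in _eval_regions(rois).items():
        rx = prescription_for(name, rois, policy)
        rows.append(
            {
                "roi": name,
                "prescription_gy": rx,
                "me_pct": mean_error(pred, gt, mask, rx),
                "mae_pct": mean_absolute_error(pred, gt, mask, rx),
            }
        )
    return pd.DataFrame(rows)


def case_dosimetric_parameters(
    pred: DoseMap, gt: DoseMap, rois: ROISet, bin_width: float = 0.1
) -> pd.DataFrame:
    """Mean dose and D5% per OAR, predicted vs ground truth."""
    rows = []
    for name in rois.oars:
        mask = rois.masks[name]
        if not mask.any():
            continue
        row = {"roi": name}
        for tag, dm in (("pred", pred), ("gt", gt)):
            curve = dvh(dm, mask, bin_width, roi_name=name)
            row[f"mean_dose_{tag}_gy"] = mean_dose(dm, mask)
            row[f"d5_{tag}_gy"] = dose_at_volume(curve, 5.0)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_report(per_case: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean +/- SD of ME/MAE over cases, one row per ROI."""
    if not per_case:
        raise ValueError("no case metrics to aggregate")
    allc = pd.concat(per_case, keys=range(len(per_case)), names=["case"]).reset_index(level=0)
    out = (
        allc.groupby("roi", sort=False)
        .agg(
            n=("me_pct", "size"),
            me_mean_pct=("me_pct", "mean"),
            me_sd_pct=("me_pct", "std"),
            mae_mean_pct=("mae_pct", "mean"),
            mae_sd_pct=("mae_pct", "std"),
        )
        .reset_index()
    )
    return out.fillna({"me_sd_pct": 0.0, "mae_sd_pct": 0.0})
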