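"""Tumor vs non-tumor contrast statistics on signed DOP images.

Three quantifications are provided:

* unit-area frequency histograms per class and their overlapping coefficient
  (0 = total separation, 1 = total overlap);
* a pixel-level ROC curve over a fixed threshold sweep (default -0.95 to
  +0.95 in steps of 0.05) with trapezoidal AUC and a seeded, stratified
  bootstrap percentile confidence interval;
* per-class mean/SD summaries of the signed metrics plus the per-pixel total
  DOP magnitude ``(|DOLP| + |DOCP|)/2``.

Threshold orientation: a pixel counts as a positive call when its value is
strictly above the threshold (ties go to the negative side).  AUC below 0.5
is reported as-is, never flipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .polarimetry import DOPImage, total_dop_magnitude
from .segmentation import RegionMask

__all__ = [
    "RegionHistograms",
    "OverlapResult",
    "ROCResult",
    "RegionSummary",
    "region_histograms",
    "overlap_area",
    "roc_curve",
    "auc",
    "auc_ci",
    "region_summary",
]

_EDGE_EPS = 1e-9


def _class_values(dop: DOPImage, mask: RegionMask, exclude: np.ndarray | None = None):
    if dop.values.shape != mask.mask.shape:
        raise ValueError("mask and DOP image disagree on shape")
    keep = dop.valid_mask.copy()
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    tumor = dop.values[keep & mask.mask]
    nontumor = dop.values[keep & ~mask.mask]
    if tumor.size == 0:
        raise ValueError("tumor class is empty (no valid pixels inside the mask)")
    if nontumor.size == 0:
        raise ValueError("non-tumor class is empty (no valid pixels outside the mask)")
    return tumor, nontumor


@dataclass
class RegionHistograms:
    """Per-class unit-area histograms over shared bin edges."""

    bin_edges: np.ndarray
    tumor_density: np.ndarray
    nontumor_density: np.ndarray
    n_tumor: int
    n_nontumor: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class OverlapResult:
    overlap_area: float
    bin_width: float


@dataclass
class ROCResult:
    """Threshold sweep with per-threshold confusion counts and trapezoid AUC."""

    thresholds: np.ndarray
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    points: np.ndarray  # (n+2, 2) of (1-specificity, sensitivity), anchored
    auc: float
    auc_ci: tuple[float, float] | None = None
    ci_method: str | None = None


@dataclass
class RegionSummary:
    """Per-metric, per-class mean/SD/n plus total-DOP magnitude means."""

    stats: dict = field(default_factory=dict)  # stats[metric][class] = {mean, sd, n}
    dop_total: dict = field(default_factory=dict)  # dop_total[class] = mean |DOPtotal|


def _density(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # normalize by the counted total so the area is exactly 1 even if a few
    # flagged values fall outside the edge span after clipping
    clipped = np.clip(values, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    width = edges[1] - edges[0]
    return counts / (counts.sum() * width)


def region_histograms(
    dop: DOPImage,
    mask: RegionMask,
    bins: int = 80,
    exclude: np.ndarray | None = None,
) -> RegionHistograms:
    """Unit-area histograms of valid tumor and non-tumor pixels.

    Fixed edges span [-1-eps, +1+eps] so boundary values +-1 are counted;
    each density integrates to exactly 1 over the bins.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    tumor, nontumor = _class_values(dop, mask, exclude)
    edges = np.linspace(-1.0 - _EDGE_EPS, 1.0 + _EDGE_EPS, bins + 1)
    return RegionHistograms(
        bin_edges=edges,
        tumor_density=_density(tumor, edges),
        nontumor_density=_density(nontumor, edges),
        n_tumor=int(tumor.size),
        n_nontumor=int(nontumor.size),
    )


def overlap_area(h: RegionHistograms) -> OverlapResult:
    """Overlapping coefficient: ``sum_bins min(d_T, d_N) * bin_width``."""
    if h.tumor_density.shape != h.nontumor_density.shape:
        raise ValueError("histograms disagree on bin count")
    ovl = float(np.sum(np.minimum(h.tumor_density, h.nontumor_density)) * h.bin_width)
    return OverlapResult(overlap_area=min(ovl, 1.0), bin_width=h.bin_width)


def _threshold_grid(step: float) -> np.ndarray:
    n = int(round(2.0 / step)) - 1
    # round to exact decimals so ties at nominal thresholds resolve correctly
    return np.round(np.linspace(-1.0 + step, 1.0 - step, n), 12)


def _counts_above(values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """For each threshold t, the number of values strictly greater than t."""
    # bin index i = number of thresholds < v, so count(v > t_k) sums bins > k
    idx = np.searchsorted(thresholds, values, side="left")
    binned = np.bincount(idx, minlength=len(thresholds) + 1)
    above = np.cumsum(binned[::-1])[::-1]
    return above[1:]


def _sweep_curve(above_t: np.ndarray, n_t: int, above_n: np.ndarray, n_n: int):
    sens = above_t / n_t
    spec = 1.0 - above_n / n_n
    pts = np.column_stack([1.0 - spec, sens])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    return sens, spec, pts[order]


def auc(roc: ROCResult) -> float:
    """Trapezoidal area under the anchored (1-specificity, sensitivity) points."""
    return float(np.trapezoid(roc.points[:, 1], roc.points[:, 0]))


def roc_curve(
    dop: DOPImage,
    mask: RegionMask,
    step: float = 0.05,
    exclude: np.ndarray | None = None,
) -> ROCResult:
    """Pixel-level ROC over the fixed interior threshold grid.

    With the default step of 0.05 the grid is -0.95, -0.90, ..., +0.95 (39
    thresholds).  At each threshold TP counts tumor pixels strictly above it,
    TN non-tumor pixels at or below it; the curve is anchored at (0, 0) and
    (1, 1) and integrated with the trapezoid rule.
    """
    if not (0.0 < step < 1.0):
        raise ValueError("step must lie in (0, 1)")
    tumor, nontumor = _class_values(dop, mask, exclude)
    thresholds = _threshold_grid(step)
    tp = _counts_above(tumor, thresholds)
    fp = _counts_above(nontumor, thresholds)
    fn = tumor.size - tp
    tn = nontumor.size - fp
    sens, spec, pts = _sweep_curve(tp, tumor.size, fp, nontumor.size)
    result = ROCResult(
        thresholds=thresholds,
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=sens,
        specificity=spec,
        points=pts,
        auc=0.0,
    )
    result.auc = auc(result)
    return result


def auc_ci(
    dop: DOPImage,
    mask: RegionMask,
    n_boot: int = 1000,
    seed: int = 0,
    step: float = 0.05,
    exclude: np.ndarray | None = None,
) -> tuple[float, float]:
    """95% percentile bootstrap interval for the threshold-sweep AUC.

    The bootstrap resamples pixels with replacement, stratified by class.
    Because the sweep AUC depends on pixel values only through the counts in
    the threshold intervals, each replicate's counts are drawn directly as a
    multinomial over those intervals — distributionally identical to
    resampling raw pixels, and fast at any pixel count.  Deterministic for a
    given seed.
    """
    tumor, nontumor = _class_values(dop, mask, exclude)
    if tumor.size < 10 or nontumor.size < 10:
        raise ValueError("both classes need >= 10 pixels for a bootstrap CI")
    thresholds = _threshold_grid(step)
    rng = np.random.default_rng(seed)

    def bin_counts(values):
        idx = np.searchsorted(thresholds, values, side="left")
        return np.bincount(idx, minlength=len(thresholds) + 1)

    ct = bin_counts(tumor)
    cn = bin_counts(nontumor)
    rep_t = rng.multinomial(tumor.size, ct / tumor.size, size=n_boot)
    rep_n = rng.multinomial(nontumor.size, cn / nontumor.size, size=n_boot)
    # counts strictly above threshold k = sum of interval bins with index > k
    above_t = np.cumsum(rep_t[:, ::-1], axis=1)[:, ::-1][:, 1:]
    above_n = np.cumsum(rep_n[:, ::-1], axis=1)[:, ::-1][:, 1:]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        _, _, pts = _sweep_curve(above_t[b], tumor.size, above_n[b], nontumor.size)
        aucs[b] = np.trapezoid(pts[:, 1], pts[:, 0])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def _moments(values: np.ndarray) -> dict:
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "n": int(values.size),
    }


def region_summary(
    dolp: DOPImage,
    docp: DOPImage,
    mask: RegionMask,
    exclude: np.ndarray | None = None,
) -> RegionSummary:
    """Class-wise mean/SD of each signed metric and mean total DOP magnitude."""
    lt, ln = _class_values(dolp, mask, exclude)
    ct, cn = _class_values(docp, mask, exclude)
    total = total_dop_magnitude(dolp, docp)
    tt, tn = _class_values(total, mask, exclude)
    return RegionSummary(
        stats={
            "linear": {"tumor": _moments(lt), "nontumor": _moments(ln)},
            "circular": {"tumor": _moments(ct), "nontumor": _moments(cn)},
        },
        dop_total={"tumor": float(tt.mean()), "nontumor": float(tn.mean())},
    )
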