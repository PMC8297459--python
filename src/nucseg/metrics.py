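"""Segmentation and count-agreement metrics.

Segmentation quality is scored on binarized (foreground vs background)
masks with the Dice similarity coefficient and intersection-over-union,

``DSC = 2|S ∩ T| / (|S| + |T|) x 100``,
``IoU = |S ∩ T| / |S ∪ T| x 100``,

which are related by ``IoU = DSC / (2 - DSC)`` on the unit scale.
Count agreement between automated and manual counts uses the Pearson
correlation and Bland-Altman analysis (bias = mean of automated minus
manual, 95% limits of agreement = bias ± 1.96 SD of the differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .image_io import BinaryMask, LabelMap

__all__ = [
    "SegScores",
    "AgreementStats",
    "DatasetReport",
    "dice",
    "iou",
    "seg_scores",
    "pearson",
    "bland_altman",
    "evaluate_dataset",
]


@dataclass(frozen=True)
class SegScores:
    """Overlap scores of a segmentation S against ground truth T."""

    dsc: float  # percent
    iou: float  # percent
    intersection: int
    size_s: int
    size_t: int


@dataclass(frozen=True)
class AgreementStats:
    """Pearson and Bland-Altman agreement between paired counts."""

    pearson_r: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    outlier_fraction: float


def _mask_array(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.pixels
    if isinstance(mask, LabelMap):
        return mask.labels > 0
    return np.asarray(mask, dtype=bool)


def _overlap(S, T) -> tuple[int, int, int]:
    s = _mask_array(S)
    t = _mask_array(T)
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {t.shape}")
    return int((s & t).sum()), int(s.sum()), int(t.sum())


def dice(S, T) -> float:
    """Dice similarity coefficient in percent.

    Empty vs empty is defined as 100% (perfect agreement on absence).
    """
    inter, ns, nt = _overlap(S, T)
    if ns + nt == 0:
        return 100.0
    return 200.0 * inter / (ns + nt)


def iou(S, T) -> float:
    """Intersection over union (Jaccard) in percent; empty vs empty is 100%."""
    inter, ns, nt = _overlap(S, T)
    union = ns + nt - inter
    if union == 0:
        return 100.0
    return 100.0 * inter / union


def seg_scores(S, T) -> SegScores:
    """Both overlap scores plus the raw pixel counts."""
    inter, ns, nt = _overlap(S, T)
    return SegScores(dice(S, T), iou(S, T), inter, ns, nt)


def pearson(counts_auto, counts_manual) -> tuple[float, float]:
    """Sample Pearson r between paired counts and its two-sided p-value
    (t transform with n - 2 degrees of freedom)."""
    x = np.asarray(counts_auto, dtype=np.float64)
    y = np.asarray(counts_manual, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of >= 3 counts")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for constant counts")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(counts_auto, counts_manual) -> AgreementStats:
    """Bland-Altman agreement of automated vs manual counts.

    The difference sign convention is automated - manual, so a method
    that undercounts shows a negative bias. Limits of agreement use the
    sample (ddof=1) standard deviation of the differences.
    """
    x = np.asarray(counts_auto, dtype=np.float64)
    y = np.asarray(counts_manual, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors of >= 2 counts")
    diff = x - y
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outliers = float(np.mean((diff < lo) | (diff > hi)))
    r, p = (np.nan, np.nan)
    try:
        r, p = pearson(x, y)
    except ValueError:
        pass
    return AgreementStats(r, p, bias, lo, hi, outliers)


def plot_bland_altman(counts_auto, counts_manual, ax=None):
    """Bland-Altman plot: paired differences vs paired means, with the
    bias (solid) and 95% limits of agreement (dashed) as horizontal lines.

    Requires matplotlib. Returns the axes.
    """
    import matplotlib.pyplot as plt

    x = np.asarray(counts_auto, dtype=np.float64)
    y = np.asarray(counts_manual, dtype=np.float64)
    stats = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2.0, x - y, s=12, alpha=0.7)
    ax.axhline(stats.bias, color="k")
    for limit in (stats.loa_low, stats.loa_high):
        ax.axhline(limit, color="k", linestyle="--")
    ax.set_xlabel("mean of automated and manual count")
    ax.set_ylabel("automated - manual count")
    return ax


@dataclass
class DatasetReport:
    """Per-image scores plus aggregate summaries for a paired dataset."""

    per_image: pd.DataFrame
    mean_dsc: float
    sd_dsc: float
    mean_iou: float
    sd_iou: float
    agreement: AgreementStats | None

    def to_csv(self, path) -> None:
        """Per-image rows plus a 'mean ± SD' summary row."""
        table = self.per_image.copy()
        summary = {
            "name": "summary(mean±sd)",
            "count_auto": table["count_auto"].mean(),
            "count_manual": table["count_manual"].mean(),
            "dsc": f"{self.mean_dsc:.2f}±{self.sd_dsc:.2f}",
            "iou": f"{self.mean_iou:.2f}±{self.sd_iou:.2f}",
        }
        table = pd.concat([table, pd.DataFrame([summary])], ignore_index=True)
        table.to_csv(path, index=False)


def evaluate_dataset(pred_maps, gt_maps, names=None) -> DatasetReport:
    """Score a list of predicted label maps against paired ground truth.

    DSC/IoU are computed on the binarized maps; counts are the numbers
    of distinct positive labels on each side. The Pearson/Bland-Altman
    agreement block is omitted (None) when fewer than two pairs exist;
    Pearson r is NaN when either count vector is constant.
    """
    if len(pred_maps) != len(gt_maps):
        raise ValueError("prediction and ground-truth lists differ in length")
    if names is None:
        names = [f"image_{i:03d}" for i in range(len(pred_maps))]
    rows = []
    for name, pred, gt in zip(names, pred_maps, gt_maps):
        pred = pred if isinstance(pred, LabelMap) else LabelMap(pred)
        gt = gt if isinstance(gt, LabelMap) else LabelMap(gt)
        scores = seg_scores(pred, gt)
        rows.append({
            "name": name,
            "count_auto": pred.n_labels,
            "count_manual": gt.n_labels,
            "dsc": scores.dsc,
            "iou": scores.iou,
        })
    table = pd.DataFrame(rows)
    agreement = None
    if len(rows) >= 2:
        x = table["count_auto"].to_numpy(dtype=np.float64)
        y = table["count_manual"].to_numpy(dtype=np.float64)
        agreement = bland_altman(x, y)
    return DatasetReport(
        per_image=table,
        mean_dsc=float(table["dsc"].mean()),
        sd_dsc=float(table["dsc"].std(ddof=1)) if len(rows) > 1 else 0.0,
        mean_iou=float(table["iou"].mean()),
        sd_iou=float(table["iou"].std(ddof=1)) if len(rows) > 1 else 0.0,
        agreement=agreement,
    )
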