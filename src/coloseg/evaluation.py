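"""Segmentation and slide-level metrics.

Pixel-level: per-class and mean Dice (= F1 at pixel level), benchmark-style
F1 after class merging and white-lumen relabeling, and the Wilcoxon
signed-rank test for paired model comparison.  Slide-level: one-vs-all
ROC/AUC and the quadratic weighted kappa, the chance-corrected agreement
measure that penalizes confusions between distant ordinal risk grades
quadratically.

Two conventions exist for classes absent from both prediction and
reference: excluding them from the mean (default) or counting them as zero
(the convention some per-center plots use); both are supported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as _scipy_stats
from sklearn.metrics import roc_auc_score

from .containers import SegmentationMap
from .schema import BACKGROUND, IGNORE_INDEX, ClassMergeMap

ABSENT = float("nan")


@dataclass
class DiceReport:
    per_class: dict[int, float]   # NaN marks a class absent from both maps
    mean: float
    n_pixels: dict[int, int]      # reference pixel count per class

    def present_classes(self) -> list[int]:
        return [c for c, v in self.per_class.items() if not np.isnan(v)]


def _as_labels(m) -> np.ndarray:
    if isinstance(m, SegmentationMap):
        return m.labels
    return np.asarray(m)


def dice_per_class(pred, ref, n_classes: int = 14,
                   ignore_index: int = IGNORE_INDEX,
                   absent_policy: str = "exclude",
                   classes=None) -> DiceReport:
    """Per-class Dice 2|P∩R| / (|P|+|R|) and its mean.

    Ignore-labeled reference pixels are excluded everywhere.  A class
    absent from both maps is marked absent (NaN); ``absent_policy`` decides
    whether the mean skips it (``"exclude"``) or counts it as zero
    (``"zero"``).  ``classes`` restricts scoring to a subset of labels.
    """
    p, r = _as_labels(pred), _as_labels(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs ref {r.shape}")
    if absent_policy not in ("exclude", "zero"):
        raise ValueError("absent_policy must be 'exclude' or 'zero'")
    valid = r != ignore_index
    p, r = p[valid], r[valid]
    per_class, n_pixels = {}, {}
    scored = []
    for c in (range(n_classes) if classes is None else classes):
        pc, rc = p == c, r == c
        np_c, nr_c = int(pc.sum()), int(rc.sum())
        n_pixels[c] = nr_c
        if np_c + nr_c == 0:
            per_class[c] = ABSENT
            if absent_policy == "zero":
                scored.append(0.0)
            continue
        d = 2.0 * int((pc & rc).sum()) / (np_c + nr_c)
        per_class[c] = d
        scored.append(d)
    mean = float(np.mean(scored)) if scored else ABSENT
    return DiceReport(per_class=per_class, mean=mean, n_pixels=n_pixels)


def relabel_lumen(reference_image: np.ndarray, reference_mask: np.ndarray,
                  threshold: float = 240.0,
                  background: int = BACKGROUND) -> np.ndarray:
    """Relabel near-white pixels (mean RGB strictly above ``threshold``) as
    background.

    Gland-benchmark annotations include the lumen in the gland object; this
    network segments lumina separately, so for comparison the white luminal
    area is moved to background in the reference mask.
    """
    img = np.asarray(reference_image, dtype=np.float64)
    if img.shape[:2] != reference_mask.shape:
        raise ValueError("image and mask must align")
    out = np.asarray(reference_mask).copy()
    out[img.mean(axis=-1) > threshold] = background
    return out


def merged_f1(pred, ref, merge: ClassMergeMap,
              reference_image: Optional[np.ndarray] = None,
              lumen_threshold: float = 240.0,
              ignore_index: int = IGNORE_INDEX) -> float:
    """Benchmark F1: merge both maps, optionally strip the white lumen from
    the reference, and average pixel-level F1 over the merged foreground
    classes (non-gland/background excluded).
    """
    p = merge.apply(_as_labels(pred), ignore_index)
    r = _as_labels(ref)
    if reference_image is not None:
        r = relabel_lumen(reference_image, r, threshold=lumen_threshold)
    r = merge.apply(r, ignore_index)
    report = dice_per_class(p, r, n_classes=max(merge.target_names) + 1,
                            ignore_index=ignore_index,
                            classes=merge.foreground, absent_policy="exclude")
    return report.mean


def wilcoxon_compare(scores_a, scores_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired scores.

    Uses the exact null distribution for ≤ 25 informative pairs, the
    normal approximation above.  All-equal pairs are degenerate: the test
    carries no information and (statistic 0, p = 1) is returned.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors of equal length required")
    d = a - b
    nz = np.count_nonzero(d)
    if nz == 0:
        return 0.0, 1.0
    method = "exact" if nz <= 25 else "approx"
    res = _scipy_stats.wilcoxon(a, b, zero_method="wilcox",
                                alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def quadratic_weighted_kappa(cm: np.ndarray) -> float:
    """Quadratic weighted kappa of a K×K confusion matrix.

    κ = 1 − Σ w_ij O_ij / Σ w_ij E_ij with weights w_ij = (i−j)²/(K−1)²
    and E the outer product of the observed marginals (scaled to the
    total).  1 is perfect agreement, 0 chance-level, negative worse than
    chance.
    """
    O = np.asarray(cm, dtype=np.float64)
    if O.ndim != 2 or O.shape[0] != O.shape[1] or O.shape[0] < 2:
        raise ValueError("confusion matrix must be K x K with K >= 2")
    if np.any(O < 0) or O.sum() == 0:
        raise ValueError("confusion matrix must be non-negative and non-empty")
    K = O.shape[0]
    total = O.sum()
    i, j = np.indices((K, K))
    w = (i - j) ** 2 / (K - 1) ** 2
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / total
    denom = (w * E).sum()
    if denom == 0:
        raise ValueError("degenerate marginals: expected agreement undefined")
    return float(1.0 - (w * O).sum() / denom)


def confusion_matrix(true_labels, pred_labels, n_classes: int) -> np.ndarray:
    """Counts with rows = reference class, columns = predicted class."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(pred_labels, dtype=np.int64)
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (t, p), 1)
    return cm


def one_vs_all_roc(scores: np.ndarray, labels, fold_ids=None) -> dict:
    """Per-class one-vs-all AUC from a (n_slides, K) class-probability table.

    Returns ``{class index: auc}``; with ``fold_ids`` the value is the
    mean AUC across folds and a ``(class, "sd")`` entry carries the spread.
    Classes with no positives or no negatives are reported as NaN.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if s.ndim != 2 or s.shape[0] != y.shape[0]:
        raise ValueError("scores must be (n_slides, n_classes)")
    K = s.shape[1]

    def _auc(yb, sc):
        if yb.min() == yb.max():
            return np.nan
        return roc_auc_score(yb, sc)

    out: dict = {}
    for c in range(K):
        yb = (y == c).astype(int)
        if fold_ids is None:
            out[c] = float(_auc(yb, s[:, c]))
        else:
            folds = np.asarray(fold_ids)
            vals = [_auc(yb[folds == f], s[folds == f, c])
                    for f in np.unique(folds)]
            vals = [v for v in vals if not np.isnan(v)]
            out[c] = float(np.mean(vals)) if vals else float("nan")
            out[(c, "sd")] = float(np.std(vals)) if vals else float("nan")
    return out
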