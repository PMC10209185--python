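"""Slide-level risk classification from segmentation maps.

Each tissue fragment of a slide is summarized by 18 features: the
normalized 14-class histogram of its segmented pixels plus four tumor
cluster statistics (count, mean, minimum and maximum cluster area in μm²)
computed on connected components of the high-grade dysplasia/tumor class
after discarding clusters below 30 μm² — an empirical cut against
speckle-sized false positives.  The filter affects only the cluster
features, not the histogram or the stored map, keeping the segmentation
auditable; a hard-removal mode that relabels small clusters into their
surrounding majority class is available.

A random forest with 1000 trees classifies fragments in a stratified
five-fold cross-validation with per-fold feature standardization (mean/sd
learned on the training folds only).  A slide's label is the worst
(highest-risk) fragment prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .containers import SegmentationMap, SlideCase
from .schema import BACKGROUND, IGNORE_INDEX, TUMOR, RiskLabel

logger = logging.getLogger(__name__)

MIN_TUMOR_CLUSTER_UM2 = 30.0
MIN_FRAGMENT_AREA_UM2 = 1e4

FEATURE_NAMES = tuple(f"hist_{i}" for i in range(14)) + (
    "n_tumor_clusters", "mean_cluster_area", "min_cluster_area",
    "max_cluster_area")


@dataclass
class FragmentFeatures:
    histogram: np.ndarray          # 14 fractions summing to 1
    n_tumor_clusters: int
    mean_cluster_area: float       # μm²
    min_cluster_area: float
    max_cluster_area: float

    def __post_init__(self):
        if self.histogram.shape != (14,):
            raise ValueError("histogram must have 14 bins")
        if self.n_tumor_clusters == 0:
            assert self.mean_cluster_area == self.min_cluster_area == \
                self.max_cluster_area == 0.0
        if not (self.min_cluster_area <= self.mean_cluster_area
                <= self.max_cluster_area):
            raise ValueError("cluster area stats must be ordered")

    def vector(self) -> np.ndarray:
        return np.concatenate([self.histogram,
                               [self.n_tumor_clusters, self.mean_cluster_area,
                                self.min_cluster_area, self.max_cluster_area]])


def find_fragments(slide_map: SegmentationMap,
                   min_area_um2: float = MIN_FRAGMENT_AREA_UM2,
                   connectivity: int = 1,
                   background: int = BACKGROUND) -> list[SegmentationMap]:
    """Connected components of non-background tissue, cropped to their box.

    Components smaller than ``min_area_um2`` are discarded as debris.
    Pixels of other fragments inside a crop are replaced by background so
    each returned map describes exactly one fragment.
    """
    tissue = (slide_map.labels != background) & \
             (slide_map.labels != IGNORE_INDEX)
    labeled = measure.label(tissue, connectivity=connectivity)
    px_area = slide_map.pixel_area_um2()
    fragments = []
    for region in measure.regionprops(labeled):
        if region.area * px_area < min_area_um2:
            continue
        r0, c0, r1, c1 = region.bbox
        crop = slide_map.labels[r0:r1, c0:c1].copy()
        crop[labeled[r0:r1, c0:c1] != region.label] = background
        fragments.append(SegmentationMap(labels=crop,
                                         spacing_um=slide_map.spacing_um))
    if not fragments:
        logger.warning("no tissue fragment above %.0f μm² found", min_area_um2)
    return fragments


def tumor_clusters(fragment: SegmentationMap,
                   min_area_um2: float = MIN_TUMOR_CLUSTER_UM2,
                   connectivity: int = 1,
                   tumor_class: int = TUMOR) -> list[float]:
    """Areas (μm², descending) of tumor components at least ``min_area_um2``.

    4-connectivity by default, so diagonally touching blobs stay separate
    clusters.
    """
    labeled = measure.label(fragment.labels == tumor_class,
                            connectivity=connectivity)
    px_area = fragment.pixel_area_um2()
    counts = np.bincount(labeled.ravel())[1:]  # skip background component 0
    areas = counts * px_area
    return sorted((float(a) for a in areas if a >= min_area_um2), reverse=True)


def remove_small_tumor_clusters(fragment: SegmentationMap,
                                min_area_um2: float = MIN_TUMOR_CLUSTER_UM2,
                                connectivity: int = 1) -> SegmentationMap:
    """Hard-removal mode: relabel sub-threshold tumor clusters to the
    majority class of their surrounding ring (background if isolated)."""
    labels = fragment.labels.copy()
    comp = measure.label(labels == TUMOR, connectivity=connectivity)
    px_area = fragment.pixel_area_um2()
    from scipy import ndimage as ndi
    for region in measure.regionprops(comp):
        if region.area * px_area >= min_area_um2:
            continue
        mask = comp == region.label
        ring = ndi.binary_dilation(mask) & ~mask
        ring_vals = labels[ring]
        ring_vals = ring_vals[(ring_vals != TUMOR) & (ring_vals != IGNORE_INDEX)]
        fill = np.bincount(ring_vals).argmax() if ring_vals.size else BACKGROUND
        labels[mask] = fill
    return SegmentationMap(labels=labels, spacing_um=fragment.spacing_um)


def extract_features(fragment: SegmentationMap,
                     min_cluster_um2: float = MIN_TUMOR_CLUSTER_UM2,
                     connectivity: int = 1) -> FragmentFeatures:
    """Histogram + tumor-cluster features for one fragment.

    The histogram counts every segmented pixel — including tumor pixels in
    clusters the 30 μm² filter later discards; the filter shapes only the
    cluster statistics.
    """
    hist = fragment.class_histogram(14).astype(np.float64)
    total = hist.sum()
    if total == 0:
        raise ValueError("fragment contains no segmented pixels")
    areas = tumor_clusters(fragment, min_area_um2=min_cluster_um2,
                           connectivity=connectivity)
    if areas:
        stats = (len(areas), float(np.mean(areas)), min(areas), max(areas))
    else:
        stats = (0, 0.0, 0.0, 0.0)
    return FragmentFeatures(histogram=hist / total, n_tumor_clusters=stats[0],
                            mean_cluster_area=stats[1],
                            min_cluster_area=stats[2],
                            max_cluster_area=stats[3])


@dataclass
class ForestModel:
    """A fitted fold: standardizer + 1000-tree forest + class order."""

    scaler: StandardScaler
    forest: RandomForestClassifier
    classes: tuple

    def predict_fragment(self, features: FragmentFeatures):
        x = self.scaler.transform(features.vector()[None, :])
        probs = self.forest.predict_proba(x)[0]
        label = RiskLabel(int(self.forest.classes_[int(np.argmax(probs))]))
        return label, {RiskLabel(int(c)): float(p)
                       for c, p in zip(self.forest.classes_, probs)}


def classify_slide(model: ForestModel, case: SlideCase):
    """Worst-grade aggregation: the highest-risk fragment labels the slide.

    Returns ``(label, probabilities)`` where the probabilities are those of
    the worst fragment.  An empty fragment list degrades to OTHER with zero
    confidence.
    """
    if not case.fragments:
        logger.warning("slide %s has no fragments; defaulting to OTHER",
                       case.slide_id)
        return RiskLabel.OTHER, {c: 0.0 for c in RiskLabel}
    best = None
    for frag in case.fragments:
        label, probs = model.predict_fragment(extract_features(frag))
        if best is None or label > best[0]:
            best = (label, probs)
    return best


@dataclass
class CVResult:
    fold_models: list
    fold_of_case: np.ndarray        # test-fold id per case
    predicted: list                  # RiskLabel per case (out-of-fold)
    probabilities: np.ndarray        # (n_cases, 4) out-of-fold slide probs
    true_labels: np.ndarray


def fit_forest(cases: list[SlideCase], n_trees: int = 1000, folds: int = 5,
               seed: int = 0) -> CVResult:
    """Stratified K-fold cross-validation of the fragment forest.

    Fragments are the training unit, each bearing its slide's (weak)
    label; splits are by slide so no slide leaks across folds, and the
    feature standardization of each fold is learned on its training folds
    only.  Out-of-fold slide predictions use worst-grade aggregation.
    """
    if any(c.label is None for c in cases):
        raise ValueError("all cases need labels for cross-validation")
    y = np.array([int(c.label) for c in cases])
    counts = np.bincount(y, minlength=4)
    if (counts[counts > 0] < folds).any():
        logger.warning("some classes have fewer cases than folds; "
                       "stratification degraded")
    feats = [[extract_features(f) for f in c.fragments] for c in cases]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_models = []
    fold_of_case = np.full(len(cases), -1)
    predicted = [None] * len(cases)
    probabilities = np.zeros((len(cases), 4))
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(cases)), y)):
        X = np.array([f.vector() for i in tr for f in feats[i]])
        yy = np.array([y[i] for i in tr for _ in feats[i]])
        scaler = StandardScaler().fit(X)
        forest = RandomForestClassifier(n_estimators=n_trees,
                                        random_state=seed + fold,
                                        n_jobs=1).fit(scaler.transform(X), yy)
        model = ForestModel(scaler=scaler, forest=forest,
                            classes=tuple(RiskLabel))
        fold_models.append(model)
        for i in te:
            fold_of_case[i] = fold
            label, probs = classify_slide(model, cases[i])
            predicted[i] = label
            for c, p in probs.items():
                probabilities[i, int(c)] = p
    return CVResult(fold_models=fold_models, fold_of_case=fold_of_case,
                    predicted=predicted, probabilities=probabilities,
                    true_labels=y)
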