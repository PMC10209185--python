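"""Synthetic tissue-like data: textured tiles with paired masks, and
slide-level cohorts following the four risk categories.

The generator is a stand-in for H&E appearance, not a simulation of it:
each tissue class gets a distinct base color and one of four texture kinds
(blob, gland-ring, fiber, speckle), glandular classes are drawn as ring
structures enclosing a near-white lumen (mean RGB > 240, so the white-lumen
relabeling rule is exercisable), and slide-level class composition encodes
the diagnostic semantics — high-risk slides carry tumor clusters that
survive the 30 μm² filter, low-grade slides carry only sub-filter tumor
specks, hyperplasia is expressed purely through an elevated gland +
lamina-propria histogram (it is not a segmentation class), and "other"
slides carry neither dysplasia nor tumor.

Everything is driven by a single seed and regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import LabeledTile, SegmentationMap, SlideCase
from .schema import (BACKGROUND, LOW_GRADE_DYSPLASIA, NORMAL_GLANDS, TUMOR,
                     RiskLabel)

GLAND_CLASSES = (NORMAL_GLANDS, LOW_GRADE_DYSPLASIA, TUMOR)

#: Base colors chosen to keep all pairwise distances comfortably above the
#: enforced minimum; background is near-white like scanned glass.
_DEFAULT_COLORS = {
    0: (150, 100, 180), 1: (195, 115, 205), 2: (120, 30, 85),
    3: (240, 185, 210), 4: (200, 140, 150), 5: (250, 160, 185),
    6: (205, 225, 240), 7: (160, 160, 105), 8: (70, 70, 200),
    9: (220, 55, 55), 10: (250, 235, 205), 11: (185, 90, 120),
    12: (230, 210, 150), 13: (248, 248, 248),
}
_DEFAULT_KINDS = {
    0: "gland-ring", 1: "gland-ring", 2: "gland-ring",
    3: "fiber", 4: "fiber", 5: "fiber", 11: "fiber", 12: "fiber",
    7: "speckle", 8: "speckle", 9: "speckle",
    6: "blob", 10: "blob", 13: "blob",
}


@dataclass
class TextureModel:
    """Per-class rendering parameters with a distinguishability guarantee."""

    colors: dict = field(default_factory=lambda: dict(_DEFAULT_COLORS))
    kinds: dict = field(default_factory=lambda: dict(_DEFAULT_KINDS))
    texture_scale: float = 8.0
    noise_sd: float = 4.0
    min_color_distance: float = 20.0

    def __post_init__(self):
        keys = sorted(self.colors)
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                d = np.linalg.norm(np.subtract(self.colors[a], self.colors[b]))
                if d < self.min_color_distance:
                    raise ValueError(
                        f"classes {a} and {b} are not distinguishable: "
                        f"color distance {d:.1f} < {self.min_color_distance}")


def _smooth_field(shape, sigma, rng):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.mean()) / (f.std() + 1e-12)


def _stamp_disc(mask, r, c, radius, value):
    rr, cc = np.ogrid[:mask.shape[0], :mask.shape[1]]
    mask[(rr - r) ** 2 + (cc - c) ** 2 <= radius ** 2] = value


def _stamp_ring(mask, lumen, r, c, r_out, thickness, value,
                lumen_label=BACKGROUND):
    rr, cc = np.ogrid[:mask.shape[0], :mask.shape[1]]
    d2 = (rr - r) ** 2 + (cc - c) ** 2
    ring = (d2 <= r_out ** 2) & (d2 > (r_out - thickness) ** 2)
    hole = d2 <= (r_out - thickness) ** 2
    mask[ring] = value
    mask[hole] = lumen_label
    lumen[hole] = True


def generate_label_geometry(shape, class_set, rng,
                            min_coverage: float = 0.01,
                            with_rings: bool = True,
                            lumen_label: int = BACKGROUND):
    """Space-filling random partition of ``shape`` into the requested classes.

    Smooth random fields (one per class) are argmaxed into regions; field
    biases are adjusted until every requested class covers at least
    ``min_coverage`` of the pixels.  Glandular classes additionally receive
    ring structures whose interior is the white lumen, labeled
    ``lumen_label``.  Returns ``(mask, lumen_mask)``.
    """
    classes = sorted(set(int(c) for c in class_set))
    if not classes:
        raise ValueError("class_set must not be empty")
    H, W = shape
    if H < 64 or W < 64:
        raise ValueError("shape must be at least 64x64")
    lumen = np.zeros(shape, dtype=bool)
    if len(classes) == 1:
        return np.full(shape, classes[0], dtype=np.int64), lumen
    fields = np.stack([_smooth_field(shape, max(H, W) / 8, rng)
                       for _ in classes])
    bias = np.zeros(len(classes))
    for _ in range(200):
        mask_idx = (fields + bias[:, None, None]).argmax(axis=0)
        frac = np.bincount(mask_idx.ravel(), minlength=len(classes)) / (H * W)
        short = frac < min_coverage * 1.5
        if not short.any():
            break
        bias[short] += 0.05
        bias[~short] -= 0.05 * short.sum() / max(1, (~short).sum())
    mask = np.asarray(classes, dtype=np.int64)[mask_idx]
    if with_rings:
        for c in classes:
            if c not in GLAND_CLASSES:
                continue
            rows, cols = np.nonzero(mask == c)
            if rows.size == 0:
                continue
            hi = max(8, min(16, H // 8))
            lo = max(6, hi - 6)
            for _ in range(int(rng.integers(1, 4))):
                k = int(rng.integers(rows.size))
                r_out = int(rng.integers(lo, hi))
                _stamp_ring(mask, lumen, rows[k], cols[k], r_out,
                            int(rng.integers(3, 5)), c, lumen_label)
    return mask, lumen


def render_texture(mask, texture: TextureModel, rng,
                   lumen_mask=None) -> np.ndarray:
    """Textured RGB rendering of a label mask.

    Lumen pixels render near-saturated white (every channel ≥ 243, so the
    per-pixel mean RGB strictly exceeds 240).
    """
    H, W = mask.shape
    img = np.zeros((H, W, 3))
    for c in np.unique(mask):
        region = mask == c
        color = np.asarray(texture.colors[int(c)], dtype=np.float64)
        kind = texture.kinds[int(c)]
        patch = np.tile(color, (H, W, 1))
        if kind in ("blob", "gland-ring"):
            mod = _smooth_field((H, W), texture.texture_scale, rng)
            patch *= (1 + 0.06 * mod)[..., None]
        elif kind == "fiber":
            mod = _smooth_field((H, W), (texture.texture_scale, 1.5), rng)
            patch *= (1 + 0.08 * mod)[..., None]
        elif kind == "speckle":
            dots = rng.random((H, W)) < 0.12
            patch[dots] *= 0.55
        img[region] = patch[region]
    img += rng.normal(0, texture.noise_sd, size=img.shape)
    if lumen_mask is not None and lumen_mask.any():
        white = np.clip(rng.normal(252, 2, size=(int(lumen_mask.sum()), 3)),
                        243, 255)
        img[lumen_mask] = white
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_tile_dataset(n_tiles: int, shape=(512, 512),
                      class_set=(0, 2, 5, 8, 13), seed: int = 0,
                      texture: TextureModel | None = None,
                      spacing_um: float = 1.0) -> list[LabeledTile]:
    """Paired (image, mask) tiles for segmentation training and evaluation."""
    texture = texture or TextureModel()
    rng = np.random.default_rng(seed)
    tiles = []
    for _ in range(n_tiles):
        mask, lumen = generate_label_geometry(shape, class_set, rng)
        img = render_texture(mask, texture, rng, lumen_mask=lumen)
        tiles.append(LabeledTile(image=img, mask=mask, spacing_um=spacing_um))
    return tiles


#: The five-class desk-scale texture task: normal glands, tumor, lamina
#: propria, lymphocytes and background — well separated in color/texture.
TEXTURE_TASK_CLASSES = (0, 2, 5, 8, 13)


def make_texture_task(n_train: int = 200, n_val: int = 20, tile_px: int = 64,
                      seed: int = 0, class_set=TEXTURE_TASK_CLASSES):
    """Segmentation task with masks relabeled to a compact 0..K−1 space.

    Returns ``(train_tiles, val_tiles, n_classes)``.  The compact label
    space matches a K-class network head; the mapping follows the order of
    ``class_set``.
    """
    lut = np.zeros(256, dtype=np.int64)
    for i, c in enumerate(class_set):
        lut[c] = i
    tiles = make_tile_dataset(n_train + n_val, shape=(tile_px, tile_px),
                              class_set=class_set, seed=seed)
    tiles = [LabeledTile(image=t.image, mask=lut[t.mask],
                         spacing_um=t.spacing_um) for t in tiles]
    return tiles[:n_train], tiles[n_train:], len(class_set)


# ---------------------------------------------------------------------------
# slide-level cohort


@dataclass
class CohortSpec:
    """Slide counts per risk class and fragment geometry.

    Defaults follow the reference cohort composition (292 high-risk, 693
    low-grade dysplasia, 36 hyperplasia, 33 other); :meth:`balanced` gives
    the equal-size design used for desk-scale validation.
    """

    n_high_risk: int = 292
    n_low_grade: int = 693
    n_hyperplasia: int = 36
    n_other: int = 33
    fragments_range: tuple[int, int] = (1, 4)
    fragment_px: int = 160
    spacing_um: float = 1.0

    @classmethod
    def balanced(cls, n: int = 40, **kw) -> "CohortSpec":
        return cls(n_high_risk=n, n_low_grade=n, n_hyperplasia=n, n_other=n,
                   **kw)

    @property
    def n_slides(self) -> int:
        return (self.n_high_risk + self.n_low_grade + self.n_hyperplasia
                + self.n_other)


def _composition(label: RiskLabel, rng) -> dict[int, float]:
    """Target class fractions inside the tissue of one fragment.

    Hyperplasia has no mask class of its own; it is encoded as an elevated
    normal-gland + lamina-propria signature whose gland range deliberately
    overlaps the gland content of low-grade slides, so the two categories
    are distinguished mainly by the presence of the low-grade class.
    """
    u = rng.uniform
    if label == RiskLabel.HIGH_RISK:
        w = {NORMAL_GLANDS: u(0.05, 0.2), LOW_GRADE_DYSPLASIA: u(0.0, 0.2),
             5: u(0.2, 0.4), 3: u(0.1, 0.3), 8: u(0.0, 0.1)}
    elif label == RiskLabel.LOW_GRADE_DYSPLASIA:
        w = {NORMAL_GLANDS: u(0.15, 0.45), LOW_GRADE_DYSPLASIA: u(0.1, 0.4),
             5: u(0.2, 0.4), 3: u(0.05, 0.2)}
    elif label == RiskLabel.HYPERPLASIA:
        w = {NORMAL_GLANDS: u(0.3, 0.55), 5: u(0.25, 0.45), 3: u(0.0, 0.15),
             6: u(0.0, 0.1)}
    else:
        w = {NORMAL_GLANDS: u(0.0, 0.12), 5: u(0.2, 0.4), 3: u(0.2, 0.4),
             6: u(0.0, 0.2), 8: u(0.0, 0.2)}
    total = sum(w.values())
    return {c: v / total for c, v in w.items() if v > 0}


def _fragment_map(label: RiskLabel, spec: CohortSpec, rng,
                  ensure_tumor: bool) -> SegmentationMap:
    n = spec.fragment_px
    labels = np.full((n, n), BACKGROUND, dtype=np.int64)
    rr, cc = np.ogrid[:n, :n]
    ar, br = n * rng.uniform(0.32, 0.45), n * rng.uniform(0.32, 0.45)
    tissue = ((rr - n / 2) / ar) ** 2 + ((cc - n / 2) / br) ** 2 <= 1.0
    comp = _composition(label, rng)
    # Voronoi partition of the tissue into composition-weighted regions
    classes = list(comp)
    n_seeds = 40
    seed_cls = rng.choice(classes, size=n_seeds, p=[comp[c] for c in classes])
    pts = rng.uniform(0, n, size=(n_seeds, 2))
    rows, cols = np.nonzero(tissue)
    d2 = (rows[:, None] - pts[None, :, 0]) ** 2 + \
         (cols[:, None] - pts[None, :, 1]) ** 2
    labels[rows, cols] = seed_cls[d2.argmin(axis=1)]
    inner = ndimage.binary_erosion(tissue, iterations=12)
    irows, icols = np.nonzero(inner)
    if label == RiskLabel.HIGH_RISK and ensure_tumor and irows.size:
        for _ in range(int(rng.integers(1, 4))):
            k = int(rng.integers(irows.size))
            _stamp_disc(labels, irows[k], icols[k],
                        int(rng.integers(7, 13)), TUMOR)
    if label == RiskLabel.LOW_GRADE_DYSPLASIA and irows.size:
        # sub-filter specks only: radius-2 discs are 13 px² < 30 μm² at
        # 1 μm/px; keep them 8 px apart so components never merge
        placed = []
        for _ in range(int(rng.integers(2, 7))):
            for _attempt in range(20):
                k = int(rng.integers(irows.size))
                p = (int(irows[k]), int(icols[k]))
                if all(abs(p[0] - q[0]) + abs(p[1] - q[1]) > 8 for q in placed):
                    _stamp_disc(labels, p[0], p[1], 2, TUMOR)
                    placed.append(p)
                    break
    labels[~tissue] = BACKGROUND
    return SegmentationMap(labels=labels, spacing_um=spec.spacing_um)


def compose_slide_map(fragments: list[SegmentationMap],
                      gap_px: int = 24) -> SegmentationMap:
    """Place fragment maps side by side on a background canvas."""
    H = max(f.shape[0] for f in fragments) + 2 * gap_px
    W = sum(f.shape[1] for f in fragments) + gap_px * (len(fragments) + 1)
    canvas = np.full((H, W), BACKGROUND, dtype=np.int64)
    c = gap_px
    for f in fragments:
        canvas[gap_px:gap_px + f.shape[0], c:c + f.shape[1]] = f.labels
        c += f.shape[1] + gap_px
    return SegmentationMap(labels=canvas, spacing_um=fragments[0].spacing_um)


def generate_cohort(spec: CohortSpec | None = None, seed: int = 0):
    """Synthetic slide cohort: ``(cases, slide_maps)``.

    Every high-risk case has at least one tumor cluster that survives the
    30 μm² filter; low-grade cases carry only sub-filter specks (zero
    surviving clusters); hyperplasia and other cases contain no tumor or
    low-grade pixels at all beyond their composition rules.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    counts = [(RiskLabel.OTHER, spec.n_other),
              (RiskLabel.HYPERPLASIA, spec.n_hyperplasia),
              (RiskLabel.LOW_GRADE_DYSPLASIA, spec.n_low_grade),
              (RiskLabel.HIGH_RISK, spec.n_high_risk)]
    cases, slide_maps = [], []
    idx = 0
    for label, n in counts:
        for _ in range(n):
            n_frag = int(rng.integers(spec.fragments_range[0],
                                      spec.fragments_range[1] + 1))
            frags = [_fragment_map(label, spec, rng, ensure_tumor=(i == 0))
                     for i in range(n_frag)]
            slide_maps.append(compose_slide_map(frags))
            cases.append(SlideCase(slide_id=f"slide_{idx:04d}",
                                   fragments=frags, label=label))
            idx += 1
    return cases, slide_maps
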