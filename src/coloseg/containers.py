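"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .schema import IGNORE_INDEX, RiskLabel


@dataclass
class LabeledTile:
    """An RGB tile with its integer label mask and pixel spacing.

    The atomic unit for training and pixel-level evaluation.  ``image`` is
    8-bit (H, W, 3); ``mask`` holds class indices 0..C−1 or the ignore
    label for unannotated pixels; ``spacing_um`` is the edge length of one
    pixel in micrometers.
    """

    image: np.ndarray
    mask: np.ndarray
    spacing_um: float = 1.0

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[-1] != 3:
            raise ValueError("image must be (H, W, 3)")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} disagree")
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class SegmentationMap:
    """A per-pixel label map with physical pixel spacing.

    ``labels`` holds class indices; ``spacing_um`` converts pixel counts to
    areas (one pixel = spacing² μm²).  ``likelihoods`` optionally keeps the
    (C, H, W) class-probability stack the labels were argmaxed from.
    """

    labels: np.ndarray
    spacing_um: float = 1.0
    likelihoods: Optional[np.ndarray] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if self.spacing_um <= 0:
            raise ValueError("spacing must be positive")
        if self.likelihoods is not None and \
                self.likelihoods.shape[1:] != self.labels.shape:
            raise ValueError("likelihoods must be (C, H, W) matching labels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def pixel_area_um2(self) -> float:
        return self.spacing_um ** 2

    def class_histogram(self, n_classes: int,
                        ignore_index: int = IGNORE_INDEX) -> np.ndarray:
        """Pixel counts per class, ignore pixels excluded."""
        valid = self.labels[self.labels != ignore_index]
        return np.bincount(valid.ravel(), minlength=n_classes)[:n_classes]


@dataclass
class SlideCase:
    """All tissue fragments of one slide plus its ordinal risk label."""

    slide_id: str
    fragments: list  # list[SegmentationMap]
    label: Optional[RiskLabel] = None

    def __post_init__(self):
        spacings = {f.spacing_um for f in self.fragments}
        if len(spacings) > 1:
            raise ValueError("all fragments of a slide must share spacing")
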