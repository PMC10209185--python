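"""Label space for colorectal tissue segmentation and biopsy risk grading.

The segmentation network predicts one of 14 tissue categories per pixel.
Background is a real, trained class (it has its own Dice score), distinct
from the ``ignore`` label that marks unannotated pixels and is excluded from
every loss and metric.  Slide-level diagnosis uses a four-step ordinal risk
scale.  Merge maps reduce the 14-class space to the binary (gland /
non-gland) and three-class (benign / malignant epithelium / non-gland)
spaces used by public gland-segmentation benchmarks.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import yaml

#: Label value for unannotated pixels.  Outside 0..13 and representable in
#: an 8-bit mask image.
IGNORE_INDEX = 255

#: Canonical class order.  Indices are part of the on-disk mask format.
CLASS_NAMES = (
    "normal glands",
    "low-grade dysplasia",
    "high-grade dysplasia/tumor",
    "submucosal stroma",
    "desmoplastic stroma",
    "stroma lamina propria",
    "mucus",
    "necrosis and debris",
    "lymphocytes",
    "erythrocytes",
    "adipose tissue",
    "muscle",
    "nerve",
    "background",
)

NORMAL_GLANDS = 0
LOW_GRADE_DYSPLASIA = 1
TUMOR = 2
BACKGROUND = 13

_DEFAULT_COLORS = (
    (31, 119, 180),
    (255, 127, 14),
    (214, 39, 40),
    (148, 103, 189),
    (140, 86, 75),
    (227, 119, 194),
    (127, 127, 127),
    (188, 189, 34),
    (23, 190, 207),
    (255, 152, 150),
    (197, 176, 213),
    (196, 156, 148),
    (247, 182, 210),
    (240, 240, 240),
)


class RiskLabel(IntEnum):
    """Ordinal slide-level diagnosis; larger value = higher clinical risk."""

    OTHER = 0
    HYPERPLASIA = 1
    LOW_GRADE_DYSPLASIA = 2
    HIGH_RISK = 3

    @classmethod
    def from_name(cls, name: str) -> "RiskLabel":
        return cls[name.strip().upper()]


@dataclass(frozen=True)
class TissueSchema:
    """The ordered tissue label space.

    Attributes
    ----------
    classes : tuple of str
        Class names; position in the tuple is the integer label.
    ignore_index : int
        Label for unannotated pixels; never a prediction target.
    display_colors : tuple of RGB triples
        Colors used when rendering label maps.
    """

    classes: tuple[str, ...] = CLASS_NAMES
    ignore_index: int = IGNORE_INDEX
    display_colors: tuple[tuple[int, int, int], ...] = _DEFAULT_COLORS

    def __post_init__(self):
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class names")
        if 0 <= self.ignore_index < len(self.classes):
            raise ValueError("ignore_index collides with a class index")
        if len(self.display_colors) != len(self.classes):
            raise ValueError("one display color per class required")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index_of(self, name: str) -> int:
        return self.classes.index(name)

    def validate_mask(self, mask: np.ndarray) -> None:
        """Raise if ``mask`` contains labels outside the schema."""
        values = np.unique(mask)
        allowed = set(range(self.n_classes)) | {self.ignore_index}
        bad = [int(v) for v in values if int(v) not in allowed]
        if bad:
            raise ValueError(f"mask contains labels outside the schema: {bad}")

    @functools.cached_property
    def content_hash(self) -> str:
        import hashlib

        payload = repr((self.classes, self.ignore_index)).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self) -> str:
        doc = {
            "ignore_index": self.ignore_index,
            "classes": [
                {"index": i, "name": n, "color": list(c)}
                for i, (n, c) in enumerate(zip(self.classes, self.display_colors))
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "TissueSchema":
        doc = yaml.safe_load(text)
        entries = sorted(doc["classes"], key=lambda e: e["index"])
        if [e["index"] for e in entries] != list(range(len(entries))):
            raise ValueError("class indices must be contiguous from 0")
        return cls(
            classes=tuple(e["name"] for e in entries),
            ignore_index=int(doc["ignore_index"]),
            display_colors=tuple(tuple(e["color"]) for e in entries),
        )


@dataclass(frozen=True)
class ClassMergeMap:
    """Total map from source class indices onto a reduced label set.

    The reduced labels are chosen among the source labels as fixed points of
    the mapping, so applying the map twice equals applying it once and a
    reduced mask stays valid under the source schema.
    """

    mapping: dict[int, int]
    target_names: dict[int, str]
    foreground: tuple[int, ...]

    def __post_init__(self):
        targets = set(self.mapping.values())
        if targets != set(self.target_names):
            raise ValueError("target_names must name exactly the merge targets")
        for t in targets:
            if self.mapping.get(t, t) != t:
                raise ValueError("merge targets must be fixed points of the mapping")

    @property
    def n_targets(self) -> int:
        return len(self.target_names)

    def apply(self, mask: np.ndarray, ignore_index: int = IGNORE_INDEX) -> np.ndarray:
        """Relabel ``mask`` into the reduced space; ignore pixels pass through."""
        lut = np.arange(max(ignore_index + 1, max(self.mapping) + 1), dtype=np.int64)
        for src, dst in self.mapping.items():
            lut[src] = dst
        lut[ignore_index] = ignore_index
        return lut[mask]

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "mapping": {int(k): int(v) for k, v in sorted(self.mapping.items())},
                "target_names": {int(k): v for k, v in sorted(self.target_names.items())},
                "foreground": [int(f) for f in self.foreground],
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ClassMergeMap":
        doc = yaml.safe_load(text)
        return cls(
            mapping={int(k): int(v) for k, v in doc["mapping"].items()},
            target_names={int(k): str(v) for k, v in doc["target_names"].items()},
            foreground=tuple(int(f) for f in doc["foreground"]),
        )


def build_default_schema() -> TissueSchema:
    """The 14-class colorectal tissue schema in canonical order."""
    return TissueSchema()


def _require_default(schema: TissueSchema) -> None:
    if tuple(schema.classes) != CLASS_NAMES:
        raise ValueError("merge maps are defined for the default 14-class schema only")


def crag_merge_map(schema: TissueSchema) -> ClassMergeMap:
    """Binary gland-vs-rest merge for CRAG-style benchmarks.

    Normal glands, low-grade dysplasia and tumor collapse to one "gland"
    label (kept at index 0); everything else becomes "non-gland", kept at
    the background index so the merged mask remains schema-valid.
    """
    _require_default(schema)
    mapping = {i: BACKGROUND for i in range(schema.n_classes)}
    for c in (NORMAL_GLANDS, LOW_GRADE_DYSPLASIA, TUMOR):
        mapping[c] = NORMAL_GLANDS
    return ClassMergeMap(
        mapping=mapping,
        target_names={NORMAL_GLANDS: "gland", BACKGROUND: "non-gland"},
        foreground=(NORMAL_GLANDS,),
    )


def glas_merge_map(schema: TissueSchema) -> ClassMergeMap:
    """Three-way merge for GlaS-style benchmarks.

    Benign epithelium (normal glands + low-grade dysplasia) keeps index 0,
    malignant epithelium (tumor) keeps index 2, all other tissue merges
    into non-gland at the background index.
    """
    _require_default(schema)
    mapping = {i: BACKGROUND for i in range(schema.n_classes)}
    mapping[NORMAL_GLANDS] = NORMAL_GLANDS
    mapping[LOW_GRADE_DYSPLASIA] = NORMAL_GLANDS
    mapping[TUMOR] = TUMOR
    return ClassMergeMap(
        mapping=mapping,
        target_names={
            NORMAL_GLANDS: "benign epithelium",
            TUMOR: "malignant epithelium",
            BACKGROUND: "non-gland",
        },
        foreground=(NORMAL_GLANDS, TUMOR),
    )
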