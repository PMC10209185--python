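"""Readers and writers for tiles, masks, label maps, configs and manifests.

Masks and label maps persist as single-channel PNG (labels fit in 8 bits
with ignore = 255); every label map carries a JSON sidecar with its pixel
spacing and the schema hash so downstream commands need no extra
arguments.  Optional likelihood stacks are quantized to 8 bits per channel
(the argmax label map is always computed before quantization).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .containers import LabeledTile, SegmentationMap
from .schema import RiskLabel, TissueSchema, build_default_schema

logger = logging.getLogger(__name__)


def read_labeled_tile(image_path, mask_path, spacing_um: float,
                      schema: TissueSchema | None = None) -> LabeledTile:
    """Load an image/mask pair, validating shapes and label values."""
    schema = schema or build_default_schema()
    image = iio.imread(image_path)
    mask = np.asarray(iio.imread(mask_path))
    if mask.ndim == 3:
        if not (mask[..., 0] == mask.max(axis=-1)).all():
            raise ValueError(f"{mask_path}: mask must be single-channel")
        mask = mask[..., 0]
    if image.shape[:2] != mask.shape:
        raise ValueError(
            f"image {image.shape[:2]} and mask {mask.shape} disagree "
            f"({image_path} vs {mask_path})")
    schema.validate_mask(mask)
    return LabeledTile(image=image, mask=mask.astype(np.int64),
                       spacing_um=spacing_um)


def write_labeled_tile(tile: LabeledTile, image_path, mask_path) -> None:
    iio.imwrite(image_path, tile.image.astype(np.uint8))
    iio.imwrite(mask_path, tile.mask.astype(np.uint8))


def write_segmentation_map(seg: SegmentationMap, path,
                           schema: TissueSchema | None = None) -> None:
    """Label map as PNG + JSON sidecar (+ quantized likelihoods if present)."""
    schema = schema or build_default_schema()
    path = Path(path)
    iio.imwrite(path, seg.labels.astype(np.uint8))
    sidecar = {"spacing_um": seg.spacing_um, "schema_hash": schema.content_hash}
    if seg.likelihoods is not None:
        q = np.clip(np.rint(seg.likelihoods * 255), 0, 255).astype(np.uint8)
        np.save(path.with_suffix(".lik.npy"), q)
        sidecar["likelihoods"] = path.with_suffix(".lik.npy").name
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_segmentation_map(path, schema: TissueSchema | None = None,
                          spacing_um: float | None = None,
                          allow_schema_mismatch: bool = False) -> SegmentationMap:
    schema = schema or build_default_schema()
    path = Path(path)
    labels = np.asarray(iio.imread(path)).astype(np.int64)
    sidecar_path = path.with_suffix(".json")
    likelihoods = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        spacing_um = float(sidecar["spacing_um"])
        if sidecar.get("schema_hash") != schema.content_hash:
            msg = f"{path}: schema hash mismatch with the active schema"
            if not allow_schema_mismatch:
                raise ValueError(msg + " (pass allow_schema_mismatch to override)")
            logger.warning(msg)
        if "likelihoods" in sidecar:
            q = np.load(path.parent / sidecar["likelihoods"])
            likelihoods = q.astype(np.float32) / 255.0
    elif spacing_um is None:
        raise ValueError(f"{path}: no sidecar found; explicit spacing required")
    return SegmentationMap(labels=labels, spacing_um=spacing_um,
                           likelihoods=likelihoods)


# ---------------------------------------------------------------------------
# manifests and label tables


def write_manifest(records: list[dict], path) -> None:
    pd.DataFrame(records, columns=["image", "mask", "spacing_um", "split",
                                   "slide_id"]).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    base = Path(path).parent
    for col in ("image", "mask"):
        for p in df[col].dropna():
            if not (base / p).exists() and not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file {p}")
    if (df["spacing_um"] <= 0).any():
        raise ValueError("manifest spacing must be positive")
    return df


def write_labels_csv(labels: dict[str, RiskLabel], path) -> None:
    pd.DataFrame(
        [{"slide_id": k, "label": v.name.lower()} for k, v in labels.items()]
    ).to_csv(path, index=False)


def read_labels_csv(path) -> dict[str, RiskLabel]:
    df = pd.read_csv(path)
    return {str(r.slide_id): RiskLabel.from_name(str(r.label))
            for r in df.itertuples()}


# ---------------------------------------------------------------------------
# configs


def write_train_config(config, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def read_train_config(path):
    from .training import TrainConfig

    doc = yaml.safe_load(Path(path).read_text())
    try:
        return TrainConfig.from_dict(doc)
    except (KeyError, TypeError) as e:
        raise ValueError(f"invalid training config {path}: {e}") from e
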