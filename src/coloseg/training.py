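"""Training protocol: balanced patch sampling, augmentation, LR schedule.

The protocol trains on 512×512 px patches at 1 μm/px with Adam from an
initial learning rate of 1e−4, halving it whenever the validation loss has
not improved for 20 consecutive epochs and stopping once it has not
improved for 50.  Mini-batches hold 5 patches; an epoch is 300 optimizer
steps.  Patch sampling is class-balanced: each patch is anchored on a pixel
of a class drawn uniformly from the classes present in the source set.
All of these are configurable; the defaults are the study protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import LabeledTile
from .losses import LossConfig, PixelBatch, loss_value, segmentation_loss
from .model import UNet
from .nn import Adam
from .schema import IGNORE_INDEX

logger = logging.getLogger(__name__)

DEFAULT_AUGMENTATIONS = (
    "flip", "rotate", "elastic", "blur", "gamma", "stain", "color", "contrast",
)


@dataclass
class TrainConfig:
    patch_px: int = 512
    spacing_um: float = 1.0
    batch_size: int = 5
    max_epochs: int = 500
    iters_per_epoch: int = 300
    lr_init: float = 1e-4
    lr_factor: float = 0.5
    lr_patience_epochs: int = 20
    stop_patience_epochs: int = 50
    augmentations: tuple = DEFAULT_AUGMENTATIONS
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    monitor: str = "val_loss"  # or "val_dice"

    def __post_init__(self):
        if min(self.patch_px, self.batch_size, self.max_epochs,
               self.iters_per_epoch, self.lr_patience_epochs,
               self.stop_patience_epochs) < 1:
            raise ValueError("all counts must be positive")
        if not (0 < self.lr_factor < 1):
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.stop_patience_epochs < self.lr_patience_epochs:
            raise ValueError("stop patience must be >= lr patience")
        if self.monitor not in ("val_loss", "val_dice"):
            raise ValueError("monitor must be val_loss or val_dice")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "patch_px", "spacing_um", "batch_size", "max_epochs",
            "iters_per_epoch", "lr_init", "lr_factor", "lr_patience_epochs",
            "stop_patience_epochs", "seed", "monitor")}
        d["augmentations"] = list(self.augmentations)
        d["loss"] = self.loss.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["loss"] = LossConfig.from_dict(d["loss"])
        d["augmentations"] = tuple(d.get("augmentations", DEFAULT_AUGMENTATIONS))
        return cls(**d)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    val_dice: float
    lr: float


@dataclass
class TrainHistory:
    records: list = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def monitored(self, monitor: str) -> list:
        if monitor == "val_dice":          # maximized -> negate to minimize
            return [-r.val_dice for r in self.records]
        return [r.val_loss for r in self.records]


class PatchSampler:
    """Class-balanced patch sampling from labeled tiles.

    For each patch an anchor class is drawn uniformly from the classes
    present anywhere in the source set; then a uniformly chosen pixel of
    that class anchors a ``patch_px`` window (clamped to the tile; tiles
    smaller than the patch are reflect-padded).  This equalizes how often
    rare tissue classes appear at patch centers.
    """

    def __init__(self, tiles: list[LabeledTile], patch_px: int,
                 seed: int = 0, balanced: bool = True,
                 ignore_index: int = IGNORE_INDEX):
        if not tiles:
            raise ValueError("no source tiles")
        self.tiles = tiles
        self.patch_px = patch_px
        self.rng = np.random.default_rng(seed)
        self.balanced = balanced
        self.ignore_index = ignore_index
        # per class: list of (tile index, flat pixel indices)
        self._locations: dict[int, list] = {}
        for ti, tile in enumerate(tiles):
            for c in np.unique(tile.mask):
                c = int(c)
                if c == ignore_index:
                    continue
                flat = np.flatnonzero(tile.mask == c)
                self._locations.setdefault(c, []).append((ti, flat))
        if not self._locations:
            raise ValueError("every pixel in every source tile is ignored")
        self.present_classes = sorted(self._locations)

    def _crop(self, tile: LabeledTile, center_r: int, center_c: int) -> LabeledTile:
        p = self.patch_px
        H, W = tile.shape
        img, mask = tile.image, tile.mask
        if H < p or W < p:
            pr, pc = max(0, p - H), max(0, p - W)
            img = np.pad(img, ((0, pr), (0, pc), (0, 0)), mode="reflect")
            mask = np.pad(mask, ((0, pr), (0, pc)), mode="reflect")
            H, W = mask.shape
        r0 = int(np.clip(center_r - p // 2, 0, H - p))
        c0 = int(np.clip(center_c - p // 2, 0, W - p))
        return LabeledTile(image=img[r0:r0 + p, c0:c0 + p],
                           mask=mask[r0:r0 + p, c0:c0 + p],
                           spacing_um=tile.spacing_um)

    def sample_one(self) -> tuple[LabeledTile, int]:
        """One patch plus the anchor class it was drawn for."""
        if self.balanced:
            anchor = int(self.rng.choice(self.present_classes))
            ti, flat = self._locations[anchor][
                int(self.rng.integers(len(self._locations[anchor])))]
            pix = int(flat[int(self.rng.integers(flat.size))])
            tile = self.tiles[ti]
            r, c = divmod(pix, tile.shape[1])
        else:
            ti = int(self.rng.integers(len(self.tiles)))
            tile = self.tiles[ti]
            r = int(self.rng.integers(tile.shape[0]))
            c = int(self.rng.integers(tile.shape[1]))
            anchor = int(tile.mask[r, c])
        return self._crop(tile, r, c), anchor

    def sample_batch(self, n: int) -> list[LabeledTile]:
        return [self.sample_one()[0] for _ in range(n)]


# ---------------------------------------------------------------------------
# augmentation


def _geometric(image, mask, transform):
    return transform(image), transform(mask)


def augment(tile: LabeledTile, transforms=DEFAULT_AUGMENTATIONS,
            rng: np.random.Generator | None = None,
            elastic_alpha: float = 8.0, elastic_sigma: float = 8.0,
            p_apply: float = 0.5) -> LabeledTile:
    """Randomly perturb a tile; geometric transforms move the mask along.

    Geometric transforms (``flip``/``flip_h``/``flip_v``, ``rotate``,
    ``elastic``) are applied identically to image and mask (mask with
    nearest-neighbor interpolation); photometric transforms (``blur``,
    ``gamma``, ``stain``, ``color``, ``contrast``) never touch the mask.
    ``flip_h``/``flip_v`` apply deterministically (each is an involution);
    the named random transforms each fire with probability ``p_apply``.
    """
    rng = rng or np.random.default_rng()
    img = np.asarray(tile.image, dtype=np.float64)
    mask = tile.mask.copy()

    def fires(name):
        return name in transforms and rng.random() < p_apply

    if "flip_h" in transforms:
        img, mask = _geometric(img, mask, lambda a: a[:, ::-1])
    if "flip_v" in transforms:
        img, mask = _geometric(img, mask, lambda a: a[::-1])
    if fires("flip"):
        axis = int(rng.integers(2))
        img, mask = _geometric(img, mask, lambda a: np.flip(a, axis=axis))
    if fires("rotate"):
        k = int(rng.integers(1, 4))
        img, mask = _geometric(img, mask,
                               lambda a: np.rot90(a, k=k, axes=(0, 1)))
    if "elastic" in transforms and (elastic_alpha == 0 or rng.random() < p_apply):
        H, W = mask.shape
        dr = ndimage.gaussian_filter(rng.normal(size=(H, W)), elastic_sigma,
                                     mode="reflect") * elastic_alpha
        dc = ndimage.gaussian_filter(rng.normal(size=(H, W)), elastic_sigma,
                                     mode="reflect") * elastic_alpha
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        coords = [rr + dr, cc + dc]
        img = np.stack([ndimage.map_coordinates(img[..., ch], coords, order=1,
                                                mode="reflect")
                        for ch in range(3)], axis=-1)
        mask = ndimage.map_coordinates(mask, coords, order=0, mode="nearest")
    if fires("blur"):
        img = ndimage.gaussian_filter(img, sigma=(rng.uniform(0.3, 1.2),) * 2 + (0,))
    if fires("gamma"):
        g = rng.uniform(0.7, 1.4)
        img = np.power(np.clip(img, 0, 255) / 255.0, g) * 255.0
    if fires("stain"):
        # jitter in optical-density space: per-channel absorbance scale/shift
        od = -np.log((np.clip(img, 0, 255) + 1.0) / 256.0)
        od = od * rng.uniform(0.9, 1.1, size=3) + rng.uniform(-0.03, 0.03, size=3)
        img = np.exp(-od) * 256.0 - 1.0
    if fires("color"):
        img = img + rng.uniform(-12, 12, size=3)
    if fires("contrast"):
        f = rng.uniform(0.8, 1.2)
        img = (img - img.mean()) * f + img.mean()
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledTile(image=np.ascontiguousarray(img),
                       mask=np.ascontiguousarray(mask),
                       spacing_um=tile.spacing_um)


# ---------------------------------------------------------------------------
# learning-rate schedule / early stop


def schedule_lr(history: TrainHistory, config: TrainConfig) -> float:
    """Learning rate implied by the monitored validation trace so far.

    Whenever the monitored quantity fails to improve for
    ``lr_patience_epochs`` consecutive epochs since the last improvement or
    the last reduction, the rate is multiplied by ``lr_factor`` (patience
    resets after a reduction).
    """
    lr = config.lr_init
    best = np.inf
    since = 0
    for value in history.monitored(config.monitor):
        if value < best:
            best = value
            since = 0
        else:
            since += 1
        if since >= config.lr_patience_epochs:
            lr *= config.lr_factor
            since = 0
    return lr


def should_stop(history: TrainHistory, config: TrainConfig) -> bool:
    """True once the monitor has not improved for ``stop_patience_epochs``."""
    values = history.monitored(config.monitor)
    if len(values) <= config.stop_patience_epochs:
        return False
    best_epoch = int(np.argmin(values))
    return len(values) - 1 - best_epoch >= config.stop_patience_epochs


# ---------------------------------------------------------------------------
# training loop


def _batch_arrays(tiles: list[LabeledTile]):
    x = np.stack([t.image for t in tiles]).astype(np.float64) / 255.0
    y = np.stack([t.mask for t in tiles]).astype(np.int64)
    return x, y


def _validate(model: UNet, val_tiles, loss_config: LossConfig, n_classes: int):
    from .evaluation import dice_per_class

    losses, dices = [], []
    for tile in val_tiles:
        x = tile.image.astype(np.float64)[None] / 255.0
        act = model.forward(x, train=False)
        flat_a = act.reshape(-1, n_classes)
        batch = PixelBatch.from_activations(flat_a, tile.mask.reshape(-1))
        losses.append(loss_value(batch, loss_config))
        pred = act[0].argmax(axis=-1)
        report = dice_per_class(pred, tile.mask, n_classes=n_classes)
        dices.append(report.mean)
    return float(np.mean(losses)), float(np.mean(dices))


def train(model: UNet, train_set: list[LabeledTile], val_set: list[LabeledTile],
          config: TrainConfig):
    """Full training run; returns the best-validation model and its history.

    Reproducible given ``config.seed``: sampling, augmentation and the
    optimizer consume independent streams derived from it.  The weights of
    the epoch with the best monitored validation value are restored before
    returning.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    n_classes = model.spec.n_classes
    sampler = PatchSampler(train_set, config.patch_px, seed=config.seed)
    aug_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    opt = Adam(model.params(), lr=config.lr_init)
    history = TrainHistory()
    best_value = np.inf
    best_state = None
    for epoch in range(config.max_epochs):
        epoch_losses = []
        for _ in range(config.iters_per_epoch):
            tiles = [augment(t, config.augmentations, aug_rng)
                     for t in sampler.sample_batch(config.batch_size)]
            x, y = _batch_arrays(tiles)
            act = model.forward(x, train=True)
            loss, grad = segmentation_loss(act, y, config.loss)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss!r}")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss)
        val_loss, val_dice = _validate(model, val_set, config.loss, n_classes)
        history.records.append(EpochRecord(
            epoch=epoch, train_loss=float(np.mean(epoch_losses)),
            val_loss=val_loss, val_dice=val_dice, lr=opt.lr))
        value = history.monitored(config.monitor)[-1]
        if value < best_value:
            best_value = value
            history.best_epoch = epoch
            best_state = [a.copy() for a in model.state_arrays()]
        opt.lr = schedule_lr(history, config)
        if should_stop(history, config):
            history.stop_reason = (
                f"no improvement for {config.stop_patience_epochs} epochs")
            break
    else:
        history.stop_reason = "max_epochs reached"
    if best_state is not None:
        for target, saved in zip(model.state_arrays(), best_state):
            target[...] = saved
    return model, history
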