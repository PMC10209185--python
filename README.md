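# coloseg

Two-stage computer-aided diagnosis of colorectal biopsies from H&E
whole-slide images, for computational-pathology researchers and engineers:

1. **Tissue segmentation.** A U-Net variant assigns every pixel of a
   512×512 px tile (at 1 μm/px) to one of 14 tissue classes — normal
   glands, low-grade dysplasia, high-grade dysplasia/tumor, submucosal
   stroma, desmoplastic stroma, stroma lamina propria, mucus, necrosis and
   debris, lymphocytes, erythrocytes, adipose tissue, muscle, nerve,
   background.  The network can be trained with any of four
   interchangeable objectives: categorical cross-entropy, focal,
   bi-tempered logistic, or Lovász-softmax.
2. **Slide classification.** Each connected tissue fragment of a slide is
   summarized by 18 features — the normalized 14-bin class histogram plus
   the count and mean/min/max area (μm²) of high-grade-dysplasia/tumor
   clusters surviving a 30 μm² filter — and classified by a 1000-tree
   random forest into an ordinal risk grade (other < hyperplasia <
   low-grade dysplasia < high-risk); the slide receives its worst
   fragment's grade.

Everything runs on CPU with numpy: the network layers, their backward
passes and the Adam optimizer are implemented in `coloseg.nn`, and a
synthetic-data generator provides tissue-like tiles and labeled slide
cohorts so the entire pipeline trains, infers and evaluates offline.

## The loss functions

With per-pixel softmax output ŷ and one-hot ground truth y over classes C:

- **Categorical cross-entropy** `L = −Σᵢ yᵢ log ŷᵢ`.
- **Focal** `L = −Σᵢ α (1−ŷᵢ)^γ yᵢ log ŷᵢ` — γ focuses training on
  hard pixels (defaults α=0.25, γ=2).
- **Bi-tempered** replaces the softmax by a heavy-tailed tempered softmax
  `ŷᵢ = exp_{t₂}(âᵢ − λ(â))` with λ chosen numerically so the outputs sum
  to 1, and the entropy by a tempered version
  `L = Σᵢ yᵢ(log_{t₁} yᵢ − log_{t₁} ŷᵢ) − (yᵢ^{2−t₁} − ŷᵢ^{2−t₁})/(2−t₁)`,
  making training robust to label noise (defaults t₁=0.8, t₂=1.2; at
  t₁=t₂=1 the ordinary logistic loss is recovered exactly).
- **Lovász-softmax** `L = (1/|C|) Σ_c Δ̄_{J_c}(m(c))`, the Lovász-extension
  surrogate of the mean Jaccard loss 1 − IoU; on hard predictions it equals
  the mean 1 − IoU exactly.

All four expose analytic gradients verified against central differences.

## Worked example

```python
from coloseg import LossConfig, ModelSpec, TrainConfig, build_model, train
from coloseg.synthetic import make_texture_task

train_tiles, val_tiles, k = make_texture_task(n_train=50, n_val=10,
                                              tile_px=64, seed=11)
model = build_model(ModelSpec(n_classes=k, base_filters=8, depth=2), seed=3)
cfg = TrainConfig(patch_px=64, batch_size=5, max_epochs=6,
                  iters_per_epoch=30, lr_init=1e-3,
                  loss=LossConfig(kind="lovasz_softmax"),
                  augmentations=("flip", "rotate"), seed=3)
model, history = train(model, train_tiles, val_tiles, cfg)
for r in history.records[-2:]:
    print(f"epoch {r.epoch}: val loss {r.val_loss:.4f}, val Dice {r.val_dice:.4f}")
```

prints (exactly reproducible with these seeds):

```
epoch 4: val loss 0.0749, val Dice 0.9690
epoch 5: val loss 0.0634, val Dice 0.9744
```

A validation Dice of 0.97 means predicted and reference masks overlap
almost perfectly on the held-out tiles of the five-class synthetic texture
task.  The `examples/` directory has one short script per capability:
losses, training, whole-image tiled inference, slide classification, and
benchmark-style class merging with white-lumen relabeling
(`python examples/01_loss_functions.py`, …).

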