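"""The four segmentation training objectives and their analytic gradients.

All losses operate on a :class:`PixelBatch` — a flat collection of pixels
with per-class scores — and return the mean loss over valid (non-ignored)
pixels.  Three of them (categorical cross-entropy, focal, Lovász-softmax)
consume normalized class probabilities; the bi-tempered loss consumes raw
activations because its heavy-tailed softmax is part of the objective.

Every loss comes with a closed-form gradient with respect to its natural
input (probabilities or activations) so the numpy training loop can
backpropagate without an autodiff framework, and so the gradients can be
verified against central differences.

Degenerate limits are exact: focal with ``gamma=0, alpha=1`` is the
cross-entropy; the bi-tempered loss at ``t1=t2=1`` is the cross-entropy of
the softmaxed activations; the Lovász-softmax on hard 0/1 probabilities is
the mean Jaccard loss (1 − IoU) over classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .schema import IGNORE_INDEX

#: Probabilities are clamped here before logarithms; cross-entropy-type
#: losses are unbounded at zero probability and must not produce NaN/inf.
PROB_EPS = 1e-12


@dataclass
class LossConfig:
    """Hyperparameters selecting and parameterizing the training objective.

    kind : one of ``cross_entropy``, ``focal``, ``bi_tempered``,
        ``lovasz_softmax``.  ``cross_entropy`` ignores all other fields.
    alpha, gamma : focal weighting and focusing strength (defaults follow
        the focal-loss reference recommendation).
    t1, t2 : bi-tempered entropy and softmax-tail temperatures (defaults
        follow the bi-tempered reference implementation); ``t1 = t2 = 1``
        recovers the plain logistic loss.
    lambda_tol, lambda_max_iter : stopping rule for the tempered-softmax
        normalizer search.
    """

    kind: str = "cross_entropy"
    alpha: float = 0.25
    gamma: float = 2.0
    t1: float = 0.8
    t2: float = 1.2
    lambda_tol: float = 1e-9
    lambda_max_iter: int = 100
    lovasz_present_only: bool = False

    KINDS = ("cross_entropy", "focal", "bi_tempered", "lovasz_softmax")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.t1 <= 1):
            raise ValueError("t1 must lie in (0, 1]")
        if self.t2 < 1:
            raise ValueError("t2 must be >= 1")
        if self.lambda_tol <= 0:
            raise ValueError("lambda_tol must be positive")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "alpha": self.alpha, "gamma": self.gamma,
            "t1": self.t1, "t2": self.t2, "lambda_tol": self.lambda_tol,
            "lambda_max_iter": self.lambda_max_iter,
            "lovasz_present_only": self.lovasz_present_only,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LossConfig":
        return cls(**d)


@dataclass
class PixelBatch:
    """A flat batch of pixels with class scores and integer targets.

    Either ``activations`` (pre-softmax scores, required by the bi-tempered
    loss) or ``probabilities`` (rows summing to 1, required by the others)
    must be present; both may be.  ``targets`` may contain ``ignore_index``;
    those pixels contribute exactly nothing to any loss.
    """

    targets: np.ndarray
    activations: Optional[np.ndarray] = None
    probabilities: Optional[np.ndarray] = None
    ignore_index: int = IGNORE_INDEX

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=np.int64)
        ref = self.activations if self.activations is not None else self.probabilities
        if ref is None:
            raise ValueError("need activations or probabilities")
        if ref.ndim != 2 or ref.shape[0] != self.targets.shape[0]:
            raise ValueError("scores must be [n_pixels, n_classes]")
        C = ref.shape[1]
        valid = self.targets != self.ignore_index
        if np.any((self.targets[valid] < 0) | (self.targets[valid] >= C)):
            raise ValueError("targets outside class range")
        if self.probabilities is not None:
            rows = self.probabilities[valid].sum(axis=1)
            if valid.any() and not np.allclose(rows, 1.0, atol=1e-5):
                raise ValueError("probability rows must sum to 1")

    @property
    def n_classes(self) -> int:
        ref = self.activations if self.activations is not None else self.probabilities
        return ref.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return self.targets != self.ignore_index

    def require_valid(self) -> np.ndarray:
        valid = self.valid_mask
        if not valid.any():
            raise ValueError("empty batch: every pixel is ignored")
        return valid

    @classmethod
    def from_activations(cls, activations, targets, ignore_index=IGNORE_INDEX):
        a = np.asarray(activations, dtype=np.float64)
        return cls(targets=targets, activations=a,
                   probabilities=softmax(a), ignore_index=ignore_index)


def softmax(activations: np.ndarray) -> np.ndarray:
    a = np.asarray(activations, dtype=np.float64)
    a = a - a.max(axis=-1, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# categorical cross-entropy


def cross_entropy_loss(batch: PixelBatch, return_grad: bool = False):
    """Mean over valid pixels of −log p(target).

    With one-hot targets the full class sum collapses to the target entry.
    The optional gradient is taken with respect to the probabilities.
    """
    valid = batch.require_valid()
    p = batch.probabilities
    if p is None:
        raise ValueError("cross_entropy_loss needs probabilities")
    idx = np.flatnonzero(valid)
    pt = np.clip(p[idx, batch.targets[idx]], PROB_EPS, None)
    loss = float(np.mean(-np.log(pt)))
    if not return_grad:
        return loss
    grad = np.zeros_like(p)
    grad[idx, batch.targets[idx]] = -1.0 / (pt * idx.size)
    return loss, grad


def focal_loss(batch: PixelBatch, alpha: float = 0.25, gamma: float = 2.0,
               return_grad: bool = False):
    """Mean over valid pixels of −α(1−p_t)^γ log p_t.

    γ focuses the objective on poorly-classified pixels; γ=0, α=1 recovers
    the cross-entropy exactly.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    valid = batch.require_valid()
    p = batch.probabilities
    if p is None:
        raise ValueError("focal_loss needs probabilities")
    idx = np.flatnonzero(valid)
    pt = np.clip(p[idx, batch.targets[idx]], PROB_EPS, 1.0)
    mod = (1.0 - pt) ** gamma
    loss = float(np.mean(-alpha * mod * np.log(pt)))
    if not return_grad:
        return loss
    # d/dp [-a(1-p)^g log p] = a·g(1-p)^(g-1) log p − a(1-p)^g / p
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -alpha * mod / pt
        if gamma > 0:
            d = d + alpha * gamma * np.where(
                pt < 1.0, (1.0 - pt) ** (gamma - 1.0), 0.0) * np.log(pt)
    grad = np.zeros_like(p)
    grad[idx, batch.targets[idx]] = d / idx.size
    return loss, grad


# ---------------------------------------------------------------------------
# bi-tempered logistic loss


def tempered_log(x, t: float):
    """Heavy-tailed logarithm: (x^(1−t) − 1)/(1−t), natural log at t=1."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x <= 0):
        raise ValueError("tempered_log requires positive input")
    if t == 1.0:
        return np.log(x)
    # (x^(1-t) - 1)/(1-t) = ln(x) * expm1(v)/v with v = (1-t) ln(x);
    # expm1(v)/v -> 1 smoothly as v -> 0, so this stays accurate for t
    # arbitrarily close to 1 where the direct form cancels catastrophically.
    logx = np.log(x)
    v = (1.0 - t) * logx
    safe = np.where(v == 0.0, 1.0, v)
    return logx * np.where(v == 0.0, 1.0, np.expm1(safe) / safe)


def tempered_exp(x, t: float):
    """Inverse of :func:`tempered_log` on its range: [1 + (1−t)x]_+^(1/(1−t))."""
    x = np.asarray(x, dtype=np.float64)
    if t == 1.0:
        return np.exp(x)
    # [1 + u]^(1/(1-t)) with u = (1-t)x, computed as exp(x * log1p(u)/u):
    # log1p(u)/u -> 1 smoothly as u -> 0, avoiding the 1/(1-t) error
    # amplification of the direct power form for t near 1.
    u = (1.0 - t) * x
    out = np.zeros(np.shape(u), dtype=np.float64)
    pos = u > -1.0
    up = u[pos]
    safe = np.where(up == 0.0, 1.0, up)
    ratio = np.where(up == 0.0, 1.0, np.log1p(safe) / safe)
    out[pos] = np.exp(np.asarray(x)[pos] * ratio)
    return out


def tempered_softmax(activations: np.ndarray, t2: float,
                     tol: float = 1e-9, max_iter: int = 100) -> np.ndarray:
    """Heavy-tailed softmax: exp_t2(a_i − λ) with λ s.t. the row sums to 1.

    λ is found by bisection on the monotone-decreasing residual
    Σ_j exp_t2(a_j − λ) − 1; the bracket [max a, max a − log_t2(1/C)]
    always contains the root.  Works on a single score vector or a
    [n, C] batch of rows.
    """
    if t2 < 1:
        raise ValueError("t2 must be >= 1")
    a = np.asarray(activations, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise ValueError("activations must be finite")
    single = a.ndim == 1
    a2 = a[None, :] if single else a
    if t2 == 1.0:
        out = softmax(a2)
        return out[0] if single else out
    C = a2.shape[1]
    amax = a2.max(axis=1)
    lo = amax.copy()                       # residual >= 0 here
    hi = amax - float(tempered_log(1.0 / C, t2))   # residual <= 0 here

    def residual(lam):
        return tempered_exp(a2 - lam[:, None], t2).sum(axis=1) - 1.0

    lam = (lo + hi) / 2.0
    for _ in range(max_iter):
        r = residual(lam)
        lo = np.where(r > 0, lam, lo)
        hi = np.where(r > 0, hi, lam)
        lam = (lo + hi) / 2.0
        if np.max(hi - lo) < min(tol, 1e-13):
            break
    out = tempered_exp(a2 - lam[:, None], t2)
    resid = np.abs(out.sum(axis=1) - 1.0)
    if np.max(resid) > max(tol, 1e-8):
        raise RuntimeError(
            f"tempered softmax normalizer did not converge: residual {np.max(resid):.3e}")
    return out[0] if single else out


def bi_tempered_loss(batch: PixelBatch, t1: float = 0.8, t2: float = 1.2,
                     tol: float = 1e-9, max_iter: int = 100,
                     return_grad: bool = False):
    """Bi-tempered logistic loss on raw activations.

    Per valid pixel with target class c and tempered-softmax output p:

        L = −log_t1(p_c) − 1/(2−t1) + (1/(2−t1)) Σ_j p_j^(2−t1)

    which is the tempered relative entropy between the one-hot target and p
    (one-hot zero entries contribute only through the Σ p^(2−t1) term).
    t1 < 1 bounds the loss for gross outliers; t2 > 1 fattens the softmax
    tail.  At t1 = t2 = 1 this is exactly −log softmax(a)_c.
    The gradient is taken with respect to the activations, using the
    implicit derivative of the shared normalizer λ.
    """
    valid = batch.require_valid()
    if batch.activations is None:
        raise ValueError("bi_tempered_loss consumes activations")
    idx = np.flatnonzero(valid)
    a = batch.activations[idx]
    tgt = batch.targets[idx]
    n, C = a.shape
    p = tempered_softmax(a, t2, tol=tol, max_iter=max_iter)
    p = np.clip(p, PROB_EPS, None)
    pc = p[np.arange(n), tgt]
    s = 2.0 - t1
    per_pixel = -tempered_log(pc, t1) - 1.0 / s + np.power(p, s).sum(axis=1) / s
    loss = float(per_pixel.mean())
    if not return_grad:
        return loss
    # dL/dp_j = p_j^(1−t1) − δ_jc p_c^(−t1); chain through the tempered
    # softmax: dp_j/da_k = p_j^t2 (δ_jk − p_k^t2 / Σ p^t2)
    dLdp = np.power(p, 1.0 - t1)
    dLdp[np.arange(n), tgt] -= np.power(pc, -t1)
    pt2 = np.power(p, t2)
    w = (dLdp * pt2)
    grad_valid = (w - pt2 * (w.sum(axis=1) / pt2.sum(axis=1))[:, None]) / n
    grad = np.zeros_like(batch.activations)
    grad[idx] = grad_valid
    return loss, grad


# ---------------------------------------------------------------------------
# Lovász-softmax


def lovasz_gradient(sorted_gt: np.ndarray) -> np.ndarray:
    """First differences of the Jaccard loss along a sorted error prefix.

    ``sorted_gt`` is the binary ground-truth vector reordered by descending
    prediction error.  Entry k of the result is J_k − J_{k−1} where J_k is
    the Jaccard loss 1 − I_k/U_k of the first k pixels; the entries sum to
    the Jaccard loss of the full vector, and the dot product with the sorted
    errors is the Lovász extension of the Jaccard loss.
    """
    gt = np.asarray(sorted_gt)
    if gt.ndim != 1 or gt.size == 0:
        raise ValueError("sorted_gt must be a non-empty vector")
    if not np.all((gt == 0) | (gt == 1)):
        raise ValueError("sorted_gt must be binary")
    gt = gt.astype(np.float64)
    gts = gt.sum()
    intersection = gts - np.cumsum(gt)
    union = gts + np.cumsum(1.0 - gt)
    jaccard = 1.0 - intersection / union
    out = jaccard.copy()
    out[1:] -= jaccard[:-1]
    return out


def lovasz_softmax_loss(batch: PixelBatch, present_only: bool = False,
                        return_grad: bool = False):
    """Lovász-softmax: mean over classes of the Lovász extension of 1 − IoU.

    For each class c the per-pixel errors |1{y=c} − p_c| are sorted in
    descending order (stable, so ties resolve by pixel index) and weighted
    by :func:`lovasz_gradient` of the ground truth in that order.  By
    default all classes are averaged; ``present_only`` restricts the mean
    to classes present in the ground truth.  On hard 0/1 probabilities the
    per-class term equals 1 − IoU of the binary masks.  The gradient treats
    the sorting permutation as locally constant, as in the reference
    algorithm.
    """
    valid = batch.require_valid()
    p = batch.probabilities
    if p is None:
        raise ValueError("lovasz_softmax_loss needs probabilities")
    idx = np.flatnonzero(valid)
    pv = p[idx]
    tv = batch.targets[idx]
    C = batch.n_classes
    grad = np.zeros_like(p) if return_grad else None

    classes = range(C)
    if present_only:
        classes = np.unique(tv)
        if len(classes) == 0:
            raise ValueError("no present classes")
    terms = []
    for c in classes:
        fg = (tv == c).astype(np.float64)
        errors = np.abs(fg - pv[:, c])
        order = np.argsort(-errors, kind="stable")
        g = lovasz_gradient(fg[order])
        terms.append(float(errors[order] @ g))
        if return_grad:
            # d|fg − p_c|/dp_c = −1 on foreground, +1 elsewhere
            sign = np.where(fg > 0, -1.0, 1.0)
            gcol = np.zeros(idx.size)
            gcol[order] = g
            grad[idx, c] += sign * gcol
    n_terms = len(terms)
    loss = float(np.mean(terms))
    if not return_grad:
        return loss
    return loss, grad / n_terms


# ---------------------------------------------------------------------------
# dispatch used by the training loop


def segmentation_loss(activations: np.ndarray, targets: np.ndarray,
                      config: LossConfig, ignore_index: int = IGNORE_INDEX):
    """Loss and gradient w.r.t. activations for a channels-last network output.

    ``activations`` has shape ``(..., C)`` and ``targets`` the matching
    leading shape.  Probability-space losses are chained through the softmax
    Jacobian (dL/da = p ⊙ (g − ⟨p, g⟩) for g = dL/dp); the bi-tempered loss
    differentiates its own tempered softmax.
    """
    shape = activations.shape
    C = shape[-1]
    flat_a = activations.reshape(-1, C)
    flat_t = np.asarray(targets).reshape(-1)
    if config.kind == "bi_tempered":
        batch = PixelBatch(targets=flat_t, activations=flat_a,
                           ignore_index=ignore_index)
        loss, grad_a = bi_tempered_loss(
            batch, t1=config.t1, t2=config.t2, tol=config.lambda_tol,
            max_iter=config.lambda_max_iter, return_grad=True)
    else:
        batch = PixelBatch.from_activations(flat_a, flat_t, ignore_index)
        p = batch.probabilities
        if config.kind == "cross_entropy":
            loss, grad_p = cross_entropy_loss(batch, return_grad=True)
        elif config.kind == "focal":
            loss, grad_p = focal_loss(batch, alpha=config.alpha,
                                      gamma=config.gamma, return_grad=True)
        elif config.kind == "lovasz_softmax":
            loss, grad_p = lovasz_softmax_loss(
                batch, present_only=config.lovasz_present_only, return_grad=True)
        else:  # pragma: no cover - guarded by LossConfig
            raise ValueError(config.kind)
        inner = (p * grad_p).sum(axis=1, keepdims=True)
        grad_a = p * (grad_p - inner)
    return loss, grad_a.reshape(shape)


def loss_value(batch: PixelBatch, config: LossConfig) -> float:
    """Evaluate the configured loss on a prepared pixel batch."""
    if config.kind == "cross_entropy":
        return cross_entropy_loss(batch)
    if config.kind == "focal":
        return focal_loss(batch, alpha=config.alpha, gamma=config.gamma)
    if config.kind == "bi_tempered":
        return bi_tempered_loss(batch, t1=config.t1, t2=config.t2,
                                tol=config.lambda_tol,
                                max_iter=config.lambda_max_iter)
    return lovasz_softmax_loss(batch, present_only=config.lovasz_present_only)
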