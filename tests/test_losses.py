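"""Loss-function values against independent oracles, plus their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coloseg.losses import (LossConfig, PixelBatch, bi_tempered_loss,
                            cross_entropy_loss, focal_loss, lovasz_gradient,
                            lovasz_softmax_loss, segmentation_loss, softmax,
                            tempered_exp, tempered_log, tempered_softmax)

from .conftest import numeric_gradient, relative_error


def _bisect_lambda(a, t2, iters=200):
    """Independent normalizer search for the tempered softmax."""
    lo, hi = a.max() - 20.0, a.max() + 20.0
    for _ in range(iters):
        mid = (lo + hi) / 2
        if tempered_exp(a - mid, t2).sum() > 1:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


class TestCrossEntropy:
    def test_perfect_prediction_is_zero(self):
        b = PixelBatch(targets=[1], probabilities=np.array([[0.0, 1.0, 0.0]]))
        assert cross_entropy_loss(b) == 0.0

    def test_uniform_prediction_is_log_c(self):
        b = PixelBatch(targets=[3], probabilities=np.full((1, 14), 1 / 14))
        assert cross_entropy_loss(b) == pytest.approx(np.log(14), abs=1e-12)

    def test_matches_direct_summation(self):
        r = np.random.default_rng(3)
        p = softmax(r.normal(size=(3, 3)))
        t = np.array([0, 2, 1])
        expected = np.mean([-np.log(p[i, t[i]]) for i in range(3)])
        b = PixelBatch(targets=t, probabilities=p)
        assert cross_entropy_loss(b) == pytest.approx(expected, abs=1e-12)

    def test_empty_batch_errors(self):
        b = PixelBatch(targets=[255], probabilities=np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError, match="empty batch"):
            cross_entropy_loss(b)


class TestFocal:
    def test_gamma_zero_is_cross_entropy(self, random_batch):
        assert focal_loss(random_batch, alpha=1.0, gamma=0.0) == pytest.approx(
            cross_entropy_loss(random_batch), abs=1e-9)

    def test_perfect_prediction_is_zero(self):
        b = PixelBatch(targets=[0], probabilities=np.array([[1.0, 0.0]]))
        assert focal_loss(b, alpha=0.5, gamma=3.0) == 0.0

    def test_single_pixel_value(self):
        b = PixelBatch(targets=[0], probabilities=np.array([[0.9, 0.1]]))
        expected = 0.25 * 0.1 ** 2 * -np.log(0.9)  # ≈ 2.6341e-4
        assert focal_loss(b, alpha=0.25, gamma=2.0) == pytest.approx(
            expected, rel=1e-12)

    def test_negative_gamma_rejected(self, random_batch):
        with pytest.raises(ValueError):
            focal_loss(random_batch, alpha=1.0, gamma=-1.0)


class TestTemperedOps:
    @pytest.mark.parametrize("t", [0.3, 0.7, 1.0, 1.5])
    def test_log_of_one_is_zero(self, t):
        assert tempered_log(1.0, t) == 0.0

    def test_natural_limits(self):
        assert tempered_log(np.e, 1.0) == pytest.approx(1.0)
        assert tempered_log(4.0, 0.5) == pytest.approx(2.0)
        assert tempered_exp(0.0, 1.7) == 1.0
        assert tempered_exp(-10.0, 2.0) == pytest.approx(1 / 11)

    def test_log_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tempered_log(0.0, 0.8)

    @given(x=st.floats(1e-3, 50.0), t=st.floats(0.05, 0.95))
    @settings(deadline=None, max_examples=50)
    def test_exp_inverts_log(self, x, t):
        assert tempered_exp(tempered_log(x, t), t) == pytest.approx(
            x, rel=1e-8)


class TestTemperedSoftmax:
    def test_t2_one_is_standard_softmax(self):
        r = np.random.default_rng(0)
        a = r.normal(size=(50, 14))
        assert np.abs(tempered_softmax(a, 1.0) - softmax(a)).max() < 1e-8

    def test_equal_activations_give_uniform(self):
        p = tempered_softmax(np.full(14, 3.2), 2.0)
        assert np.allclose(p, 1 / 14, atol=1e-9)

    def test_matches_independent_bisection(self):
        a = np.array([2.0, 1.0, 0.5])
        lam = _bisect_lambda(a, 1.5)
        expected = tempered_exp(a - lam, 1.5)
        assert np.abs(tempered_softmax(a, 1.5) - expected).max() < 1e-10

    @given(t2=st.floats(1.0, 4.0), seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_outputs_are_distributions(self, t2, seed):
        a = np.random.default_rng(seed).normal(scale=4, size=(8, 14))
        p = tempered_softmax(a, t2)
        assert (p >= 0).all()
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-8

    def test_t2_one_ulp_above_one_is_stable(self):
        # regression: the direct power form of exp_t amplifies rounding by
        # 1/(1-t), blowing up the normalization for t2 barely above 1
        t2 = np.nextafter(1.0, 2.0)
        a = np.random.default_rng(0).normal(scale=5, size=(50, 14))
        p = tempered_softmax(a, t2)
        assert np.abs(p.sum(axis=1) - 1).max() < 1e-12
        assert np.abs(p - softmax(a)).max() < 1e-12

    def test_preserves_activation_order(self):
        a = np.array([3.0, -1.0, 0.5, 2.0])
        p = tempered_softmax(a, 1.8)
        assert np.array_equal(np.argsort(p), np.argsort(a))


class TestBiTempered:
    def test_limit_recovers_cross_entropy(self, random_batch):
        bt = bi_tempered_loss(random_batch, t1=1.0, t2=1.0)
        assert bt == pytest.approx(cross_entropy_loss(random_batch), abs=1e-6)

    def test_perfect_prediction_vanishes(self):
        b = PixelBatch(targets=[0], activations=np.array([[50.0, 0.0, -1.0]]))
        assert bi_tempered_loss(b, t1=0.8, t2=1.2) < 1e-4

    def test_matches_high_precision_oracle(self):
        a = np.array([[1.0, 0.0, -1.0]])
        t1, t2 = 0.8, 1.2
        lam = _bisect_lambda(a[0], t2)
        p = tempered_exp(a[0] - lam, t2)
        # tempered relative entropy with one-hot target at class 0
        expected = (-tempered_log(p[0], t1)
                    - (1 - p[0] ** (2 - t1)) / (2 - t1)
                    + sum(p[j] ** (2 - t1) / (2 - t1) for j in (1, 2)))
        got = bi_tempered_loss(PixelBatch(targets=[0], activations=a),
                               t1=t1, t2=t2)
        assert got == pytest.approx(expected, abs=1e-9)


class TestLovasz:
    def test_gradient_base_cases(self):
        assert np.array_equal(lovasz_gradient(np.array([1])), [1.0])
        assert np.array_equal(lovasz_gradient(np.array([1, 0])), [1.0, 0.0])

    def test_gradient_rejects_non_binary(self):
        with pytest.raises(ValueError):
            lovasz_gradient(np.array([0.5, 1.0]))

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60)
    def test_gradient_telescopes_to_jaccard_loss(self, bits):
        gt = np.array(bits)
        g = lovasz_gradient(gt)
        n_fg = gt.sum()
        # prefix of everything: intersection 0 unless no foreground at all
        expected = (1.0 - 0.0 / (n_fg + (len(bits) - n_fg))) if n_fg else 1.0
        assert g.sum() == pytest.approx(expected, abs=1e-12)

    def test_exact_prediction_is_zero(self):
        t = np.array([0, 1, 1, 0])
        p = np.zeros((4, 2))
        p[np.arange(4), t] = 1.0
        assert lovasz_softmax_loss(PixelBatch(targets=t, probabilities=p)) == 0

    def test_hard_predictions_equal_one_minus_iou(self):
        t = np.array([0, 0, 1, 1, 1, 0])
        pred = np.array([0, 1, 1, 1, 0, 0])
        p = np.zeros((6, 2))
        p[np.arange(6), pred] = 1.0
        per_class = []
        for c in (0, 1):
            inter = ((pred == c) & (t == c)).sum()
            union = ((pred == c) | (t == c)).sum()
            per_class.append(1 - inter / union)
        got = lovasz_softmax_loss(PixelBatch(targets=t, probabilities=p))
        assert got == pytest.approx(np.mean(per_class), abs=1e-12)

    def test_soft_predictions_match_interpolation_oracle(self):
        # Choquet form of the Lovász extension: sum over sorted error levels
        # of (m_(k) − m_(k+1)) · JaccardLoss(top-k prefix)
        r = np.random.default_rng(12)
        for _ in range(200):
            n, C = 6, r.integers(2, 4)
            p = softmax(r.normal(size=(n, C)))
            t = r.integers(0, C, size=n)
            terms = []
            for c in range(C):
                fg = (t == c).astype(float)
                m = np.abs(fg - p[:, c])
                order = np.argsort(-m, kind="stable")
                ms, gts = m[order], fg[order]
                total = gts.sum()
                acc, prev_j = 0.0, 0.0
                for k in range(1, n + 1):
                    inter = total - gts[:k].sum()
                    union = total + (1 - gts[:k]).sum()
                    jk = 1 - inter / union
                    acc += ms[k - 1] * (jk - prev_j)
                    prev_j = jk
                terms.append(acc)
            got = lovasz_softmax_loss(PixelBatch(targets=t, probabilities=p))
            assert got == pytest.approx(np.mean(terms), abs=1e-8)


class TestSharedInvariants:
    LOSSES = {
        "cross_entropy": lambda b: cross_entropy_loss(b),
        "focal": lambda b: focal_loss(b, 0.25, 2.0),
        "bi_tempered": lambda b: bi_tempered_loss(b, 0.8, 1.2),
        "lovasz_softmax": lambda b: lovasz_softmax_loss(b),
    }

    @pytest.mark.parametrize("name", sorted(LOSSES))
    def test_nonnegative_and_ignore_invariant(self, name, random_batch):
        fn = self.LOSSES[name]
        value = fn(random_batch)
        assert value >= 0
        # appending ignored pixels must not change the loss at all
        r = np.random.default_rng(1)
        extra_a = r.normal(size=(10, 5))
        bigger = PixelBatch.from_activations(
            np.vstack([random_batch.activations, extra_a]),
            np.concatenate([random_batch.targets, np.full(10, 255)]))
        assert fn(bigger) == pytest.approx(value, abs=1e-12)

    @pytest.mark.parametrize("kind", sorted(LOSSES))
    def test_analytic_gradients_match_central_differences(self, kind):
        r = np.random.default_rng(99)
        a = r.normal(size=(10, 4))
        t = r.integers(0, 4, size=10)
        p = softmax(a)
        if kind == "bi_tempered":
            _, ga = bi_tempered_loss(PixelBatch(targets=t, activations=a),
                                     0.8, 1.2, return_grad=True)
            gn = numeric_gradient(
                lambda x: bi_tempered_loss(
                    PixelBatch(targets=t, activations=x), 0.8, 1.2), a)
        elif kind == "cross_entropy":
            _, ga = cross_entropy_loss(PixelBatch(targets=t, probabilities=p),
                                       return_grad=True)
            gn = numeric_gradient(
                lambda q: cross_entropy_loss(
                    PixelBatch(targets=t, probabilities=q)), p)
        elif kind == "focal":
            _, ga = focal_loss(PixelBatch(targets=t, probabilities=p),
                               0.25, 2.0, return_grad=True)
            gn = numeric_gradient(
                lambda q: focal_loss(
                    PixelBatch(targets=t, probabilities=q), 0.25, 2.0), p)
        else:
            _, ga = lovasz_softmax_loss(PixelBatch(targets=t, probabilities=p),
                                        return_grad=True)
            gn = numeric_gradient(
                lambda q: lovasz_softmax_loss(
                    PixelBatch(targets=t, probabilities=q)), p)
        assert relative_error(ga, gn) <= 1e-3

    def test_segmentation_loss_grad_matches_numeric(self):
        r = np.random.default_rng(5)
        a = r.normal(size=(1, 4, 4, 3))
        t = r.integers(0, 3, size=(1, 4, 4))
        for kind in ("cross_entropy", "focal", "lovasz_softmax", "bi_tempered"):
            cfg = LossConfig(kind=kind)
            _, grad = segmentation_loss(a, t, cfg)
            gn = numeric_gradient(
                lambda x: segmentation_loss(x, t, cfg)[0], a)
            assert relative_error(grad, gn) <= 1e-3, kind


class TestLossConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            LossConfig(kind="dice")
        with pytest.raises(ValueError):
            LossConfig(t1=1.5)
        with pytest.raises(ValueError):
            LossConfig(t2=0.5)

    def test_round_trip(self):
        cfg = LossConfig(kind="focal", alpha=0.5, gamma=1.0)
        assert LossConfig.from_dict(cfg.to_dict()) == cfg
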