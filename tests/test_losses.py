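"""Loss formulas against hand-computed values, aggregation algebra, and a
finite-difference check of the gradients a center ships to the generator."""

import numpy as np
import pytest

from distsynth.features import IdentityExtractor, RandomConvExtractor
from distsynth.losses import (GradientPacket, LossWeights, aggregate_gradients,
                              discriminator_loss, generator_adversarial_grad,
                              generator_center_loss, l1_grad,
                              multimodal_generator_loss, pack_gradient_packet,
                              reminding_grad, reminding_loss,
                              unpack_gradient_packet)
from distsynth.nets import DiscriminatorSpec, build_discriminator

EPS = 1e-8


class TestDiscriminatorLoss:
    def test_perfect_discriminator_limit_is_zero(self):
        s = np.full((2, 1, 3, 3), 1.0 - EPS)
        f = np.full((2, 1, 3, 3), EPS)
        assert discriminator_loss(s, f, EPS) == pytest.approx(0.0, abs=1e-6)

    def test_uninformative_scores_give_two_log_two(self):
        s = np.full((4, 1, 2, 2), 0.5)
        assert discriminator_loss(s, s, EPS) == pytest.approx(2 * np.log(2),
                                                              abs=1e-12)

    def test_clamping_keeps_saturated_scores_finite(self):
        # worst case for both terms: real scored eps, fake scored 1 - eps
        s_r = np.full((1, 1, 2, 2), EPS)
        s_f = np.full((1, 1, 2, 2), 1.0 - EPS)
        val = discriminator_loss(s_r, s_f, EPS)
        assert np.isfinite(val)
        assert val == pytest.approx(-2 * np.log(EPS), rel=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            discriminator_loss(np.ones((1, 1, 2, 2)), np.ones((1, 1, 3, 3)))

    def test_nonnegative_and_minimized_at_correct_scores(self, rng):
        correct = discriminator_loss(np.full((1, 1, 2, 2), 1 - EPS),
                                     np.full((1, 1, 2, 2), EPS))
        for _ in range(20):
            s, f = rng.uniform(0.01, 0.99, (2, 1, 1, 2, 2))
            assert discriminator_loss(s, f) >= correct >= 0.0


class TestGeneratorCenterLoss:
    def test_identity_images_zero_reconstruction_terms(self, rng):
        y = rng.random((2, 1, 8, 8))
        w = LossWeights(lambda1=100.0, lambda2=10.0)
        ex = RandomConvExtractor(1, seed=0)
        total, terms = generator_center_loss(np.full((2, 1, 2, 2), 0.5), y,
                                             y.copy(), w, ex)
        assert terms["l1"] == 0.0 and terms["perceptual"] == 0.0
        assert total == pytest.approx(np.log(0.5), abs=1e-12)

    def test_adversarial_only_equals_log_half(self):
        y = np.zeros((1, 1, 4, 4))
        w = LossWeights(lambda1=0.0, lambda2=0.0)
        total, _ = generator_center_loss(np.full((1, 1, 2, 2), 0.5), y, y, w)
        assert total == pytest.approx(np.log(0.5), abs=1e-12)

    def test_constant_offset_l1_arithmetic(self):
        y = np.zeros((1, 1, 4, 4))
        yhat = y + 0.2
        w = LossWeights(lambda1=1.0, lambda2=0.0)
        total, _ = generator_center_loss(np.full((1, 1, 2, 2), 0.5), y, yhat, w)
        assert total == pytest.approx(np.log(0.5) + 0.2, abs=1e-12)

    def test_perceptual_without_extractor_rejected(self):
        y = np.zeros((1, 1, 4, 4))
        with pytest.raises(ValueError, match="extractor"):
            generator_center_loss(np.full((1, 1, 2, 2), 0.5), y, y,
                                  LossWeights(lambda2=10.0), None)


class TestAggregation:
    def test_single_center_identity(self, rng):
        g = rng.normal(size=(2, 1, 4, 4))
        out = aggregate_gradients([GradientPacket("A", g)], [1.0])
        assert np.allclose(out, g)

    def test_equal_weights_two_centers_halve_shared_gradient(self, rng):
        g = rng.normal(size=(2, 1, 4, 4))
        out = aggregate_gradients([GradientPacket("A", g.copy()),
                                   GradientPacket("B", g.copy())], [0.5, 0.5])
        assert np.allclose(out, g / 2)  # 1/N prefactor as printed

    def test_zero_weight_center_contributes_nothing(self, rng):
        g1, g2 = rng.normal(size=(2, 1, 1, 4, 4))
        out = aggregate_gradients([GradientPacket("A", g1),
                                   GradientPacket("B", g2)], [1.0, 0.0])
        assert np.allclose(out, g1 / 2)

    def test_linear_in_each_packet_and_permutation_invariant(self, rng):
        g1, g2, g3 = rng.normal(size=(3, 1, 1, 4, 4))
        w = [0.2, 0.5, 0.3]
        pk = lambda g: GradientPacket("x", g)
        base = aggregate_gradients([pk(g1), pk(g2), pk(g3)], w)
        scaled = aggregate_gradients([pk(2 * g1), pk(g2), pk(g3)], w)
        assert np.allclose(scaled - base, aggregate_gradients(
            [pk(g1), pk(0 * g2), pk(0 * g3)], w))
        perm = aggregate_gradients([pk(g3), pk(g1), pk(g2)],
                                   [w[2], w[0], w[1]])
        assert np.allclose(base, perm)

    def test_relaxed_prefactor_drops_centre_count(self, rng):
        g = rng.normal(size=(1, 1, 4, 4))
        out = aggregate_gradients([GradientPacket("A", g.copy()),
                                   GradientPacket("B", g.copy())], [0.5, 0.5],
                                  strict_prefactor=False)
        assert np.allclose(out, g)

    def test_empty_packets_rejected(self):
        with pytest.raises(ValueError):
            aggregate_gradients([], [])


class TestGradientAgainstFiniteDifferences:
    def test_shipped_gradient_matches_numerical_derivative(self, rng):
        """The aggregated per-center gradients must equal the numerical
        derivative of the pi-weighted sum of local generator losses with
        respect to the synthetic batch (4x4 toy, tolerance 1e-4)."""
        w = LossWeights(lambda1=3.0, lambda2=2.0, clamp_eps=1e-8)
        ex = IdentityExtractor()
        pis = np.array([0.7, 0.3])
        n = 2
        discs = [build_discriminator(
            DiscriminatorSpec(in_channels=2, layers=((4, 3, 2), (1, 3, 1))),
            seed=s) for s in (0, 1)]
        mask = rng.random((2, 1, 4, 4))
        y = rng.uniform(-0.5, 0.5, (2, 1, 4, 4))
        yhat = rng.uniform(-0.5, 0.5, (2, 1, 4, 4))

        def center_grad(d, yh):
            s = d.forward(mask, yh, train=False)
            g = d.backward_image(generator_adversarial_grad(s, w.clamp_eps), 1)
            d.zero_grad()
            g = g + w.lambda1 * l1_grad(y, yh)
            fy, fyh = ex.features(y), ex.features(yh)
            g = g + w.lambda2 * ex.features_grad(yh, 2 * (fyh - fy) / fy.size)
            return g

        def total_loss(yh):
            acc = 0.0
            for pi, d in zip(pis, discs):
                s = d.forward(mask, yh, train=False)
                t, _ = generator_center_loss(s, y, yh, w, ex)
                acc += pi * t
            return acc / (n * pis.sum())

        packets = [GradientPacket(f"c{i}", center_grad(d, yhat))
                   for i, d in enumerate(discs)]
        agg = aggregate_gradients(packets, pis, N=n)
        num = np.zeros_like(yhat)
        eps = 1e-6
        it = np.nditer(yhat, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            yp, ym = yhat.copy(), yhat.copy()
            yp[i] += eps
            ym[i] -= eps
            num[i] = (total_loss(yp) - total_loss(ym)) / (2 * eps)
        assert np.abs(agg - num).max() < 1e-4


class TestMultimodal:
    def _terms(self, rng, score=0.5):
        y = rng.random((2, 1, 4, 4))
        yhat = rng.random((2, 1, 4, 4))
        return (np.full((2, 1, 2, 2), score), y, yhat)

    def test_single_modality_reduces_to_center_loss(self, rng):
        w = LossWeights(lambda1=5.0, lambda2=0.0)
        t = self._terms(rng)
        total, _ = multimodal_generator_loss({0: t}, {0}, w)
        ref, _ = generator_center_loss(*t, w)
        assert total == pytest.approx(ref, abs=1e-12)

    def test_unavailable_modalities_never_enter_the_sum(self, rng):
        w = LossWeights(lambda1=5.0, lambda2=0.0)
        t0, t1 = self._terms(rng), self._terms(rng)
        total, breakdown = multimodal_generator_loss({0: t0, 1: t1}, {0, 1}, w)
        assert set(breakdown) == {0, 1}
        ref = sum(generator_center_loss(*t, w)[0] for t in (t0, t1))
        assert total == pytest.approx(ref, abs=1e-12)

    def test_supplying_a_modality_outside_cj_is_a_contract_violation(self, rng):
        w = LossWeights(lambda1=5.0, lambda2=0.0)
        with pytest.raises(ValueError, match="not in C_j"):
            multimodal_generator_loss({0: self._terms(rng),
                                       2: self._terms(rng)}, {0, 1}, w)

    def test_identical_modalities_sum_linearly(self, rng):
        w = LossWeights(lambda1=5.0, lambda2=0.0)
        t = self._terms(rng)
        total, _ = multimodal_generator_loss({0: t, 1: t, 2: t}, {0, 1, 2}, w)
        single, _ = generator_center_loss(*t, w)
        assert total == pytest.approx(3 * single, abs=1e-12)


class TestReminding:
    def test_identical_generators_give_zero(self, rng):
        a = rng.normal(size=(2, 1, 8, 8))
        assert reminding_loss(a, a.copy()) == 0.0

    def test_constant_offset_mean_square(self, rng):
        a = rng.normal(size=(2, 1, 8, 8))
        assert reminding_loss(a + 0.1, a) == pytest.approx(0.01, abs=1e-12)

    def test_gradient_is_derivative_of_mean_square(self, rng):
        a = rng.normal(size=(1, 1, 4, 4))
        b = rng.normal(size=(1, 1, 4, 4))
        g = reminding_grad(a, b)
        eps = 1e-6
        i = (0, 0, 2, 3)
        ap = a.copy()
        ap[i] += eps
        am = a.copy()
        am[i] -= eps
        num = (reminding_loss(ap, b) - reminding_loss(am, b)) / (2 * eps)
        assert g[i] == pytest.approx(num, abs=1e-9)


def test_gradient_packet_wire_roundtrip(rng):
    p = GradientPacket("center-7", rng.normal(size=(2, 3, 4, 4)),
                       {"l1": 0.5, "adversarial": -0.7})
    q = unpack_gradient_packet(pack_gradient_packet(p))
    assert q.center_id == p.center_id
    assert np.array_equal(q.grad, p.grad)
    assert q.losses == pytest.approx(p.losses)


def test_non_finite_gradients_rejected():
    with pytest.raises(ValueError, match="non-finite"):
        GradientPacket("A", np.array([np.inf]))
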