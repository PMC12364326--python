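import numpy as np
import pytest

from heeseggan.errors import ShapeError
from heeseggan.generator import GeneratorConfig, build_generator
from heeseggan.losses import (LossWeights, adversarial_loss,
                              aggregated_mask_loss, balanced_positive_weight,
                              dice_loss, discriminator_loss, edge_loss,
                              generator_loss, weighted_bce_level)
from heeseggan.nn import Tensor
from heeseggan.preprocessing import build_pyramid, extract_edge_map


def bce_oracle(logits, label, weight):
    """Per-pixel double-loop reference of the balanced BCE sum."""
    total = 0.0
    for i in range(logits.shape[0]):
        for j in range(logits.shape[1]):
            s = 1 / (1 + np.exp(-logits[i, j]))
            y = label[i, j]
            total -= weight * y * np.log(s) + (1 - y) * np.log(1 - s)
    return total


class TestAdversarial:
    def test_identical_scores(self):
        assert adversarial_loss(0.3, 0.3).item() == pytest.approx(0.0)

    def test_gap(self):
        assert adversarial_loss(0.7, 0.3).item() == pytest.approx(0.4)

    def test_symmetric(self, rng):
        a, b = rng.normal(size=2)
        assert adversarial_loss(a, b).item() == pytest.approx(
            adversarial_loss(b, a).item())


class TestBalancedWeight:
    def test_all_zero_label(self):
        assert balanced_positive_weight(np.zeros((8, 8))) == 1.0

    def test_equal_counts(self):
        label = np.zeros((4, 4))
        label[:2] = 1
        assert balanced_positive_weight(label) == 1.0

    def test_direct_ratio(self):
        label = np.zeros((16, 16))
        label[0, :4] = 1
        assert balanced_positive_weight(label) == pytest.approx(252 / 4)

    def test_batched(self):
        labels = np.zeros((2, 4, 4))
        labels[0, 0, 0] = 1
        w = balanced_positive_weight(labels)
        np.testing.assert_allclose(w, [15.0, 1.0])


class TestWeightedBCE:
    def test_perfect_prediction_limit(self):
        label = np.zeros((8, 8))
        label[2:4, 2:4] = 1
        logits = np.where(label > 0, 100.0, -100.0)
        assert weighted_bce_level(Tensor(logits), label, 5.0).item() < 1e-8

    def test_single_pixel_closed_form(self):
        loss = weighted_bce_level(Tensor(np.zeros((1, 1))),
                                  np.ones((1, 1)), 1.0)
        assert loss.item() == pytest.approx(np.log(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_instance_matches_oracle(self, seed):
        r = np.random.default_rng(seed)
        logits = r.normal(size=(8, 8))
        label = (r.random((8, 8)) > 0.7).astype(float)
        weight = float(r.uniform(0.5, 8.0))
        ours = weighted_bce_level(Tensor(logits), label, weight).item()
        assert ours == pytest.approx(bce_oracle(logits, label, weight), abs=1e-9)

    def test_batched_is_mean_of_per_image_sums(self, rng):
        logits = rng.normal(size=(3, 4, 4))
        label = (rng.random((3, 4, 4)) > 0.5).astype(float)
        w = balanced_positive_weight(label)
        batched = weighted_bce_level(Tensor(logits), label, w).item()
        singles = [weighted_bce_level(Tensor(logits[i]), label[i],
                                      float(w[i])).item() for i in range(3)]
        assert batched == pytest.approx(np.mean(singles), abs=1e-9)

    def test_mean_reduction_mode(self, rng):
        logits = rng.normal(size=(4, 4))
        label = np.zeros((4, 4))
        s = weighted_bce_level(Tensor(logits), label, 1.0, reduction="sum").item()
        m = weighted_bce_level(Tensor(logits), label, 1.0, reduction="mean").item()
        assert m == pytest.approx(s / 16)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ShapeError):
            weighted_bce_level(Tensor(rng.normal(size=(4, 4))),
                               np.zeros((8, 8)), 1.0)


def make_pyramid_case(seed=0, size=16):
    r = np.random.default_rng(seed)
    logits = [Tensor(r.normal(size=(size // 2 ** k, size // 2 ** k)))
              for k in range(4)]
    labels = [(r.random((size // 2 ** k, size // 2 ** k)) > 0.8).astype(np.uint8)
              for k in range(4)]
    return logits, labels


class TestAggregatedMaskLoss:
    def test_perfect_prediction_vanishes(self):
        _, labels = make_pyramid_case()
        logits = [Tensor(np.where(lv > 0, 100.0, -100.0)) for lv in labels]
        total, _, _ = aggregated_mask_loss(logits, labels)
        assert total.item() < 1e-7

    def test_additivity(self):
        logits, labels = make_pyramid_case(3)
        total, per_level, weights = aggregated_mask_loss(logits, labels)
        assert total.item() == pytest.approx(
            sum(l.item() for l in per_level), abs=1e-9)
        manual = sum(weighted_bce_level(s, y, balanced_positive_weight(y)).item()
                     for s, y in zip(logits, labels))
        assert total.item() == pytest.approx(manual, abs=1e-9)

    def test_per_level_weight_recomputed(self):
        # a 16x16 level-4 label with exactly 1 positive uses w = 255 there only
        labels = [np.zeros((16 // 2 ** k, 16 // 2 ** k), dtype=np.uint8)
                  for k in range(4)]
        labels[3][0, 0] = 1  # level 4: 2x2... actually 16/8 = 2x2 grid
        labels[0][:8, :] = 1
        logits = [Tensor(np.zeros_like(lv, dtype=float)) for lv in labels]
        _, _, weights = aggregated_mask_loss(logits, labels)
        assert weights[0] == pytest.approx(1.0)
        assert weights[3] == pytest.approx(3.0)  # 2x2 grid, 1 positive

    def test_level4_256px_single_positive(self):
        label = np.zeros((16, 16), dtype=np.uint8)
        label[5, 7] = 1
        assert balanced_positive_weight(label) == pytest.approx(255.0)

    def test_level_count_mismatch(self):
        logits, labels = make_pyramid_case()
        with pytest.raises(ValueError):
            aggregated_mask_loss(logits[:3], labels)


class TestDiscriminatorLoss:
    def test_values(self):
        assert discriminator_loss(0.4, 0.6).item() == pytest.approx(-1.0)
        assert discriminator_loss(0.0, 0.0).item() == pytest.approx(0.0)

    def test_monotone_in_adversarial_gap(self):
        l1 = discriminator_loss(0.2, 1.0).item()
        l2 = discriminator_loss(0.5, 1.0).item()
        assert l2 < l1

    def test_nonpositive_for_nonnegative_terms(self, rng):
        la, lds = rng.random(2)
        assert discriminator_loss(la, lds).item() <= 0


class TestEdgeLoss:
    def test_empty_edges_strong_negatives_vanish(self):
        labels = [np.zeros((16 // 2 ** k, 16 // 2 ** k), dtype=np.uint8)
                  for k in range(4)]
        logits = [Tensor(np.full(lv.shape, -100.0)) for lv in labels]
        total, _, _ = edge_loss(logits, labels)
        assert total.item() < 1e-8

    def test_definitional_decomposition(self):
        logits, labels = make_pyramid_case(5)
        total, per_level, _ = edge_loss(logits, labels)
        manual = sum(weighted_bce_level(s, y, balanced_positive_weight(y)).item()
                     for s, y in zip(logits, labels))
        assert total.item() == pytest.approx(manual, abs=1e-9)

    def test_single_level_toy_oracle(self):
        r = np.random.default_rng(9)
        logits = r.normal(size=(16, 16))
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[4:12, 4:12] = 1
        edge = extract_edge_map(mask)
        w = balanced_positive_weight(edge)
        ours = weighted_bce_level(Tensor(logits), edge.astype(float), w).item()
        assert ours == pytest.approx(bce_oracle(logits, edge, w), abs=1e-9)


class TestDice:
    def test_perfect_overlap(self, rng):
        truth = (rng.random((8, 8)) > 0.5).astype(float)
        assert dice_loss(Tensor(truth), truth).item() == pytest.approx(0.0, abs=1e-6)

    def test_disjoint(self):
        pred = np.zeros((4, 4))
        pred[0, 0] = 1
        truth = np.zeros((4, 4))
        truth[3, 3] = 1
        assert dice_loss(Tensor(pred), truth).item() == pytest.approx(1.0, abs=1e-5)

    def test_half_overlap(self):
        pred = np.zeros((4, 4))
        pred[0, :4] = 1
        truth = np.zeros((4, 4))
        truth[0, 2:] = 1
        truth[1, :2] = 1
        assert dice_loss(Tensor(pred), truth).item() == pytest.approx(0.5, abs=1e-6)

    def test_empty_both_is_zero_loss(self):
        assert dice_loss(Tensor(np.zeros((4, 4))),
                         np.zeros((4, 4))).item() == pytest.approx(0.0)

    def test_in_unit_interval(self, rng):
        pred = rng.random((8, 8))
        truth = (rng.random((8, 8)) > 0.5).astype(float)
        assert 0.0 <= dice_loss(Tensor(pred), truth).item() <= 1.0


class TestGeneratorLoss:
    def test_adversarial_only_ablation(self):
        w = LossWeights(omega_e=0.0, omega_s=0.0)
        assert generator_loss(0.37, 5.0, 0.9, w).item() == pytest.approx(0.37)

    def test_weighted_sum(self):
        assert generator_loss(0.1, 2.0, 0.5, LossWeights(1, 1)).item() \
            == pytest.approx(2.6)

    def test_linearity_in_each_term(self, rng):
        la, lge, lgs = rng.random(3)
        w = LossWeights(2.0, 3.0)
        base = generator_loss(la, lge, lgs, w).item()
        assert generator_loss(la + 1, lge, lgs, w).item() \
            == pytest.approx(base + 1)
        assert generator_loss(la, lge + 1, lgs, w).item() \
            == pytest.approx(base + 2)
        assert generator_loss(la, lge, lgs + 1, w).item() \
            == pytest.approx(base + 3)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(omega_e=-1.0)


class TestEdgeGradientFocus:
    def test_edge_pixels_receive_larger_gradients(self):
        """With the edge loss on, untrained side-output gradients are larger
        on true edge pixels than on background (class balancing at work)."""
        wins = 0
        for seed in range(5):
            gen = build_generator(GeneratorConfig(base_widths=(4, 8, 16, 32)),
                                  np.random.default_rng(seed))
            r = np.random.default_rng(seed + 50)
            x = r.random((1, 3, 32, 32))
            mask = np.zeros((32, 32), dtype=np.uint8)
            mask[10:22, 10:22] = 1
            edge = extract_edge_map(mask)
            pyramid = build_pyramid(edge, kind="edge")
            pred = gen(x)
            total, _, _ = edge_loss(pred.side.native,
                                    [l[None] for l in pyramid.levels])
            total.backward()
            g = np.abs(pred.side.native[0].grad[0, 0])
            edge_mag = g[edge.astype(bool)].mean()
            bg = ~mask.astype(bool)
            bg_mag = g[bg].mean()
            if edge_mag > bg_mag:
                wins += 1
        assert wins >= 4
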