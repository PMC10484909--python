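"""Segmentation metrics against hand counts and exhaustive brute-force
oracles, plus the U-Net training contract."""

import numpy as np
import pytest

from distsynth.datagen import CenterSpec, PhantomSpec, make_center_data
from distsynth.downstream import (SegConfig, aji, boundary, dice, evaluate, hd,
                                  hd95, object_dice, surface_distance,
                                  train_segmenter)


def _mask(shape, coords):
    m = np.zeros(shape, dtype=bool)
    for r, c in coords:
        m[r, c] = True
    return m


from _brute import (brute_aji as _brute_aji, brute_boundary as _brute_boundary,
                    brute_dice as _brute_dice, brute_hd95 as _brute_hd95,
                    brute_sd as _brute_sd)


# ---------------------------------------------------------------------------

class TestDice:
    def test_identical_nonempty_masks(self):
        m = _mask((8, 8), [(2, 2), (2, 3)])
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = _mask((8, 8), [(0, 0)])
        b = _mask((8, 8), [(5, 5)])
        assert dice(a, b) == 0.0

    def test_half_overlap_pixel_counts(self):
        a = _mask((8, 8), [(1, 1), (1, 2), (2, 1), (2, 2)])
        b = _mask((8, 8), [(2, 1), (2, 2), (3, 1), (3, 2)])
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), dtype=bool)
        assert dice(z, z) == 1.0


class TestBoundaryDistances:
    def test_identical_masks_zero(self):
        m = np.zeros((10, 10), dtype=bool)
        m[3:7, 3:7] = True
        assert hd95(m, m) == 0.0
        assert surface_distance(m, m) == 0.0
        assert hd(m, m) == 0.0

    def test_single_pixels_five_apart(self):
        a = _mask((10, 10), [(2, 2)])
        b = _mask((10, 10), [(2, 7)])
        assert hd95(a, b) == pytest.approx(5.0)
        assert surface_distance(a, b) == pytest.approx(5.0)
        assert hd(a, b) == pytest.approx(5.0)

    def test_empty_mask_is_undefined(self):
        m = _mask((4, 4), [(1, 1)])
        with pytest.raises(ValueError, match="empty"):
            hd95(m, np.zeros((4, 4), dtype=bool))

    def test_boundary_excludes_interior_pixels(self):
        m = np.zeros((6, 6), dtype=bool)
        m[1:5, 1:5] = True
        pts = {tuple(p) for p in boundary(m)}
        assert (2, 2) not in pts and (1, 1) in pts
        assert pts == {tuple(p) for p in _brute_boundary(m)}


class TestAji:
    def test_perfect_single_object(self):
        g = np.zeros((6, 6), dtype=int)
        g[2:4, 2:4] = 1
        assert aji(g, g) == 1.0

    def test_partial_match_counts(self):
        g = np.zeros((6, 6), dtype=int)
        g[1, 1:5] = 1                      # 4-pixel object
        s = np.zeros((6, 6), dtype=int)
        s[1, 1:3] = 1                      # 2-pixel subset: 2 / 4
        assert aji(g, s) == pytest.approx(0.5)

    def test_spurious_object_enters_denominator(self):
        g = np.zeros((6, 6), dtype=int)
        g[1, 1:5] = 1
        s = np.zeros((6, 6), dtype=int)
        s[1, 1:5] = 1                      # perfect 4-pixel match
        s[4, 0:2] = 2                      # spurious 2-pixel object
        assert aji(g, s) == pytest.approx(4 / 6)

    def test_empty_maps_zero_by_convention(self):
        z = np.zeros((4, 4), dtype=int)
        assert aji(z, z) == 0.0

    def test_object_dice_perfect_and_empty(self):
        g = np.zeros((6, 6), dtype=int)
        g[2:4, 2:4] = 1
        assert object_dice(g, g) == 1.0
        assert object_dice(g, np.zeros_like(g)) == 0.0


class TestOracleEquivalence:
    def test_metrics_match_brute_force_on_random_instances(self):
        """Random 16x16 instance maps: Dice/HD95/SD/AJI must agree exactly
        with exhaustive per-pixel implementations."""
        from scipy.ndimage import label
        rng = np.random.default_rng(42)
        for _ in range(50):
            gt = (rng.random((16, 16)) < 0.35)
            seg = (rng.random((16, 16)) < 0.35)
            assert dice(gt, seg) == pytest.approx(_brute_dice(gt, seg), abs=1e-12)
            if gt.any() and seg.any():
                assert hd95(gt, seg) == pytest.approx(_brute_hd95(gt, seg),
                                                      abs=1e-12)
                assert surface_distance(gt, seg) == pytest.approx(
                    _brute_sd(gt, seg), abs=1e-12)
            gti, _ = label(gt)
            segi, _ = label(seg)
            assert aji(gti, segi) == pytest.approx(_brute_aji(gti, segi),
                                                   abs=1e-12)


class TestTrainSegmenter:
    def _data(self, n, seed=0):
        phantom = PhantomSpec(image_size=16, n_classes=2,
                              intensity_table=((0.1,), (0.45,), (0.8,)),
                              noise_sd=0.02)
        d = make_center_data(CenterSpec("A", n, (0,), seed=seed), phantom)
        return d.masks, d.images

    def test_eighty_twenty_split(self):
        masks, images = self._data(10)
        _, hist = train_segmenter(masks, images, 2,
                                  SegConfig(epochs=1, seed=0))
        assert (hist["n_train"], hist["n_val"]) == (8, 2)

    def test_too_few_samples_rejected(self):
        masks, images = self._data(4)
        with pytest.raises(ValueError, match="at least 5"):
            train_segmenter(masks, images, 2, SegConfig())

    def test_fixed_seed_reproduces_training_curve(self):
        masks, images = self._data(8)
        cfg = SegConfig(epochs=3, width=4, seed=5)
        _, h1 = train_segmenter(masks, images, 2, cfg)
        _, h2 = train_segmenter(masks, images, 2, cfg)
        assert h1["loss"] == h2["loss"]
        assert h1["val_dice"] == h2["val_dice"]

    def test_learnable_by_construction_reaches_high_dice(self):
        """Intensity deterministically encodes the class, so a competent
        trainer must reach Dice > 0.9 on held-out data."""
        masks, images = self._data(24, seed=3)
        model, _ = train_segmenter(masks, images, 2,
                                   SegConfig(epochs=30, width=8, seed=0))
        tmasks, timages = self._data(10, seed=77)
        res = evaluate(model, tmasks, timages, 2)
        assert res.mean_dice > 0.9


class TestEvaluate:
    def test_sd_uses_divisor_n(self):
        # {0.8, 1.0}: sd = 0.1 under divisor n, 0.1414 under n-1
        assert np.std([0.8, 1.0]) == pytest.approx(0.1)

    def test_perfect_and_trivial_predictors(self):
        masks, images = TestTrainSegmenter()._data(10, seed=1)

        class Oracle:
            def forward(self, x, train=False):
                out = np.zeros((x.shape[0], 3, *x.shape[2:]))
                for i, m in enumerate(self._truth):
                    for c in range(3):
                        out[i, c] = (m == c) * 10.0
                return out

        oracle = Oracle()
        oracle._truth = masks
        res = evaluate(oracle, masks, images, 2)
        assert res.mean_dice == pytest.approx(1.0)
        for c in (1, 2):
            assert res.aggregate[c]["dice_sd"] == 0.0
            assert res.aggregate[c]["hd95_mean"] == 0.0
            assert res.aggregate[c]["sd_mean"] == 0.0

        class Background:
            def forward(self, x, train=False):
                out = np.zeros((x.shape[0], 3, *x.shape[2:]))
                out[:, 0] = 10.0
                return out

        res0 = evaluate(Background(), masks, images, 2)
        assert res0.mean_dice == pytest.approx(0.0)
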