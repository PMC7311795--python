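import numpy as np
import pytest
from scipy.ndimage import binary_dilation

from caliperase import annotate, coarse, inpaint, phantom
from caliperase.inpaint import (
    ContractError,
    InsufficientContextError,
    TexSynthParams,
    inpaint_quality,
    inpaint_texture,
    locate_markers,
    mean_fill,
)


def glyph_fixture(seed):
    """(annotated image, dilated mask, original) from a seeded phantom."""
    ds = phantom.render_dataset(phantom.PhantomConfig(n_train=1, n_test=0),
                                seed=seed)
    item = ds.items[0]
    ann = annotate.annotate_phantom(item.image, item.nodules, seed=seed + 500)
    mask = annotate.marker_mask(ann.groups, ann.glyph, item.image.shape,
                                dilation=1)
    return ann.image, mask, item.image


class TestTextureSynthesis:
    def test_empty_mask_is_identity(self):
        img = phantom.generate_background(64, 64, seed=0)
        res = inpaint_texture(img, np.zeros_like(img, dtype=bool), seed=0)
        np.testing.assert_array_equal(res.image, img)

    def test_full_mask_rejected(self):
        img = phantom.generate_background(64, 64, seed=0)
        with pytest.raises(InsufficientContextError):
            inpaint_texture(img, np.ones_like(img, dtype=bool))

    def test_outside_mask_bit_exact(self):
        corrupted, mask, _ = glyph_fixture(1)
        res = inpaint_texture(corrupted, mask, seed=0)
        np.testing.assert_array_equal(res.image[~mask], corrupted[~mask])
        assert res.image[mask].min() >= 0 and res.image[mask].max() <= 1

    def test_periodic_texture_hole_recovered_exactly(self):
        """A periodic pattern with period <= window admits an exact refill."""
        base = np.add.outer(np.arange(48), np.arange(48))
        img = 0.3 + 0.4 * ((np.sin(base * 2 * np.pi / 4) + 1) / 2)
        mask = np.zeros_like(img, dtype=bool)
        mask[20:24, 20:24] = True  # one 4x4 period
        corrupted = img.copy()
        corrupted[mask] = 0.0
        res = inpaint_texture(corrupted, mask, TexSynthParams(patch_radius=4),
                              seed=0)
        mse = float(((res.image[mask] - img[mask]) ** 2).mean())
        assert mse < 1e-6

    def test_beats_mean_fill_on_glyph_masks(self):
        wins = 0
        for seed in range(5):
            corrupted, mask, original = glyph_fixture(seed)
            res = inpaint_texture(corrupted, mask, seed=seed)
            tex = inpaint_quality(original, res.image, mask)["masked_mse"]
            mf = inpaint_quality(original, mean_fill(corrupted, mask),
                                 mask)["masked_mse"]
            wins += int(tex < mf)
        assert wins >= 4

    def test_single_pixel_matches_brute_force_argmin(self):
        """One missing pixel: chosen source equals the global SSD argmin."""
        img = phantom.generate_background(48, 48, seed=3)
        mask = np.zeros_like(img, dtype=bool)
        mask[24, 25] = True
        params = TexSynthParams(patch_radius=3, tolerance=0.0)
        res = inpaint_texture(img, mask, params, seed=0)
        p = 2 * params.patch_radius + 1
        # brute force over all fully-known patches
        best, best_val = None, np.inf
        known = ~mask
        target = img * known
        for r in range(48 - p + 1):
            for c in range(48 - p + 1):
                if mask[r:r + p, c:c + p].any():
                    continue
                patch = img[r:r + p, c:c + p]
                tpatch = target[24 - 3:24 + 4, 25 - 3:25 + 4]
                w = known[24 - 3:24 + 4, 25 - 3:25 + 4]
                ssd = float((((patch - tpatch) ** 2) * w).sum())
                if ssd < best_val - 1e-15:
                    best_val, best = ssd, patch[3, 3]
        assert res.image[24, 25] == pytest.approx(best, abs=1e-12)

    def test_seeded_determinism(self):
        corrupted, mask, _ = glyph_fixture(2)
        a = inpaint_texture(corrupted, mask, seed=5).image
        b = inpaint_texture(corrupted, mask, seed=5).image
        np.testing.assert_array_equal(a, b)

    def test_priority_fill_strategy_runs(self):
        corrupted, mask, _ = glyph_fixture(4)
        params = TexSynthParams(fill_strategy="priority")
        res = inpaint_texture(corrupted, mask, params, seed=0)
        np.testing.assert_array_equal(res.image[~mask], corrupted[~mask])

    def test_mse_degrades_with_mask_dilation(self):
        """Statistically, larger holes are harder to refill."""
        small, large = [], []
        for seed in range(8):
            corrupted, mask, original = glyph_fixture(seed + 20)
            big = binary_dilation(mask, iterations=2)
            small.append(inpaint_quality(
                original, inpaint_texture(corrupted, mask, seed=0).image,
                mask)["masked_mse"])
            large.append(inpaint_quality(
                original, inpaint_texture(corrupted, big, seed=0).image,
                big)["masked_mse"])
        assert np.mean(large) >= np.mean(small)


class TestLocateMarkers:
    def test_dice_against_oracle_mask(self):
        ds = phantom.render_dataset(phantom.PhantomConfig(n_train=1, n_test=0),
                                    seed=6)
        ann = annotate.annotate_phantom(ds.items[0].image, ds.items[0].nodules,
                                        seed=106)
        located = locate_markers(ann.image)
        oracle = binary_dilation(ann.mask)
        dice = 2 * (located & oracle).sum() / (located.sum() + oracle.sum())
        assert dice >= 0.9

    def test_no_false_positives_on_marker_free_phantom(self):
        for seed in range(5):
            img = phantom.render_dataset(
                phantom.PhantomConfig(n_train=1, n_test=0), seed=seed).items[0].image
            fp = locate_markers(img, threshold=0.8).sum() / img.size
            assert fp < 0.005

    def test_blank_image_gives_empty_mask(self):
        assert locate_markers(np.full((64, 64), 0.5)).sum() == 0


class TestQuality:
    def test_identity_gives_zero_mse_capped_psnr(self):
        img = phantom.generate_background(32, 32, seed=0)
        mask = np.zeros_like(img, dtype=bool)
        mask[4:8, 4:8] = True
        q = inpaint_quality(img, img.copy(), mask)
        assert q["masked_mse"] == 0.0
        assert q["masked_psnr"] == inpaint.PSNR_CAP

    def test_constant_offset_arithmetic(self):
        img = np.full((32, 32), 0.4)
        mask = np.zeros_like(img, dtype=bool)
        mask[10:20, 10:20] = True
        restored = img.copy()
        restored[mask] += 0.1
        assert inpaint_quality(img, restored, mask)["masked_mse"] == \
            pytest.approx(0.01)

    def test_independent_of_outside_pixels(self):
        img = phantom.generate_background(32, 32, seed=1)
        mask = np.zeros_like(img, dtype=bool)
        mask[4:8, 4:8] = True
        restored = img + 0.05
        restored[mask] = img[mask]
        assert inpaint_quality(img, restored, mask)["masked_mse"] == 0.0

    def test_empty_mask_rejected(self):
        img = np.zeros((16, 16))
        with pytest.raises(ContractError):
            inpaint_quality(img, img, np.zeros_like(img, dtype=bool))


class TestCoarseNet:
    @pytest.fixture(scope="class")
    def triples(self):
        return [glyph_fixture(seed) for seed in range(55)]

    @pytest.fixture(scope="class")
    def trained(self, triples):
        cfg = coarse.CoarseNetConfig(epochs=40)
        return coarse.train_coarse_net(triples[:50], cfg, seed=0)

    def test_training_beats_untrained_on_holdout(self, trained, triples):
        held = triples[50:]
        untrained = coarse.init_coarse_net(trained.config, seed=0)
        assert coarse.masked_l1(trained, held) < coarse.masked_l1(untrained, held)

    def test_seeded_determinism(self, triples, trained):
        again = coarse.train_coarse_net(triples[:50],
                                        coarse.CoarseNetConfig(epochs=40), seed=0)
        assert again.history[-1] == trained.history[-1]

    def test_masked_mse_within_band_of_texture_synthesis(self, trained, triples):
        ratios = []
        for corrupted, mask, original in triples[50:]:
            mc = inpaint_quality(original,
                                 coarse.inpaint_coarse(trained, corrupted, mask).image,
                                 mask)["masked_mse"]
            mt = inpaint_quality(original,
                                 inpaint_texture(corrupted, mask, seed=1).image,
                                 mask)["masked_mse"]
            ratios.append(mc / mt)
        assert np.mean(ratios) <= 1.5

    def test_outside_mask_preserved(self, trained, triples):
        corrupted, mask, _ = triples[50]
        res = coarse.inpaint_coarse(trained, corrupted, mask)
        np.testing.assert_array_equal(res.image[~mask], corrupted[~mask])

    def test_too_few_pairs_rejected(self, triples):
        with pytest.raises(coarse.DataError):
            coarse.train_coarse_net(triples[:10])
        with pytest.raises(coarse.DataError):
            coarse.train_coarse_net([])
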