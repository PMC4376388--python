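"""Vessel pipeline: down-sampling, segmentation, artefact cleanup, thinning."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from retfractal.phantom import PhantomParams, generate_phantom
from retfractal.vessel import (
    clean_artifacts,
    count_components,
    downsample,
    segment_vessels,
    skeletonize,
)


def dice(a, b):
    return 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


class TestDownsample:
    def test_target_shape(self):
        img = np.random.default_rng(0).random((2048, 3072))
        out = downsample(img)
        assert out.shape == (685, 584)

    def test_identity_at_native_shape(self):
        img = np.random.default_rng(1).random((100, 120))
        out = downsample(img, (100, 120))
        np.testing.assert_array_equal(out, img)

    def test_constant_preserved(self):
        img = np.full((400, 400), 0.37)
        out = downsample(img, (100, 100))
        assert np.allclose(out, 0.37)

    def test_upsampling_refused(self):
        with pytest.raises(ValueError, match="upsample"):
            downsample(np.zeros((100, 100)), (200, 200))

    def test_mask_downsampling_stays_binary(self):
        mask = np.zeros((200, 200), dtype=bool)
        mask[50:150, 50:150] = True
        out = downsample(mask, (100, 100), is_mask=True)
        assert out.dtype == bool
        assert 0 < out.sum() < out.size


class TestSegmentVessels:
    def test_dice_against_truth_noise_free(self, phantom):
        mask = segment_vessels(phantom.intensity_image)
        assert dice(mask, phantom.truth_mask) >= 0.8

    def test_constant_image_yields_empty_mask(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = segment_vessels(np.full((128, 128), 0.5))
        assert not mask.any()

    def test_component_count_near_truth_extreme_contrast(self, phantom):
        img = np.where(phantom.truth_mask, 0.0, 1.0)
        mask = segment_vessels(img)
        assert abs(count_components(mask) - count_components(phantom.truth_mask)) <= 2

    def test_dice_nonincreasing_in_noise(self):
        """Segmentation quality degrades (weakly) with rendering noise."""
        levels = (0.0, 0.05, 0.10)
        means = []
        for noise in levels:
            scores = []
            for seed in range(4):
                ph = generate_phantom(PhantomParams(noise_level=noise), seed=seed)
                scores.append(dice(segment_vessels(ph.intensity_image), ph.truth_mask))
            means.append(np.mean(scores))
        assert means[0] >= means[1] - 0.02
        assert means[1] >= means[2] - 0.02


class TestCleanArtifacts:
    def test_speck_removed_tree_kept(self, phantom):
        mask = phantom.truth_mask.copy()
        mask[5:7, 300:302] = True  # 4-px speck away from the border ring
        out = clean_artifacts(mask, min_component=10, border_ring_width=0)
        assert not out[5:7, 300:302].any()
        assert (out & phantom.truth_mask).sum() == phantom.truth_mask.sum()

    def test_empty_in_empty_out(self):
        out = clean_artifacts(np.zeros((64, 64), dtype=bool))
        assert not out.any()

    def test_dust_ring_removed_tree_untouched(self):
        h, w = 256, 256
        mask = np.zeros((h, w), dtype=bool)
        mask[100:150, 100:150] = True  # central "tree", disjoint from the ring
        tree_count = mask.sum()
        yy, xx = np.ogrid[:h, :w]
        radius = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2)
        ring = (radius > 124) & (radius <= 127)
        out = clean_artifacts(mask | ring, min_component=10, border_ring_width=5)
        assert out.sum() == tree_count
        assert out[100:150, 100:150].all()

    def test_monotone_and_idempotent(self, phantom):
        noisy = phantom.truth_mask.copy()
        rng = np.random.default_rng(8)
        noisy[rng.integers(0, 685, 300), rng.integers(0, 584, 300)] = True
        once = clean_artifacts(noisy)
        assert not (once & ~noisy).any()  # never adds pixels
        np.testing.assert_array_equal(clean_artifacts(once), once)


class TestSkeletonize:
    def test_bar_collapses_to_line(self):
        mask = np.zeros((64, 128), dtype=bool)
        mask[30:35, 10:110] = True
        skel = skeletonize(mask)
        assert count_components(skel) == 1
        # one pixel wide: every occupied column in the bar has exactly 1 pixel
        cols = skel[:, 15:105].sum(axis=0)
        assert (cols == 1).all()

    def test_idempotent_on_thin_line(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[32, 5:60] = True
        np.testing.assert_array_equal(skeletonize(mask), mask)

    def test_plus_sign_junction_census(self):
        """Crossing bars thin to a skeleton with 4 endpoints and a junction."""
        mask = np.zeros((101, 101), dtype=bool)
        mask[48:53, 10:91] = True
        mask[10:91, 48:53] = True
        skel = skeletonize(mask)
        assert count_components(skel) == 1
        from scipy import ndimage as ndi

        neigh = ndi.convolve(skel.astype(int), np.ones((3, 3), int), mode="constant")
        degree = np.where(skel, neigh - 1, 0)
        assert (degree == 1).sum() == 4  # endpoints
        n4 = (degree >= 4).sum()
        n3 = (degree == 3).sum()
        assert n4 >= 1 or n3 >= 2  # one X-junction or two T-junctions

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            skel = skeletonize(np.zeros((32, 32), dtype=bool))
        assert not skel.any()

    @pytest.mark.parametrize("seed", range(12))
    def test_component_count_preserved_on_phantoms(self, seed):
        ph = generate_phantom(PhantomParams(depth=4, initial_length=60), seed=seed)
        mask = ph.truth_mask
        assert count_components(skeletonize(mask)) == count_components(mask)
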