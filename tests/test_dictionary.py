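import warnings

import numpy as np
import pytest

from pcbc.dictionary import (Patch, agglomerative_cluster, build_stage1_network,
                             extract_keypoint_patches,
                             extract_whole_image_patches, harris_keypoints)
from pcbc.preprocess import local_contrast, zmncc
from pcbc.core import solve_steady_state
from oracles import enumerate_merge_orders


def smooth_patch(rng, size=9):
    from scipy.ndimage import gaussian_filter
    return gaussian_filter(rng.random((size, size)), 1.0)


class TestWholeImagePatches:
    def test_labels_preserved(self, rng):
        images = [rng.random((6, 6)) for _ in range(10)]
        labels = ["a"] * 5 + ["b"] * 5
        patches = extract_whole_image_patches(images, labels)
        assert len(patches) == 10
        assert [p.label for p in patches] == labels
        for p, img in zip(patches, images):
            np.testing.assert_array_equal(p.pixels, img)

    def test_empty(self):
        assert extract_whole_image_patches([], []) == []

    def test_size_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            extract_whole_image_patches(
                [rng.random((6, 6)), rng.random((5, 5))], ["a", "b"])


class TestHarrisKeypoints:
    def test_blank_image_no_keypoints(self):
        assert harris_keypoints(np.zeros((20, 20))).shape == (0, 2)

    def test_square_corners(self):
        img = np.zeros((32, 32))
        img[10:22, 10:22] = 1.0
        kps = harris_keypoints(img)
        corners = [(10, 10), (10, 21), (21, 10), (21, 21)]
        for corner in corners:
            d = np.abs(kps - corner).max(axis=1).min()
            assert d <= 2, f"no keypoint within 2 px of corner {corner}"

    def test_count_monotone_in_threshold(self, rng):
        img = rng.random((40, 40))
        counts = [len(harris_keypoints(img, threshold_rel=t))
                  for t in (0.001, 0.01, 0.1, 0.5)]
        assert counts == sorted(counts, reverse=True)


class TestKeypointPatches:
    def test_single_scale_shapes_and_labels(self):
        img = np.zeros((32, 32))
        img[10:22, 10:22] = 1.0
        patches = extract_keypoint_patches([img, img], ["t", "n"],
                                           patch_size=9)
        assert patches
        assert all(p.pixels.shape == (9, 9) for p in patches)
        assert {p.label for p in patches} == {"t", "n"}
        assert all(p.scale_index == 0 for p in patches)

    def test_multi_scale_indices(self):
        img = np.zeros((48, 48))
        img[12:36, 12:36] = 1.0
        patches = extract_keypoint_patches([img], ["t"], patch_size=9,
                                           scales=(0.8, 1.0, 1.2))
        assert {p.scale_index for p in patches} == {0, 1, 2}

    def test_even_patch_size_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            extract_keypoint_patches([rng.random((20, 20))], ["t"],
                                     patch_size=8)

    def test_patch_larger_than_image_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            extract_keypoint_patches([rng.random((20, 20))], ["t"],
                                     patch_size=15, scales=(0.5,))


class TestAgglomerativeCluster:
    def test_dissimilar_patches_stay_singletons(self, rng):
        patches = [Patch(pixels=smooth_patch(rng), label="a")
                   for _ in range(6)]
        sims = [zmncc(a.pixels, b.pixels) for i, a in enumerate(patches)
                for b in patches[i + 1:]]
        kappa = max(sims) + 1e-6
        d = agglomerative_cluster(patches, kappa=min(kappa, 1.0), lambda_min=0)
        assert len(d) == 6
        assert all(el.member_count == 1 for el in d.elements)

    def test_identical_patches_merge_to_mean(self, rng):
        p = smooth_patch(rng)
        patches = [Patch(pixels=p.copy(), label="a") for _ in range(3)]
        d = agglomerative_cluster(patches, kappa=1.0, lambda_min=0)
        assert len(d) == 1
        assert d.elements[0].member_count == 3
        np.testing.assert_allclose(d.elements[0].pixels, p)

    def test_lambda_filter(self, rng):
        # two tight clusters of sizes 11 and 12; lambda = 12 keeps only
        # the larger one
        a = smooth_patch(rng)
        b = -a  # perfectly anti-correlated with a
        patches = [Patch(pixels=a + 1e-4 * rng.random(a.shape), label="x")
                   for _ in range(11)]
        patches += [Patch(pixels=b + 1e-4 * rng.random(a.shape), label="x")
                    for _ in range(12)]
        d = agglomerative_cluster(patches, kappa=0.9, lambda_min=12)
        assert len(d) == 1
        assert d.elements[0].member_count == 12

    def test_matches_exhaustive_merge_orders(self, rng):
        # two tight groups plus an outlier: every valid merge order must
        # reach the same terminal partition as the greedy scheduler
        base1, base2 = smooth_patch(rng), smooth_patch(rng)
        arrays = [base1 + 0.01 * rng.random(base1.shape) for _ in range(3)]
        arrays += [base2 + 0.01 * rng.random(base2.shape) for _ in range(2)]
        arrays.append(rng.random(base1.shape))
        kappa = 0.9
        patches = [Patch(pixels=a, label="g") for a in arrays]
        d = agglomerative_cluster(patches, kappa=kappa, lambda_min=0)
        n = len(arrays)
        sims = np.array([[zmncc(arrays[i], arrays[j]) for j in range(n)]
                         for i in range(n)])
        terminals = enumerate_merge_orders(sims, kappa)
        assert len(terminals) == 1
        partition = next(iter(terminals))
        expected_means = sorted(
            tuple(np.round(np.mean([arrays[i] for i in sorted(c)], axis=0),
                           6).ravel())
            for c in partition)
        got_means = sorted(tuple(np.round(el.pixels, 6).ravel())
                           for el in d.elements)
        assert got_means == expected_means

    def test_order_invariance(self, rng):
        arrays = [smooth_patch(rng) for _ in range(8)]
        patches = [Patch(pixels=a, label="g") for a in arrays]
        d1 = agglomerative_cluster(patches, kappa=0.5, lambda_min=0)
        perm = rng.permutation(8)
        d2 = agglomerative_cluster([patches[i] for i in perm], kappa=0.5,
                                   lambda_min=0)
        assert len(d1) == len(d2)
        for e1, e2 in zip(d1.elements, d2.elements):
            np.testing.assert_array_equal(e1.pixels, e2.pixels)
            assert e1.member_count == e2.member_count

    def test_kappa_monotone_cluster_count(self, rng):
        patches = [Patch(pixels=smooth_patch(rng), label="g")
                   for _ in range(10)]
        counts = [len(agglomerative_cluster(patches, kappa=k, lambda_min=0))
                  for k in (0.2, 0.5, 0.8, 0.95)]
        assert counts == sorted(counts)

    def test_per_label_partition(self, rng):
        p = smooth_patch(rng)
        patches = [Patch(pixels=p.copy(), label="a"),
                   Patch(pixels=p.copy(), label="b")]
        d = agglomerative_cluster(patches, kappa=0.5, lambda_min=0)
        # identical pixels but different labels: never merged
        assert len(d) == 2
        assert {el.label for el in d.elements} == {"a", "b"}

    def test_empty_input(self):
        d = agglomerative_cluster([], kappa=0.5, lambda_min=0)
        assert len(d) == 0

    def test_invalid_kappa(self, rng):
        with pytest.raises(ValueError, match="kappa"):
            agglomerative_cluster([Patch(pixels=smooth_patch(rng),
                                         label="a")], kappa=0.0)


class TestBuildStage1Network:
    def test_single_element_row_sum(self, rng):
        d = agglomerative_cluster(
            [Patch(pixels=smooth_patch(rng, 7), label="a")], kappa=0.9)
        net = build_stage1_network(d, sigma=1.5)
        assert net.W.shape == (1, 2 * 49)
        assert net.W.sum() == pytest.approx(1.0)
        assert net.meta["labels"] == ["a"]

    def test_constant_element_excluded_with_warning(self, rng):
        patches = [Patch(pixels=smooth_patch(rng, 7), label="a"),
                   Patch(pixels=np.full((7, 7), 0.5), label="b")]
        d = agglomerative_cluster(patches, kappa=0.99)
        with pytest.warns(UserWarning, match="zero contrast"):
            net = build_stage1_network(d, sigma=1.5)
        assert net.n_prediction == 1

    def test_all_constant_rejected(self):
        d = agglomerative_cluster(
            [Patch(pixels=np.zeros((5, 5)), label="a")], kappa=0.9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="non-zero contrast"):
                build_stage1_network(d, sigma=1.0)

    def test_self_match(self, rng):
        # every element's own preprocessed patch maximally activates its
        # own neuron (20-element random dictionary)
        patches = [Patch(pixels=smooth_patch(rng, 11), label=f"e{i}")
                   for i in range(20)]
        d = agglomerative_cluster(patches, kappa=0.999)
        assert len(d) == 20
        net = build_stage1_network(d, sigma=2.0)
        order = {el.label: i for i, el in enumerate(d.elements)}
        for el in d.elements:
            x = local_contrast(el.pixels, 2.0).as_vector()
            y = solve_steady_state(net, x).y
            assert int(np.argmax(y)) == net.meta["labels"].index(el.label)
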