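"""CIF: block partition, min/max quantizers, color reduction, histograms, conv block."""

import numpy as np
import pytest

from mondnet.cif import (
    CifConvSpec,
    CifContractError,
    cif_conv_block,
    cif_feature,
    cif_histograms,
    minmax_quantize,
    partition_blocks,
    quantizer_feature_map,
    reduce_colors,
    shuffle_permutation,
)


class TestPartitionBlocks:
    def test_exact_tiling(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3))
        grid = partition_blocks(img, 4)
        assert grid.n_blocks == 16
        assert all(block.shape == (4, 4, 3) for _, block in grid)

    def test_partial_blocks_retained(self, rng):
        img = rng.integers(0, 256, size=(10, 10, 3))
        grid = partition_blocks(img, 4)
        assert grid.n_blocks == 9
        shapes = {(u, v): b.shape[:2] for (u, v), b in grid}
        assert shapes[(0, 2)] == (4, 2)
        assert shapes[(2, 0)] == (2, 4)
        assert shapes[(2, 2)] == (2, 2)

    def test_oversized_block_is_single_block(self, rng):
        img = rng.integers(0, 256, size=(6, 7, 3))
        grid = partition_blocks(img, 100)
        assert grid.n_blocks == 1
        assert next(iter(grid))[1].shape == (6, 7, 3)

    @pytest.mark.parametrize("h,w,b", [(9, 13, 4), (16, 16, 5), (7, 7, 3), (8, 12, 8)])
    def test_every_pixel_in_exactly_one_block(self, rng, h, w, b):
        # tag each pixel uniquely, then count appearances across blocks
        img = np.arange(h * w).reshape(h, w)
        grid = partition_blocks(img, b)
        seen = np.concatenate([blk.reshape(-1) for _, blk in grid])
        assert sorted(seen.tolist()) == list(range(h * w))


class TestMinMaxQuantize:
    def test_constant_block(self):
        img = np.full((4, 4, 3), 9)
        maps = minmax_quantize(partition_blocks(img, 4))
        np.testing.assert_array_equal(maps.s_min[0, 0], [9, 9, 9])
        np.testing.assert_array_equal(maps.s_max[0, 0], [9, 9, 9])

    def test_extremes(self):
        img = np.zeros((2, 2, 3))
        img[1, 1] = 255
        maps = minmax_quantize(partition_blocks(img, 2))
        np.testing.assert_array_equal(maps.s_min[0, 0], [0, 0, 0])
        np.testing.assert_array_equal(maps.s_max[0, 0], [255, 255, 255])

    def test_matches_full_scan_oracle(self, rng):
        img = rng.integers(0, 256, size=(11, 14, 3))
        b = 4
        grid = partition_blocks(img, b)
        maps = minmax_quantize(grid)
        for (u, v), _ in grid:
            block = img[u * b : (u + 1) * b, v * b : (v + 1) * b]
            for ch in range(3):
                vals = [block[i, j, ch] for i in range(block.shape[0]) for j in range(block.shape[1])]
                assert maps.s_min[u, v, ch] == min(vals)
                assert maps.s_max[u, v, ch] == max(vals)

    def test_min_leq_max_channelwise(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3))
        maps = minmax_quantize(partition_blocks(img, 5))
        assert (maps.s_min <= maps.s_max).all()


class TestReduceColors:
    def test_underfull_palette_is_exact(self):
        colors = np.array([[10, 20, 30], [200, 100, 0], [0, 0, 255]])
        pal = reduce_colors(colors, 8)
        assert pal.size == 3
        assert {tuple(e) for e in pal.entries} == {(10, 20, 30), (200, 100, 0), (0, 0, 255)}
        # zero quantization error
        assigned = pal.entries[pal.assign(colors)]
        np.testing.assert_allclose(assigned, colors)

    def test_two_clusters_find_cluster_means(self, rng):
        c1 = np.clip(rng.normal(40, 2, size=(20, 3)), 0, 255)
        c2 = np.clip(rng.normal(210, 2, size=(20, 3)), 0, 255)
        colors = np.vstack([c1, c2])
        pal = reduce_colors(colors, 2)
        assert pal.size <= 2
        means = np.array([np.rint(c1).mean(axis=0), np.rint(c2).mean(axis=0)])
        order = np.argsort(pal.entries[:, 0])
        for entry, mean in zip(pal.entries[order], means[np.argsort(means[:, 0])]):
            assert np.linalg.norm(entry - mean) < 5.0

    def test_identical_colors_single_entry(self):
        colors = np.tile([[7, 7, 7]], (10, 1))
        pal = reduce_colors(colors, 4)
        assert pal.size == 1
        np.testing.assert_allclose(pal.entries[0], [7, 7, 7])

    def test_quantization_error_nonincreasing_in_k(self, rng):
        colors = rng.integers(0, 256, size=(60, 3)).astype(float)
        errs = []
        for k in (1, 2, 4, 8, 16, 32):
            pal = reduce_colors(colors, k)
            err = np.linalg.norm(colors - pal.entries[pal.assign(colors)], axis=1).sum()
            errs.append(err)
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(CifContractError):
            reduce_colors(np.zeros((0, 3)), 2)
        with pytest.raises(CifContractError):
            reduce_colors(np.array([[1, 2, 3]]), 0)


class TestCifHistograms:
    def test_single_block_one_hot(self):
        img = np.full((4, 4, 3), 50)
        maps = minmax_quantize(partition_blocks(img, 4))
        pal_min = reduce_colors(maps.s_min.reshape(-1, 3), 4)
        pal_max = reduce_colors(maps.s_max.reshape(-1, 3), 4)
        feat = cif_histograms(maps, pal_min, pal_max)
        assert feat.hist_min.sum() == pytest.approx(1.0)
        assert (feat.hist_min == 1.0).sum() == 1
        assert (feat.hist_max == 1.0).sum() == 1

    def test_histograms_sum_to_one(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3))
        maps = minmax_quantize(partition_blocks(img, 4))
        pal_min = reduce_colors(maps.s_min.reshape(-1, 3), 6)
        pal_max = reduce_colors(maps.s_max.reshape(-1, 3), 6)
        feat = cif_histograms(maps, pal_min, pal_max)
        assert feat.hist_min.sum() == pytest.approx(1.0, abs=1e-9)
        assert feat.hist_max.sum() == pytest.approx(1.0, abs=1e-9)
        assert (feat.hist_min >= 0).all() and (feat.hist_max >= 0).all()

    def test_matches_frequency_count_oracle(self, rng):
        img = rng.integers(0, 256, size=(8, 16, 3))  # 8 blocks of 8x8... 2x2 grid of 8
        maps = minmax_quantize(partition_blocks(img, 4))
        pal_min = reduce_colors(maps.s_min.reshape(-1, 3), 4)
        pal_max = reduce_colors(maps.s_max.reshape(-1, 3), 4)
        feat = cif_histograms(maps, pal_min, pal_max)
        # direct per-block nearest-palette loop
        for maps_arr, pal, hist in (
            (maps.s_min, pal_min, feat.hist_min),
            (maps.s_max, pal_max, feat.hist_max),
        ):
            counts = np.zeros(pal.size)
            flat = maps_arr.reshape(-1, 3)
            for color in flat:
                d = [np.sum((color - e) ** 2) for e in pal.entries]
                counts[int(np.argmin(d))] += 1
            np.testing.assert_allclose(hist, counts / len(flat), atol=1e-12)

    def test_fixed_feature_length(self, rng):
        img = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        vec = cif_feature(img, block_size=8, k_min=16, k_max=16)
        assert vec.shape == (32,)
        assert vec[:16].sum() == pytest.approx(1.0)
        assert vec[16:].sum() == pytest.approx(1.0)


def naive_conv_block(x, pw, perm, dw, reorder):
    """Direct nested-loop PWConv -> shuffle -> DWConv -> reorder oracle."""
    n, h, w, _ = x.shape
    c = pw.shape[1]
    y = np.zeros((n, h, w, c))
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                y[ni, i, j] = x[ni, i, j] @ pw
    y = y[:, :, :, perm]
    z = np.zeros_like(y)
    for ni in range(n):
        for ch in range(c):
            for i in range(h):
                for j in range(w):
                    acc = 0.0
                    for a in range(3):
                        for b in range(3):
                            ii, jj = i + a - 1, j + b - 1
                            if 0 <= ii < h and 0 <= jj < w:
                                acc += dw[ch, a, b] * y[ni, ii, jj, ch]
                    z[ni, i, j, ch] = acc
    return z[:, :, :, reorder]


class TestCifConvBlock:
    def test_identity_composition(self, rng):
        x = rng.normal(size=(1, 5, 5, 4))
        spec = CifConvSpec(pw_filters=4, shuffle_groups=2)  # identity pw + center-1 dw
        out = cif_conv_block(x, spec)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_shuffle_reorder_inverse(self):
        perm = shuffle_permutation(6, 3)
        inv = np.argsort(perm)
        np.testing.assert_array_equal(np.arange(6)[perm][inv], np.arange(6))

    def test_shuffle_preserves_channel_multiset(self, rng):
        x = rng.normal(size=(2, 3, 3, 8))
        perm = shuffle_permutation(8, 4)
        shuffled = x[:, :, :, perm]
        np.testing.assert_allclose(np.sort(x, axis=3), np.sort(shuffled, axis=3))

    def test_matches_naive_oracle(self, rng):
        x = rng.normal(size=(1, 6, 6, 4))
        pw = rng.normal(size=(4, 4))
        dw = rng.normal(size=(4, 3, 3))
        spec = CifConvSpec(pw_filters=4, shuffle_groups=2, pw_weights=pw, dw_kernels=dw)
        out = cif_conv_block(x, spec)
        perm = shuffle_permutation(4, 2)
        expected = naive_conv_block(x, pw, perm, dw, np.argsort(perm))
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_indivisible_groups_rejected(self):
        with pytest.raises(CifContractError):
            CifConvSpec(pw_filters=6, shuffle_groups=4)

    def test_quantizer_map_input(self, rng):
        img = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        maps = minmax_quantize(partition_blocks(img, 4))
        fmap = quantizer_feature_map(maps)
        assert fmap.shape == (1, 4, 4, 6)
        out = cif_conv_block(fmap, CifConvSpec(pw_filters=6, shuffle_groups=3))
        assert out.shape == fmap.shape
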