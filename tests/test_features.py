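"""Block partitioning, histograms and feature assembly."""

import numpy as np
import pytest

from conftest import naive_histogram, naive_lddscp_codes
from lddscp import (
    CodePair,
    DescriptorConfig,
    HistogramPair,
    assemble_feature,
    block_histogram_pair,
    encode_image,
    extract_lddscp,
    partition_blocks,
)
from lddscp.features import _run_sizes, block_slices


def _random_code_pair(rng, shape):
    return CodePair(
        rng.integers(0, 16, shape).astype(np.uint8),
        rng.integers(0, 16, shape).astype(np.uint8),
    )


class TestPartition:
    def test_cropped_128_input_split(self):
        # 128x128 image coded with crop border -> 126x126 map; N=8 gives
        # 64 blocks, interior runs 16 px, first/last runs 15 px
        sizes = _run_sizes(126, 8)
        assert sizes == [15, 16, 16, 16, 16, 16, 16, 15]
        codes = _random_code_pair(np.random.default_rng(0), (126, 126))
        blocks = partition_blocks(codes, DescriptorConfig())
        assert len(blocks) == 64
        assert blocks[0].shape == (15, 15)
        assert blocks[9].shape == (16, 16)

    def test_single_block_is_identity(self, rng):
        codes = _random_code_pair(rng, (10, 12))
        (block,) = partition_blocks(codes, DescriptorConfig(blocks_per_side=1))
        np.testing.assert_array_equal(block.code1, codes.code1)

    def test_two_by_two_on_8x8(self, rng):
        codes = _random_code_pair(rng, (8, 8))
        blocks = partition_blocks(codes, DescriptorConfig(blocks_per_side=2))
        assert [b.shape for b in blocks] == [(4, 4)] * 4
        np.testing.assert_array_equal(blocks[1].code1, codes.code1[:4, 4:])  # row-major

    def test_blocks_tile_the_map(self, rng):
        codes = _random_code_pair(rng, (13, 17))
        cfg = DescriptorConfig(blocks_per_side=4)
        rebuilt = np.full(codes.shape, 99, dtype=np.int64)
        for (rs, cs), block in zip(block_slices(codes.shape, 4), partition_blocks(codes, cfg)):
            rebuilt[rs, cs] = block.code1
        np.testing.assert_array_equal(rebuilt, codes.code1)

    def test_grid_larger_than_map_rejected(self, rng):
        codes = _random_code_pair(rng, (6, 6))
        with pytest.raises(ValueError):
            partition_blocks(codes, DescriptorConfig(blocks_per_side=8))


class TestHistograms:
    def test_degenerate_codes_uncounted(self):
        block = CodePair(np.full((5, 5), 15, dtype=np.uint8), np.zeros((5, 5), dtype=np.uint8))
        pair = block_histogram_pair(block)
        assert pair.h1.sum() == 0 and pair.h2.sum() == 0

    def test_forced_counting(self):
        block = CodePair(np.full((16, 16), 3, dtype=np.uint8), np.full((16, 16), 12, dtype=np.uint8))
        pair = block_histogram_pair(block)
        assert pair.h1[2] == 256 and pair.h1.sum() == 256  # bin index 2 <-> code 3
        assert pair.h2[11] == 256 and pair.h2.sum() == 256

    def test_matches_naive_tally(self, rng):
        block = _random_code_pair(rng, (9, 11))
        pair = block_histogram_pair(block)
        np.testing.assert_array_equal(pair.h1, naive_histogram(block.code1))
        np.testing.assert_array_equal(pair.h2, naive_histogram(block.code2))

    def test_empty_block_rejected(self):
        empty = CodePair(np.zeros((0, 4), dtype=np.uint8), np.zeros((0, 4), dtype=np.uint8))
        with pytest.raises(ValueError):
            block_histogram_pair(empty)


class TestAssembly:
    def test_default_feature_length_is_896(self, rng):
        img = rng.integers(0, 256, (128, 128))
        assert extract_lddscp(img).shape == (896,)

    def test_concatenate_gives_28_dims_per_block(self, rng):
        cfg = DescriptorConfig(strategy="concatenate")
        img = rng.integers(0, 256, (128, 128))
        feature = extract_lddscp(img, cfg)
        assert feature.shape == (64 * 28,)
        assert cfg.bins_per_block == 28

    @pytest.mark.parametrize("n", [2, 4, 8, 16])
    @pytest.mark.parametrize("strategy", ["stack", "concatenate"])
    def test_dimension_law(self, rng, n, strategy):
        cfg = DescriptorConfig(blocks_per_side=n, strategy=strategy)
        img = rng.integers(0, 256, (64, 64))
        factor = 14 if strategy == "stack" else 28
        assert extract_lddscp(img, cfg).shape == (n * n * factor,)

    def test_stacked_segment_is_elementwise_sum(self, rng):
        pairs = [
            HistogramPair(rng.integers(0, 20, 14), rng.integers(0, 20, 14))
            for _ in range(4)
        ]
        cfg = DescriptorConfig(blocks_per_side=2)
        feature = assemble_feature(pairs, cfg)
        for b, p in enumerate(pairs):
            seg = feature[b * 14 : (b + 1) * 14]
            np.testing.assert_array_equal(seg, p.h1 + p.h2)
            assert seg.sum() == p.h1.sum() + p.h2.sum()

    def test_wrong_pair_count_rejected(self):
        with pytest.raises(ValueError):
            assemble_feature([HistogramPair(np.zeros(14), np.zeros(14))], DescriptorConfig())

    def test_constant_image_zero_feature(self):
        feature = extract_lddscp(np.full((128, 128), 77))
        assert feature.shape == (896,)
        assert np.all(feature == 0)

    def test_affine_invariance_lifts_to_features(self, rng):
        img = rng.integers(0, 256, (64, 64))
        np.testing.assert_array_equal(extract_lddscp(img), extract_lddscp(3 * img + 40))

    def test_l1_normalization_flag(self, rng):
        img = rng.integers(0, 256, (64, 64))
        feature = extract_lddscp(img, DescriptorConfig(normalize=True))
        assert feature.sum() == pytest.approx(1.0)

    def test_matches_chained_naive_pipeline(self, rng):
        img = rng.integers(0, 256, (32, 32))
        cfg = DescriptorConfig(blocks_per_side=3)
        c1, c2 = naive_lddscp_codes(img)
        expected = []
        for rs, cs in block_slices(c1.shape, 3):
            expected.append(naive_histogram(c1[rs, cs]) + naive_histogram(c2[rs, cs]))
        np.testing.assert_array_equal(extract_lddscp(img, cfg), np.concatenate(expected))


class TestInvariants:
    def test_conservation_bound(self, rng):
        img = rng.integers(0, 256, (64, 64))
        feature = extract_lddscp(img)
        pair = encode_image(img)
        informative = sum(
            int(((codes != 0) & (codes != 15)).sum()) for codes in (pair.code1, pair.code2)
        )
        coded_pixels = pair.code1.size
        assert feature.sum() == informative
        assert feature.sum() <= 2 * coded_pixels

    def test_block_swap_locality(self, rng):
        # swapping two 16x16 tiles of the *code map* swaps exactly the
        # corresponding feature segments (exercised via a pad-border config
        # so blocks align with image tiles)
        cfg = DescriptorConfig(blocks_per_side=4, border="pad")
        img = rng.integers(0, 256, (64, 64))
        pair = encode_image(img, border="pad")
        blocks = partition_blocks(pair, cfg)
        swapped = list(blocks)
        swapped[0], swapped[5] = swapped[5], swapped[0]
        f_orig = assemble_feature([block_histogram_pair(b, cfg) for b in blocks], cfg)
        f_swap = assemble_feature([block_histogram_pair(b, cfg) for b in swapped], cfg)
        seg = lambda f, b: f[b * 14 : (b + 1) * 14]
        np.testing.assert_array_equal(seg(f_swap, 0), seg(f_orig, 5))
        np.testing.assert_array_equal(seg(f_swap, 5), seg(f_orig, 0))
        for b in range(16):
            if b not in (0, 5):
                np.testing.assert_array_equal(seg(f_swap, b), seg(f_orig, b))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DescriptorConfig(blocks_per_side=0)
        with pytest.raises(ValueError):
            DescriptorConfig(strategy="average")
        with pytest.raises(ValueError):
            DescriptorConfig(bits_per_code=8)
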