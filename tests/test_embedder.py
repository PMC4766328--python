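import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import framemark as fm
from framemark import embedder, metrics
from framemark.embedder import CapacityError, ConfigurationError


class TestPartitionRegions:
    def test_masks_are_complementary(self):
        roi = fm.RegionSpec.from_rect(480, 640, x=192, y=144, w=256, h=192)
        roi_mask, roni_mask = fm.partition_regions(480, 640, roi)
        assert not np.any(roi_mask & roni_mask)
        assert np.all(roi_mask | roni_mask)
        assert roi_mask.sum() == 256 * 192

    def test_full_frame_roi_rejected(self):
        with pytest.raises(CapacityError):
            fm.RegionSpec(np.ones((32, 32), dtype=bool))

    def test_roi_without_a_full_block_rejected(self):
        roi = fm.RegionSpec.from_rect(32, 32, x=1, y=1, w=4, h=4)
        with pytest.raises(ConfigurationError):
            fm.partition_regions(32, 32, roi, block_size=8)

    @settings(derandomize=True, max_examples=40)
    @given(data=st.data())
    def test_counts_always_cover_the_frame(self, data):
        h = data.draw(st.integers(16, 64))
        w = data.draw(st.integers(16, 64))
        x = data.draw(st.integers(0, w - 2))
        y = data.draw(st.integers(0, h - 2))
        rw = data.draw(st.integers(1, w - x - (1 if x == 0 else 0)))
        rh = data.draw(st.integers(1, h - y))
        roi = fm.RegionSpec.from_rect(h, w, x, y, rw, rh)
        roi_mask, roni_mask = fm.partition_regions(h, w, roi)
        assert int(roi_mask.sum()) + int(roni_mask.sum()) == h * w


class TestBlockGrid:
    def test_square_roi_tiles_into_four_blocks(self):
        roi = fm.RegionSpec.from_rect(32, 32, x=8, y=8, w=16, h=16)
        grid = fm.build_block_grid(roi.roi_mask, 8, key=1)
        assert grid.n_blocks == 4
        # raster order of origins
        assert [tuple(o) for o in grid.origins] == [(8, 8), (8, 16), (16, 8), (16, 16)]

    def test_mapping_deterministic_per_key(self):
        roi = fm.RegionSpec.from_rect(32, 32, x=0, y=0, w=24, h=24)
        g1 = fm.build_block_grid(roi.roi_mask, 8, key=77)
        g2 = fm.build_block_grid(roi.roi_mask, 8, key=77)
        g3 = fm.build_block_grid(roi.roi_mask, 8, key=78)
        assert np.array_equal(g1.mapping, g2.mapping)
        assert not np.array_equal(g1.mapping, g3.mapping)

    @pytest.mark.parametrize("key", [0, 1, 7, 2**31, 2**32 - 1])
    def test_mapping_has_no_fixed_points(self, key):
        roi = fm.RegionSpec.from_rect(16, 88, x=0, y=0, w=80, h=8)  # 10 blocks
        grid = fm.build_block_grid(roi.roi_mask, 8, key=key)
        assert grid.n_blocks == 10
        assert sorted(grid.mapping) == list(range(10))
        for i in range(10):  # exhaustive brute-force check
            assert grid.mapping[i] != i
        assert np.array_equal(grid.mapping[grid.inverse], np.arange(10))

    def test_empty_tiling_rejected(self):
        roi = fm.RegionSpec.from_rect(32, 32, x=2, y=2, w=6, h=6)
        with pytest.raises(ConfigurationError):
            fm.build_block_grid(roi.roi_mask, 8, key=1)


class TestBlockAuthCode:
    def test_deterministic(self):
        msbs = np.arange(64, dtype=np.uint8) % 64
        c1 = fm.block_auth_code(msbs, 3, 17, 0xABCD)
        c2 = fm.block_auth_code(msbs, 3, 17, 0xABCD)
        assert c1 == c2
        assert 0 <= c1 < 2**16

    def test_single_value_flips_always_change_the_code(self):
        # oracle: recompute the code after each flip and compare
        rng = np.random.Generator(np.random.PCG64(123))
        msbs = rng.integers(0, 64, 64, dtype=np.uint8)
        base = fm.block_auth_code(msbs, 0, 0, 42)
        changed = 0
        for _ in range(1000):
            i = int(rng.integers(0, 64))
            delta = int(rng.integers(1, 64))
            flipped = msbs.copy()
            flipped[i] = (flipped[i] + delta) % 64
            if fm.block_auth_code(flipped, 0, 0, 42) != base:
                changed += 1
        assert changed >= 999

    def test_frame_index_separates_codes(self):
        rng = np.random.Generator(np.random.PCG64(9))
        differing = 0
        for _ in range(1000):
            msbs = rng.integers(0, 64, 64, dtype=np.uint8)
            if fm.block_auth_code(msbs, 3, 5, 7) != fm.block_auth_code(msbs, 4, 5, 7):
                differing += 1
        assert differing >= 999


class TestEmbedFrame:
    def test_only_lsb_planes_change(self, small_stack, rect_config, marked_small):
        marked, _ = marked_small
        delta = small_stack.frames ^ marked.frames
        assert int(delta.max()) <= 3  # bits above the two LSB planes untouched
        assert np.array_equal(small_stack.frames >> 2, marked.frames >> 2)

    def test_per_pixel_difference_bounded(self, small_stack, marked_small):
        marked, _ = marked_small
        diff = np.abs(small_stack.frames.astype(int) - marked.frames.astype(int))
        assert diff.max() <= 3

    def test_frame_mse_matches_direct_oracle(self, small_stack, rect_config):
        out = fm.embed_frame(small_stack.frames[0], rect_config, 0)
        direct = float(
            np.mean((small_stack.frames[0].astype(float) - out.astype(float)) ** 2)
        )
        assert metrics.mse(small_stack.frames[0], out) == pytest.approx(direct, rel=1e-12)
        # 2-LSB randomization over ROI blocks + archive bits over the RONI
        assert 0.3 <= direct <= 2.5
        assert metrics.psnr(small_stack.frames[0], out) >= 38.59

    def test_deterministic(self, small_stack, rect_config):
        a = fm.embed_frame(small_stack.frames[2], rect_config, 2)
        b = fm.embed_frame(small_stack.frames[2], rect_config, 2)
        assert np.array_equal(a, b)

    def test_capacity_error_names_required_and_available_bits(self):
        # ROI so large that the near-incompressible speckle LSBs cannot fit
        # the remaining RONI
        stack = fm.gen_stack(
            fm.FixtureSpec(
                frame_count=1, height=96, width=128, seed=5,
                roi=fm.RegionSpec.from_rect(96, 128, x=0, y=0, w=128, h=88),
            )
        )
        cfg = fm.WatermarkConfig(
            roi=fm.RegionSpec.from_rect(96, 128, x=0, y=0, w=128, h=88), key=1
        )
        with pytest.raises(CapacityError) as err:
            fm.embed_frame(stack.frames[0], cfg, 0)
        assert re.search(r"\d+ bits.*\d+", str(err.value))

    def test_dimension_mismatch_rejected(self, rect_config):
        with pytest.raises(ConfigurationError):
            fm.embed_frame(np.zeros((10, 10), dtype=np.uint8), rect_config, 0)


class TestEmbedStack:
    def test_sequential_preserves_count_and_order(self, small_stack, marked_small):
        marked, records = marked_small
        assert marked.frame_count == small_stack.frame_count
        assert [r.frame_number for r in records] == list(range(1, 7))

    def test_single_frame_stack_equals_embed_frame(self, small_stack, rect_config):
        one = fm.ImageStack(small_stack.frames[:1].copy())
        marked, _ = fm.embed_stack_sequential(one, rect_config)
        assert np.array_equal(marked.frames[0], fm.embed_frame(small_stack.frames[0], rect_config, 0))

    def test_archive_decompresses_to_original_lsbs(self, small_stack, rect_config, marked_small):
        marked, _ = marked_small
        bits = embedder.read_roni_archive(marked.frames[0], rect_config, 0)
        assert bits is not None
        restored = embedder.restore_lsb_planes(marked.frames[0], rect_config, bits)
        # every pixel's LSB planes must equal the pre-embedding original's
        assert np.array_equal(restored & 3, small_stack.frames[0] & 3)

    def test_frame_errors_carry_one_based_number(self, small_stack):
        cfg = fm.WatermarkConfig(roi=fm.RegionSpec.from_rect(64, 64, 0, 0, 32, 32), key=3)
        with pytest.raises(ConfigurationError, match="frame 1"):
            fm.embed_stack_sequential(small_stack, cfg)


class TestConfigValidation:
    def test_lsb_count_limited(self):
        roi = fm.RegionSpec.from_rect(32, 32, 0, 0, 16, 16)
        with pytest.raises(ConfigurationError):
            fm.WatermarkConfig(roi=roi, key=1, lsb_count=3)

    def test_block_size_must_be_even(self):
        roi = fm.RegionSpec.from_rect(32, 32, 0, 0, 16, 16)
        with pytest.raises(ConfigurationError):
            fm.WatermarkConfig(roi=roi, key=1, block_size=7)

    def test_default_payload_layout_fills_capacity_exactly(self):
        roi = fm.RegionSpec.from_rect(32, 32, 0, 0, 16, 16)
        cfg = fm.WatermarkConfig(roi=roi, key=1)
        assert cfg.block_capacity_bits == 128
        assert cfg.recovery_bits == 96  # 16 auth + 96 recovery + 16 padding
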