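import numpy as np
import pytest

import framemark as fm


@pytest.fixture(scope="session")
def small_stack() -> fm.ImageStack:
    """6-frame 96x128 synthetic stack — fast enough for per-test pipelines."""
    return fm.gen_stack(fm.FixtureSpec(frame_count=6, height=96, width=128, seed=11))


@pytest.fixture(scope="session")
def rect_config() -> fm.WatermarkConfig:
    """Aligned rectangular ROI (40% area) on 96x128 — block accounting is
    exact: 48x56 ROI region -> 6x7 = 42 blocks."""
    roi = fm.RegionSpec.from_rect(96, 128, x=32, y=24, w=56, h=48)
    return fm.WatermarkConfig(roi=roi, key=0xDEADBEEF)


@pytest.fixture(scope="session")
def marked_small(small_stack, rect_config):
    marked, records = fm.embed_stack_sequential(small_stack, rect_config)
    return marked, records


@pytest.fixture(scope="session")
def study_stack() -> fm.ImageStack:
    """The full-size study condition: 15 frames of 480x640, fan ROI, seed 7."""
    return fm.gen_stack(fm.FixtureSpec(frame_count=15, height=480, width=640, seed=7))


@pytest.fixture(scope="session")
def study_config() -> fm.WatermarkConfig:
    return fm.default_config(480, 640, key=7 * 2654435761 % 2**31)


@pytest.fixture(scope="session")
def marked_study(study_stack, study_config):
    marked, records = fm.embed_stack_sequential(study_stack, study_config)
    return marked, records


def block_index_of(grid: fm.BlockGrid, row: int, col: int) -> int:
    """Index of the grid block containing pixel (row, col), or -1."""
    bs = grid.block_size
    for i, (r, c) in enumerate(np.asarray(grid.origins)):
        if r <= row < r + bs and c <= col < c + bs:
            return i
    return -1
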