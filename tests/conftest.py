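"""Shared fixtures: in-memory grids and population matrices built by hand."""

import numpy as np
import pytest

from cnvpop.population import PopulationDepthMatrix
from cnvpop.windows import WindowGrid


def make_grid(n_windows: int, window_size: int = 400, chrom: str = "chr1") -> WindowGrid:
    """Single-chromosome grid with all windows retained, GC 0.5, no gaps."""
    step = window_size // 2
    length = (n_windows - 1) * step + window_size
    return WindowGrid(
        window_size=window_size,
        step=step,
        chroms=[chrom],
        chrom_lengths={chrom: length},
        index=np.arange(n_windows, dtype=np.int64),
        chrom_id=np.zeros(n_windows, dtype=np.int32),
        start=np.arange(n_windows, dtype=np.int64) * step,
        gc=np.full(n_windows, 0.5),
        gap=np.zeros(n_windows),
    )


def make_matrix(depths: np.ndarray, grid: WindowGrid | None = None) -> PopulationDepthMatrix:
    """Population matrix straight from a (samples x windows) depth array."""
    depths = np.asarray(depths, dtype=np.float64)
    if grid is None:
        grid = make_grid(depths.shape[1])
    return PopulationDepthMatrix(
        sample_ids=[f"S{i:03d}" for i in range(depths.shape[0])],
        depths=depths,
        grid=grid,
        sample_mean=depths.mean(axis=1),
        sample_std=depths.std(axis=1, ddof=0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
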