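"""Spatial pyramid pooling: fixed-size descriptors from variable-size maps.

A feature map of any spatial extent is pooled over a pyramid of bin grids
(default 4x4, 2x2 and 1x1, i.e. 16 + 4 + 1 = 21 blocks); each block yields one
value per channel, so the descriptor is always ``(21, C)`` no matter how large
the input image was.  Bin boundaries use the adaptive floor/ceil rule, which
covers every cell for every extent (a fixed window/stride rule leaves gaps,
e.g. extent 7 into 4 bins).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor

import numpy as np

DEFAULT_LEVELS: tuple[int, ...] = (4, 2, 1)


@dataclass(frozen=True)
class PyramidDescriptor:
    """Fixed-size SPP output: ``blocks`` is (n_blocks, C), level-major and
    row-major within each level; ``flat`` is blocks flattened with channels
    innermost (block 0 channels, block 1 channels, ...)."""

    blocks: np.ndarray
    levels: tuple[int, ...] = DEFAULT_LEVELS

    @property
    def flat(self) -> np.ndarray:
        return self.blocks.reshape(-1)

    @property
    def n_channels(self) -> int:
        return self.blocks.shape[1]


def n_blocks(levels=DEFAULT_LEVELS) -> int:
    return int(sum(n * n for n in levels))


def pyramid_bins(extent: int, n_bins: int) -> list[tuple[int, int]]:
    """Half-open index intervals partitioning ``[0, extent)`` into ``n_bins``
    overlapping-boundary bins: bin i = [floor(i*e/n), ceil((i+1)*e/n)).

    Every bin is non-empty and the union covers [0, extent) for any extent
    >= 1, including extents smaller than would divide evenly.
    """
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    if extent < 1:
        raise ValueError(f"extent must be >= 1, got {extent}")
    return [
        (floor(i * extent / n_bins), ceil((i + 1) * extent / n_bins))
        for i in range(n_bins)
    ]


def spp_pool(feature_map: np.ndarray, levels=DEFAULT_LEVELS, statistic: str = "max") -> PyramidDescriptor:
    """Pool an (H, W, C) feature map into a fixed (sum n^2, C) descriptor.

    Each level ``n`` overlays an n x n grid of bins (row-major order) and each
    bin contributes the per-channel max (or mean, with ``statistic="mean"``)
    over its cells.  Output rows are ordered coarsest-level-last: for the
    default levels, 16 rows of the 4x4 grid, then 4, then the global bin.
    """
    f = np.asarray(feature_map)
    if f.ndim != 3:
        raise ValueError(f"expected (H, W, C) feature map, got shape {f.shape}")
    h, w, _ = f.shape
    need = max(levels)
    if h < need or w < need:
        raise ValueError(
            f"feature map {h}x{w} too small for pyramid level {need}: "
            f"both spatial extents must be >= {need}"
        )
    if statistic not in ("max", "mean"):
        raise ValueError(f"statistic must be 'max' or 'mean', got {statistic!r}")
    reduce = np.max if statistic == "max" else np.mean
    rows = []
    for n in levels:
        rbins = pyramid_bins(h, n)
        cbins = pyramid_bins(w, n)
        for r0, r1 in rbins:
            for c0, c1 in cbins:
                rows.append(reduce(f[r0:r1, c0:c1, :], axis=(0, 1)))
    return PyramidDescriptor(np.stack(rows), tuple(levels))
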