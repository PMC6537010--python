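"""Block partitioning, per-block code histograms and feature assembly.

A coded image is split into an ``N x N`` grid of non-overlapping blocks.
Each block contributes a pair of 14-bin histograms (one per mask group),
counting only the informative codes ``1..14``. The whole-image descriptor is
either the per-block *stack* (element-wise sum of the two histograms, 14
dims/block — the default, and the configuration that gives the 896-dim
feature at 128x128 with an 8x8 grid) or the *concatenation* (28 dims/block).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .masks import CodePair, encode_image

__all__ = [
    "DescriptorConfig",
    "HistogramPair",
    "partition_blocks",
    "block_histogram_pair",
    "assemble_feature",
    "extract_lddscp",
]

ASSEMBLY_STRATEGIES = ("stack", "concatenate")


@dataclass(frozen=True)
class DescriptorConfig:
    """Descriptor hyper-parameters.

    Parameters
    ----------
    blocks_per_side
        ``N``: the image is split into ``N x N`` blocks. Default 8, the
        block count found optimal for 128x128 inputs (16x16-pixel blocks).
    bits_per_code
        Bits per group code; the symmetric-group encoder is 4-bit, giving
        ``2**4 - 2 = 14`` histogram bins.
    strategy
        ``"stack"`` (element-wise sum of the two per-block histograms) or
        ``"concatenate"`` (side by side).
    border
        Border policy forwarded to the encoder (``"crop"`` or ``"pad"``).
    normalize
        If True, L1-normalize the final feature vector. Off by default:
        the descriptor uses raw counts.
    expected_side
        Documented working resolution; inputs are not resized here.
    """

    blocks_per_side: int = 8
    bits_per_code: int = 4
    strategy: str = "stack"
    border: str = "crop"
    normalize: bool = False
    expected_side: int = 128

    def __post_init__(self):
        if self.blocks_per_side < 1:
            raise ValueError("blocks_per_side must be >= 1")
        if self.bits_per_code != 4:
            raise ValueError("the symmetric-group encoder is 4-bit")
        if self.strategy not in ASSEMBLY_STRATEGIES:
            raise ValueError(f"strategy must be one of {ASSEMBLY_STRATEGIES}")

    @property
    def n_bins(self) -> int:
        """Informative bins per histogram: ``2**k - 2``."""
        return 2**self.bits_per_code - 2

    @property
    def bins_per_block(self) -> int:
        return self.n_bins if self.strategy == "stack" else 2 * self.n_bins

    @property
    def feature_length(self) -> int:
        return self.blocks_per_side**2 * self.bins_per_block

    def with_(self, **kwargs) -> "DescriptorConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class HistogramPair:
    """Per-block 14-bin counts for the two code maps (codes 1..14)."""

    h1: np.ndarray
    h2: np.ndarray


def _run_sizes(side: int, n: int) -> list[int]:
    """Split ``side`` pixels into ``n`` contiguous runs, as even as possible.

    Any shortfall relative to equal-sized runs is taken from the runs at the
    two ends of the side, so interior blocks keep the nominal size (a
    126-pixel side split 8 ways gives runs 15,16,16,16,16,16,16,15).
    """
    if n > side:
        raise ValueError(f"cannot split a side of {side} pixels into {n} runs")
    q, r = divmod(side, n)
    if r == 0:
        return [q] * n
    # r runs of q+1 in the middle, n-r runs of q pushed to the ends
    n_small = n - r
    lead = n_small // 2
    return [q] * lead + [q + 1] * r + [q] * (n_small - lead)


def block_slices(shape: tuple, n: int) -> list[tuple]:
    """Row-major list of ``(row_slice, col_slice)`` for the ``n x n`` grid."""
    h, w = shape
    row_edges = np.cumsum([0] + _run_sizes(h, n))
    col_edges = np.cumsum([0] + _run_sizes(w, n))
    return [
        (slice(row_edges[i], row_edges[i + 1]), slice(col_edges[j], col_edges[j + 1]))
        for i in range(n)
        for j in range(n)
    ]


def partition_blocks(codes: CodePair, config: DescriptorConfig) -> list[CodePair]:
    """Split a code-map pair into ``N**2`` disjoint blocks, row-major."""
    n = config.blocks_per_side
    h, w = codes.shape
    if n > min(h, w):
        raise ValueError(
            f"block grid {n}x{n} exceeds code map of shape {(h, w)}"
        )
    return [CodePair(codes.code1[rs, cs], codes.code2[rs, cs]) for rs, cs in block_slices((h, w), n)]


def code_histogram(codes: np.ndarray, n_bins: int = 14) -> np.ndarray:
    """Counts of code values ``1..n_bins``; degenerate codes are skipped."""
    counts = np.bincount(np.asarray(codes, dtype=np.int64).ravel(), minlength=n_bins + 2)
    return counts[1 : n_bins + 1]


def block_histogram_pair(block: CodePair, config: DescriptorConfig | None = None) -> HistogramPair:
    """The two per-block histograms over the informative code values."""
    if block.code1.size == 0:
        raise ValueError("block region is empty")
    n_bins = (config or DescriptorConfig()).n_bins
    return HistogramPair(
        h1=code_histogram(block.code1, n_bins), h2=code_histogram(block.code2, n_bins)
    )


def assemble_feature(pairs: list[HistogramPair], config: DescriptorConfig) -> np.ndarray:
    """Assemble per-block histogram pairs into the whole-image feature.

    ``stack`` emits ``h1 + h2`` per block; ``concatenate`` emits ``h1`` then
    ``h2``. Blocks are laid out row-major; the result is a float vector of
    counts (or frequencies when ``config.normalize``).
    """
    n_expected = config.blocks_per_side**2
    if len(pairs) != n_expected:
        raise ValueError(f"expected {n_expected} histogram pairs, got {len(pairs)}")
    if config.strategy == "stack":
        segments = [p.h1 + p.h2 for p in pairs]
    else:
        segments = [np.concatenate([p.h1, p.h2]) for p in pairs]
    feature = np.concatenate(segments).astype(np.float64)
    if config.normalize:
        total = feature.sum()
        if total > 0:
            feature = feature / total
    return feature


def extract_lddscp(image, config: DescriptorConfig | None = None) -> np.ndarray:
    """Whole-image descriptor: encode, partition, histogram, assemble."""
    config = config or DescriptorConfig()
    codes = encode_image(image, border=config.border)
    blocks = partition_blocks(codes, config)
    pairs = [block_histogram_pair(b, config) for b in blocks]
    return assemble_feature(pairs, config)
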