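"""Baseline block-histogram descriptors: LBP, CS-LBP and LDP.

These share the block/assembly skeleton of the main descriptor but encode a
single code map per image, so per-block histograms are simply concatenated:

* **LBP** — 8-bit code thresholding each of the 8 ring neighbours against
  the centre pixel (``neighbour >= centre`` sets the bit); 256 bins/block.
* **CS-LBP** — 4-bit code thresholding the 4 centre-symmetric neighbour
  pairs (``n_i - n_{i+4} > T``); 16 bins/block.
* **LDP** — 8-bit code setting the ``k`` masks with largest absolute Kirsch
  response (default ``k = 3``); 256-bin histograms, of which only the
  ``C(8, 3) = 56`` three-bit codes are attainable.

Neighbour index ``i`` is the ring position at ``45*i`` degrees counter-
clockwise starting East, matching the compass-mask direction order, and bit
``i`` carries weight ``2**i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import block_slices
from .masks import DirectionMaskSet, directional_responses, kirsch_mask_groups

__all__ = [
    "BaselineConfig",
    "lbp_codes",
    "cslbp_codes",
    "ldp_codes",
    "lbp_feature",
    "cslbp_feature",
    "ldp_feature",
]

# (row, col) offsets of the 8-connected ring, CCW from East (rows grow down).
NEIGHBOR_OFFSETS = (
    (0, 1),
    (-1, 1),
    (-1, 0),
    (-1, -1),
    (0, -1),
    (1, -1),
    (1, 0),
    (1, 1),
)

_BINS = {"lbp": 256, "cslbp": 16, "ldp": 256}


@dataclass(frozen=True)
class BaselineConfig:
    """Parameters shared by the baseline descriptors.

    ``blocks_per_side = 8`` reproduces the standard 16x16-pixel blocks at
    the 128x128 working resolution.
    """

    descriptor: str = "lbp"
    blocks_per_side: int = 8
    border: str = "crop"
    k_ldp: int = 3
    threshold: float = 0.0

    def __post_init__(self):
        if self.descriptor not in _BINS:
            raise ValueError(f"descriptor must be one of {tuple(_BINS)}")
        if not 1 <= self.k_ldp <= 7:
            raise ValueError("k_ldp must be in 1..7")

    @property
    def n_bins(self) -> int:
        return _BINS[self.descriptor]

    @property
    def feature_length(self) -> int:
        return self.blocks_per_side**2 * self.n_bins


def _neighbor_stack(image, border: str):
    """Centre map plus the 8 ring-neighbour maps, shape ``(8, H, W)``."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={arr.ndim}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got {arr.shape}")
    if border == "pad":
        arr = np.pad(arr, 1, mode="edge")
    elif border != "crop":
        raise ValueError("border must be 'crop' or 'pad'")
    h, w = arr.shape
    center = arr[1 : h - 1, 1 : w - 1]
    neigh = np.stack(
        [arr[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc] for dr, dc in NEIGHBOR_OFFSETS]
    )
    return center, neigh


def lbp_codes(image, border: str = "crop") -> np.ndarray:
    """Classic 8-bit local binary pattern code map (256 code values)."""
    center, neigh = _neighbor_stack(image, border)
    bits = neigh >= center
    weights = (2 ** np.arange(8)).reshape(8, 1, 1)
    return (bits * weights).sum(axis=0).astype(np.uint8)


def cslbp_codes(image, threshold: float = 0.0, border: str = "crop") -> np.ndarray:
    """4-bit centre-symmetric LBP code map (16 code values)."""
    _, neigh = _neighbor_stack(image, border)
    bits = (neigh[:4] - neigh[4:]) > threshold
    weights = (2 ** np.arange(4)).reshape(4, 1, 1)
    return (bits * weights).sum(axis=0).astype(np.uint8)


def ldp_codes(
    image,
    k: int = 3,
    border: str = "crop",
    masks: DirectionMaskSet | None = None,
) -> np.ndarray:
    """8-bit local directional pattern code map.

    Sets a 1 at the ``k`` compass masks with the largest absolute response;
    ties at the k-th rank are broken toward the lower mask index. Every code
    has exactly ``k`` set bits.
    """
    if masks is None:
        masks = kirsch_mask_groups()
    stack = directional_responses(image, masks=masks, border=border)
    resp = np.abs(stack.responses.reshape(8, *stack.shape))
    # stable argsort on -|response|: equal magnitudes keep ascending mask index
    order = np.argsort(-resp, axis=0, kind="stable")[:k]
    codes = np.zeros(stack.shape, dtype=np.uint16)
    for rank in range(k):
        codes |= (1 << order[rank]).astype(np.uint16)
    return codes.astype(np.uint8)


def _block_feature(codes: np.ndarray, n_bins: int, n_blocks: int) -> np.ndarray:
    segments = []
    for rs, cs in block_slices(codes.shape, n_blocks):
        segments.append(np.bincount(codes[rs, cs].ravel(), minlength=n_bins)[:n_bins])
    return np.concatenate(segments).astype(np.float64)


def lbp_feature(image, config: BaselineConfig | None = None) -> np.ndarray:
    """Concatenated 256-bin block histograms of LBP codes."""
    cfg = config or BaselineConfig(descriptor="lbp")
    return _block_feature(lbp_codes(image, cfg.border), 256, cfg.blocks_per_side)


def cslbp_feature(image, config: BaselineConfig | None = None) -> np.ndarray:
    """Concatenated 16-bin block histograms of CS-LBP codes."""
    cfg = config or BaselineConfig(descriptor="cslbp")
    return _block_feature(
        cslbp_codes(image, cfg.threshold, cfg.border), 16, cfg.blocks_per_side
    )


def ldp_feature(image, config: BaselineConfig | None = None) -> np.ndarray:
    """Concatenated 256-bin block histograms of LDP codes."""
    cfg = config or BaselineConfig(descriptor="ldp")
    return _block_feature(
        ldp_codes(image, cfg.k_ldp, cfg.border), 256, cfg.blocks_per_side
    )
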