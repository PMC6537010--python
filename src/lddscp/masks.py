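"""Kirsch compass masks and the symmetric-group directional encoder.

The descriptor rests on the eight 3x3 Kirsch compass masks, split into two
symmetric groups by direction: group 1 probes {0, 45, 90, 135} degrees and
group 2 probes {180, 225, 270, 315} degrees. Each pixel is convolved against
all eight masks; within each group the four responses are compared to the
group mean, and the four sign bits form a 4-bit code per group. The all-zero
and all-one words carry no dominant-direction information and are treated as
degenerate downstream.

Conventions (documented because the coding is only meaningful relative to
them):

* 0 degrees = East = the +5 column on the right of the mask; successive mask
  indices rotate the weight pattern 45 degrees counter-clockwise.
* Masks are applied as correlation stencils (no flip).
* Bit ``i`` (weight ``2**i``) of a group's code corresponds to mask index
  ``i`` of that group, so bit 0 is 0 deg for group 1 and 180 deg for group 2.
* The sign function assigns 1 to ties: ``S(x) = 1 iff x >= 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_DEG",
    "DEGENERATE_CODES",
    "VALID_CODES",
    "DirectionMaskSet",
    "ResponseStack",
    "CodePair",
    "kirsch_mask_groups",
    "directional_responses",
    "encode_patterns",
    "encode_image",
]

#: The eight compass directions probed by the mask set, in mask-index order.
DIRECTIONS_DEG = (0, 45, 90, 135, 180, 225, 270, 315)

#: 4-bit words excluded from histograms: no direction dominates.
DEGENERATE_CODES = (0, 15)

#: The 2**4 - 2 = 14 informative code values.
VALID_CODES = tuple(c for c in range(16) if c not in DEGENERATE_CODES)

BORDER_POLICIES = ("crop", "pad")

# Canonical Kirsch mask for 0 deg / East: three +5 weights on the right
# column, five -3 elsewhere, zero center; weights sum to zero.
_EAST = np.array([[-3, -3, 5], [-3, 0, 5], [-3, -3, 5]], dtype=np.int64)

# Border ring of a 3x3 stencil, counter-clockwise starting at East
# (image rows grow downward, so "up" is row 0).
_RING = ((1, 2), (0, 2), (0, 1), (0, 0), (1, 0), (2, 0), (2, 1), (2, 2))


def _rotate45(mask: np.ndarray) -> np.ndarray:
    """Rotate a 3x3 compass stencil 45 degrees counter-clockwise."""
    out = mask.copy()
    vals = [mask[p] for p in _RING]
    vals = vals[-1:] + vals[:-1]
    for pos, v in zip(_RING, vals):
        out[pos] = v
    return out


@dataclass(frozen=True)
class DirectionMaskSet:
    """The eight Kirsch masks partitioned into two symmetric groups.

    ``group1[i]`` probes direction ``45*i`` degrees, ``group2[i]`` probes
    ``45*i + 180`` degrees; ``group2[i]`` is the 180-degree rotation of
    ``group1[i]``'s weight pattern.
    """

    group1: np.ndarray  # (4, 3, 3) int64
    group2: np.ndarray  # (4, 3, 3) int64
    directions_group1: tuple = DIRECTIONS_DEG[:4]
    directions_group2: tuple = DIRECTIONS_DEG[4:]

    def all_masks(self) -> np.ndarray:
        """All 8 masks stacked in direction order, shape ``(8, 3, 3)``."""
        return np.concatenate([self.group1, self.group2], axis=0)

    def to_table(self) -> str:
        """Plain-text rendering of the mask set (for docs and manifests)."""
        lines = []
        for deg, mask in zip(DIRECTIONS_DEG, self.all_masks()):
            lines.append(f"# direction {deg} deg")
            for row in mask:
                lines.append(" ".join(f"{w:3d}" for w in row))
        return "\n".join(lines)


def kirsch_mask_groups() -> DirectionMaskSet:
    """Build the canonical Kirsch mask set in its two symmetric groups.

    Starting from the East stencil, each subsequent mask is the 45-degree
    counter-clockwise rotation of its predecessor, so the set of eight is
    closed under 45-degree rotation and ``group2[i]`` is ``group1[i]``
    rotated by 180 degrees.
    """
    masks = [_EAST]
    for _ in range(7):
        masks.append(_rotate45(masks[-1]))
    arr = np.stack(masks)
    arr.setflags(write=False)
    return DirectionMaskSet(group1=arr[:4], group2=arr[4:])


@dataclass(frozen=True)
class ResponseStack:
    """Per-pixel responses of the eight masks, grouped.

    Attributes
    ----------
    responses
        Array of shape ``(2, 4, H, W)``: ``responses[j, i]`` is the
        correlation of the image with mask ``i`` of group ``j + 1``. Under
        the ``crop`` border policy ``H = h - 2`` and ``W = w - 2``.
    group_means
        Array of shape ``(2, H, W)``: arithmetic mean of each group's four
        responses at every pixel.
    border
        Border policy the stack was computed under.
    """

    responses: np.ndarray
    group_means: np.ndarray
    border: str = "crop"

    @property
    def shape(self) -> tuple:
        return self.responses.shape[-2:]


@dataclass(frozen=True)
class CodePair:
    """Per-pixel 4-bit code maps for the two mask groups.

    ``code1`` and ``code2`` hold integers in ``0..15``; values 0 and 15 are
    degenerate (no dominant direction) and are skipped when histograms are
    built.
    """

    code1: np.ndarray
    code2: np.ndarray

    def __post_init__(self):
        if self.code1.shape != self.code2.shape:
            raise ValueError("code1 and code2 must share dimensions")

    @property
    def shape(self) -> tuple:
        return self.code1.shape


def _validate_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got ndim={arr.ndim}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image must be at least 3x3, got {arr.shape}")
    return arr


def directional_responses(
    image, masks: DirectionMaskSet | None = None, border: str = "crop"
) -> ResponseStack:
    """Correlate an image with all eight masks and compute group means.

    Parameters
    ----------
    image
        2-D intensity grid, at least 3x3. 8-bit integers are the norm but
        any real grid is accepted.
    masks
        Mask set; defaults to :func:`kirsch_mask_groups`.
    border
        ``"crop"`` codes only pixels with full 3x3 support, yielding
        ``(h-2, w-2)`` maps; ``"pad"`` replicates edge pixels so the maps
        keep the image shape.
    """
    arr = _validate_image(image)
    if border not in BORDER_POLICIES:
        raise ValueError(f"border must be one of {BORDER_POLICIES}, got {border!r}")
    if masks is None:
        masks = kirsch_mask_groups()

    all_masks = masks.all_masks().astype(np.float64)
    if border == "crop":
        full = [ndimage.correlate(arr, m, mode="constant") for m in all_masks]
        resp = np.stack([f[1:-1, 1:-1] for f in full])
    else:
        resp = np.stack([ndimage.correlate(arr, m, mode="nearest") for m in all_masks])
    resp = resp.reshape(2, 4, *resp.shape[-2:])
    return ResponseStack(responses=resp, group_means=resp.mean(axis=1), border=border)


def encode_patterns(stack: ResponseStack) -> CodePair:
    """Encode each pixel's two 4-bit dominant-direction codes.

    For group ``j`` the code is ``sum_i S(M_ji - mean_j) * 2**i`` with
    ``S(x) = 1 iff x >= 0``. The comparison is evaluated as
    ``4*M_ji - sum_i M_ji >= 0``, which is exact for integer imagery.
    """
    resp = stack.responses
    # 4*M - sum(M) has the same sign as M - mean and stays exact in float64
    # for 8-bit inputs (all intermediate values are integers < 2**53).
    diff = 4.0 * resp - resp.sum(axis=1, keepdims=True)
    bits = diff >= 0
    weights = (2 ** np.arange(4)).reshape(1, 4, 1, 1)
    codes = (bits * weights).sum(axis=1).astype(np.uint8)
    return CodePair(code1=codes[0], code2=codes[1])


def encode_image(
    image, masks: DirectionMaskSet | None = None, border: str = "crop"
) -> CodePair:
    """Convenience composition: responses then codes."""
    return encode_patterns(directional_responses(image, masks=masks, border=border))
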