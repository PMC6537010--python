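"""Shared fixtures and independent naive oracles.

The oracle functions here deliberately re-derive every operation with plain
per-pixel loops from the definitions, independent of the vectorised
implementations they are used to check.
"""

from collections import Counter

import numpy as np
import pytest

from lddscp.masks import kirsch_mask_groups

# ---------------------------------------------------------------------------
# naive oracles


def naive_lddscp_codes(image, border="crop"):
    """Triple-loop group-mean encoder straight from the definitions."""
    arr = np.asarray(image, dtype=np.float64)
    masks = kirsch_mask_groups().all_masks()
    if border == "pad":
        arr = np.pad(arr, 1, mode="edge")
    h, w = arr.shape
    code1 = np.zeros((h - 2, w - 2), dtype=np.uint8)
    code2 = np.zeros_like(code1)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            window = arr[r - 1 : r + 2, c - 1 : c + 2]
            resp = [float((m * window).sum()) for m in masks]
            for g, out in ((0, code1), (1, code2)):
                group = resp[4 * g : 4 * g + 4]
                avg = sum(group) / 4.0
                code = 0
                for i, v in enumerate(group):
                    if v - avg >= 0:
                        code += 2**i
                out[r - 1, c - 1] = code
    return code1, code2


def naive_lbp_codes(image):
    """Per-pixel 8-bit LBP, ring CCW from East, neighbour >= centre."""
    arr = np.asarray(image, dtype=np.float64)
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    h, w = arr.shape
    out = np.zeros((h - 2, w - 2), dtype=np.uint8)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for i, (dr, dc) in enumerate(offsets):
                if arr[r + dr, c + dc] >= arr[r, c]:
                    code += 2**i
            out[r - 1, c - 1] = code
    return out


def naive_cslbp_codes(image, threshold=0.0):
    arr = np.asarray(image, dtype=np.float64)
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    h, w = arr.shape
    out = np.zeros((h - 2, w - 2), dtype=np.uint8)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for i in range(4):
                dr1, dc1 = offsets[i]
                dr2, dc2 = offsets[i + 4]
                if arr[r + dr1, c + dc1] - arr[r + dr2, c + dc2] > threshold:
                    code += 2**i
            out[r - 1, c - 1] = code
    return out


def naive_ldp_codes(image, k=3):
    """Top-|response| coding with lower-mask-index tie break."""
    arr = np.asarray(image, dtype=np.float64)
    masks = kirsch_mask_groups().all_masks()
    h, w = arr.shape
    out = np.zeros((h - 2, w - 2), dtype=np.uint8)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            window = arr[r - 1 : r + 2, c - 1 : c + 2]
            resp = [abs(float((m * window).sum())) for m in masks]
            ranked = sorted(range(8), key=lambda i: (-resp[i], i))[:k]
            out[r - 1, c - 1] = sum(2**i for i in ranked)
    return out


def naive_histogram(codes, lo=1, hi=14):
    tally = Counter(int(v) for v in np.asarray(codes).ravel())
    return np.array([tally.get(i, 0) for i in range(lo, hi + 1)])


def naive_loso_knn(features, labels, k=1, metric="euclidean"):
    """O(n^2) fold-by-fold LOSO with explicit distance loops."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(labels)

    def dist(a, b):
        if metric == "euclidean":
            return float(np.sqrt(((a - b) ** 2).sum()))
        return float(0.5 * (((a - b) ** 2) / (a + b + 1e-10)).sum())

    preds = []
    for i in range(n):
        pairs = [(dist(features[i], features[j]), j) for j in range(n) if j != i]
        pairs.sort(key=lambda t: (t[0], t[1]))
        neighbours = [j for _, j in pairs[:k]]
        votes = Counter(labels[j] for j in neighbours)
        top = max(votes.values())
        winners = {lab for lab, c in votes.items() if c == top}
        if len(winners) == 1:
            preds.append(winners.pop())
        else:
            preds.append(next(labels[j] for j in neighbours if labels[j] in winners))
    preds = np.asarray(preds)
    return preds, float((preds == labels).mean())


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def east_edge_patch():
    """3x3 patch with a bright East column; the hand-worked coding example."""
    return np.array([[0, 0, 100], [0, 0, 100], [0, 0, 100]])


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study set (6 classes x 10 images, seed 0)."""
    from lddscp import make_dataset

    return make_dataset(seed=0)


@pytest.fixture(scope="session")
def default_lddscp_features(default_dataset):
    from lddscp import extract_matrix

    return extract_matrix(default_dataset.images, "lddscp")
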