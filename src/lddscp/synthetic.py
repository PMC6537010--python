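"""Synthetic oriented-texture fixtures.

The descriptor under study is a dominant-direction encoder, so the synthetic
datasets are built from oriented textures: plane ramps and asymmetric
sawtooth gratings whose intensity gradient points along one of the eight
compass directions. These exercise exactly the mechanism the encoder claims
— discriminating textures by dominant direction — without any face data.

A structural fact shapes the class design: for one-dimensional textures
(intensity a function of a single projected coordinate) the group-2 code is
the bitwise complement of the group-1 code, so the *stacked* histogram is
identical for a texture and its 180-degree flip. Orientation alone can
therefore define at most four stack-separable classes. Datasets with more
classes draw on further texture families the encoder genuinely
distinguishes: crossed gratings (plaids, two superposed orientations) and
isotropic smoothed random fields (no dominant orientation).

All generators are pure functions of their parameters and seed; a dataset's
manifest suffices to regenerate it bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .baselines import lbp_codes
from .masks import DIRECTIONS_DEG, encode_image

__all__ = [
    "LabeledDataset",
    "make_oriented_texture",
    "make_plaid_texture",
    "make_isotropic_texture",
    "make_dataset",
    "dataset_from_manifest",
    "find_lbp_flip_patch",
]


@dataclass
class LabeledDataset:
    """Images with class labels and a regeneration manifest."""

    images: list  # list of (H, W) uint8 arrays
    labels: list  # class label per image
    manifest: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.images)

    @property
    def classes(self) -> list:
        return sorted(set(self.labels))


def _quantize(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def make_oriented_texture(
    direction_deg: int,
    size: int = 128,
    contrast: float = 160.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    kind: str = "grating",
    period: float = 16.0,
    phase: float = 0.0,
    rise_fraction: float = 0.875,
) -> np.ndarray:
    """A synthetic texture whose intensity gradient points along a compass direction.

    Parameters
    ----------
    direction_deg
        One of the eight compass directions {0, 45, ..., 315}; 0 is East
        and angles grow counter-clockwise.
    size
        Image side length (>= 16); output is ``size x size`` uint8.
    contrast
        Peak-to-peak intensity span of the clean pattern, centred on 128.
    noise_sigma
        Standard deviation of additive Gaussian jitter applied before
        8-bit quantization.
    kind
        ``"ramp"``: a single plane ramp rising along the direction (every
        pixel shares the same gradient). ``"grating"``: an asymmetric
        sawtooth that rises slowly along the direction over
        ``rise_fraction`` of each period and resets sharply, so the slow
        gradient — and hence the dominant code — points along
        ``direction_deg`` on most pixels.
    period
        Grating period in pixels (ignored for ramps).
    phase
        Grating phase in periods, in ``[0, 1)``.
    seed
        Seed for the jitter; the clean pattern is deterministic.
    """
    direction_deg = int(direction_deg) % 360
    if direction_deg not in DIRECTIONS_DEG:
        raise ValueError(
            f"unsupported direction {direction_deg}; use one of {DIRECTIONS_DEG}"
        )
    if size < 16:
        raise ValueError("size must be >= 16")
    if contrast <= 0:
        raise ValueError("contrast must be positive")
    if kind not in ("ramp", "grating"):
        raise ValueError("kind must be 'ramp' or 'grating'")
    if not 0 < rise_fraction < 1:
        raise ValueError("rise_fraction must be in (0, 1)")

    theta = np.deg2rad(direction_deg)
    cols = np.arange(size, dtype=np.float64)
    rows = np.arange(size, dtype=np.float64)
    x = cols[None, :]
    y = -rows[:, None]  # rows grow downward; y grows toward North
    u = x * np.cos(theta) + y * np.sin(theta)

    if kind == "ramp":
        span = u.max() - u.min()
        clean = 128.0 + contrast * ((u - u.min()) / span - 0.5)
    else:
        frac = (u / period - phase) % 1.0
        profile = np.where(
            frac < rise_fraction, frac / rise_fraction, (1.0 - frac) / (1.0 - rise_fraction)
        )
        clean = 128.0 + contrast * (profile - 0.5)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sigma, clean.shape)
    return _quantize(clean)


def make_plaid_texture(
    directions: tuple = (0, 90),
    size: int = 128,
    contrast: float = 160.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    period: float = 16.0,
    phases: tuple = (0.0, 0.0),
) -> np.ndarray:
    """A crossed grating: the mean of two oriented sawtooth gratings."""
    a = make_oriented_texture(
        directions[0], size=size, contrast=contrast, kind="grating", period=period, phase=phases[0]
    ).astype(np.float64)
    b = make_oriented_texture(
        directions[1], size=size, contrast=contrast, kind="grating", period=period, phase=phases[1]
    ).astype(np.float64)
    img = (a + b) / 2.0
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return _quantize(img)


def make_isotropic_texture(
    size: int = 128,
    contrast: float = 160.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    scale: float = 2.0,
) -> np.ndarray:
    """An isotropic texture: a Gaussian-smoothed random field, no dominant direction."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), scale)
    field = field / field.std() * (contrast / 4.0)
    img = 128.0 + field
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return _quantize(img)


def _class_spec(class_index: int, separation: int) -> dict:
    """Map a class index to a texture-family recipe.

    Classes 0..3 are sawtooth gratings ``separation`` degrees apart within
    the stack-separable 0..135 range; further classes are crossed gratings
    and isotropic fields (see module docstring for why plain orientation
    cannot carry more than four stacked-histogram classes).
    """
    if separation % 45 != 0 or not 0 < separation <= 135:
        raise ValueError("separation must be 45, 90 or 135 degrees")
    n_orients = min(4, 1 + (135 // separation))
    recipes = [
        {"kind": "grating", "direction": d * separation} for d in range(n_orients)
    ] + [
        {"kind": "plaid", "directions": (0, 90)},
        {"kind": "isotropic", "scale": 2.0},
        {"kind": "plaid", "directions": (45, 135)},
        {"kind": "isotropic", "scale": 4.0},
    ]
    if class_index >= len(recipes):
        raise ValueError(
            f"at most {len(recipes)} distinct classes at separation {separation}"
        )
    return recipes[class_index]


def make_dataset(
    n_classes: int = 6,
    n_per_class: int = 10,
    size: int = 128,
    separation: int = 45,
    noise_sigma: float = 2.0,
    contrast: float = 160.0,
    base_period: float = 16.0,
    seed: int = 0,
) -> LabeledDataset:
    """A labeled set of synthetic textures in up to 8 classes.

    With the default 45-degree separation, classes 0..3 are sawtooth
    gratings at 0/45/90/135 degrees, class 4 a 0+90 crossed grating,
    class 5 an isotropic smoothed field (then a 45+135 plaid and a
    coarser isotropic field). Within a class, images differ by random
    grating phase / field realisation and Gaussian jitter. The defaults —
    6 classes of 10 images at 128x128, contrast 160, jitter sigma 2 —
    give clearly separated but non-identical classes and stand in for a
    small expression-labeled image set.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_classes > 8:
        raise ValueError("at most 8 classes are supported")
    if n_per_class < 1:
        raise ValueError("need at least 1 image per class")

    rng = np.random.default_rng(seed)
    entries = []
    for c in range(n_classes):
        recipe = _class_spec(c, separation)
        for _ in range(n_per_class):
            entry = {
                "label": c,
                "phases": [float(rng.random()), float(rng.random())],
                "seed": int(rng.integers(0, 2**31 - 1)),
                **recipe,
            }
            entries.append(entry)
    manifest = {
        "params": {
            "n_classes": n_classes,
            "n_per_class": n_per_class,
            "size": size,
            "separation": separation,
            "noise_sigma": noise_sigma,
            "contrast": contrast,
            "base_period": base_period,
            "seed": seed,
        },
        "images": entries,
    }
    return dataset_from_manifest(manifest)


def dataset_from_manifest(manifest: dict) -> LabeledDataset:
    """Regenerate a dataset bit-identically from its manifest."""
    params = manifest["params"]
    common = {
        "size": params["size"],
        "contrast": params["contrast"],
        "noise_sigma": params["noise_sigma"],
    }
    images, labels = [], []
    for entry in manifest["images"]:
        kind = entry["kind"]
        if kind == "grating":
            img = make_oriented_texture(
                entry["direction"],
                kind="grating",
                period=params["base_period"],
                phase=entry["phases"][0],
                seed=entry["seed"],
                **common,
            )
        elif kind == "plaid":
            img = make_plaid_texture(
                tuple(entry["directions"]),
                period=params["base_period"],
                phases=tuple(entry["phases"]),
                seed=entry["seed"],
                **common,
            )
        elif kind == "isotropic":
            img = make_isotropic_texture(
                scale=entry["scale"], seed=entry["seed"], **common
            )
        else:
            raise ValueError(f"unknown texture kind {kind!r} in manifest")
        labels.append(entry["label"])
        images.append(img)
    return LabeledDataset(images=images, labels=labels, manifest=manifest)


def find_lbp_flip_patch(search_budget: int = 100_000, seed: int = 0) -> tuple:
    """Search for a noise-tolerance witness patch.

    Returns a 3x3 integer patch and a copy with a single neighbour pixel
    perturbed such that the centre pixel's 8-bit LBP code changes while
    both 4-bit dominant-direction codes stay identical — the encoder
    absorbing a perturbation that flips an LBP bit. Raises ``RuntimeError``
    if no witness is found within the budget (which would falsify the
    robustness property).
    """
    if search_budget < 1:
        raise ValueError("search_budget must be >= 1")
    rng = np.random.default_rng(seed)
    neighbours = [(r, c) for r in range(3) for c in range(3) if (r, c) != (1, 1)]
    for _ in range(search_budget):
        patch = rng.integers(0, 64, size=(3, 3)).astype(np.int64)
        r, c = neighbours[rng.integers(len(neighbours))]
        delta = int(rng.integers(1, 6)) * (1 if rng.random() < 0.5 else -1)
        perturbed = patch.copy()
        perturbed[r, c] = np.clip(perturbed[r, c] + delta, 0, 255)
        if perturbed[r, c] == patch[r, c]:
            continue
        if lbp_codes(patch)[0, 0] == lbp_codes(perturbed)[0, 0]:
            continue
        a, b = encode_image(patch), encode_image(perturbed)
        if a.code1[0, 0] == b.code1[0, 0] and a.code2[0, 0] == b.code2[0, 0]:
            return patch, perturbed
    raise RuntimeError(
        f"no witness found in {search_budget} trials: the robustness property failed"
    )
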