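"""Noise models and descriptor-accuracy sweeps.

Two corruption models, matching the standard robustness protocol for
texture descriptors:

* salt-and-pepper noise parameterised by corruption density ``p`` (each
  pixel independently replaced by 0 or the maximum intensity with equal
  probability), and
* additive white Gaussian noise parameterised by SNR in dB, with noise
  variance ``P_signal / 10**(snr_db/10)`` where the signal power is the
  mean square intensity of the clean image.

:func:`noise_sweep` corrupts a whole dataset per grid point, extracts the
requested descriptor and runs leave-one-sample-out KNN, emitting a tidy
accuracy table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import evaluate_dataset

__all__ = ["NoiseSpec", "add_salt_pepper", "add_awgn", "apply_noise", "noise_sweep", "plot_sweep"]

MAX_INTENSITY = 255.0


@dataclass(frozen=True)
class NoiseSpec:
    """One corruption condition: kind, level and seed.

    ``level`` is the density ``p`` for ``salt_pepper`` and the SNR in dB
    for ``awgn``.
    """

    kind: str
    level: float
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("salt_pepper", "awgn"):
            raise ValueError("kind must be 'salt_pepper' or 'awgn'")
        if self.kind == "salt_pepper" and not 0.0 <= self.level <= 1.0:
            raise ValueError("salt-and-pepper density must be in [0, 1]")
        if not np.isfinite(self.level):
            raise ValueError("noise level must be finite")


def add_salt_pepper(image, p: float, seed: int | None = None, max_intensity: float = MAX_INTENSITY):
    """Corrupt each pixel independently with probability ``p``.

    Corrupted pixels are set to 0 ("pepper") or ``max_intensity`` ("salt")
    with equal probability. ``p = 0`` returns the input unchanged (a copy);
    identical seeds give identical corruption.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {p}")
    arr = np.asarray(image)
    out = arr.copy()
    if p == 0.0:
        return out
    rng = np.random.default_rng(seed)
    corrupt = rng.random(arr.shape) < p
    salt = rng.random(arr.shape) < 0.5
    out[corrupt & salt] = np.asarray(max_intensity).astype(arr.dtype)
    out[corrupt & ~salt] = np.asarray(0).astype(arr.dtype)
    return out


def add_awgn(image, snr_db: float, seed: int | None = None, max_intensity: float = MAX_INTENSITY):
    """Add zero-mean white Gaussian noise at a given SNR (dB).

    The noise variance is ``mean(image**2) / 10**(snr_db/10)``; the output
    is clipped to ``[0, max_intensity]`` and returned as float64.
    """
    arr = np.asarray(image, dtype=np.float64)
    power = float((arr**2).mean())
    if power == 0.0:
        raise ValueError("image has zero power; SNR is undefined")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    noisy = arr + rng.normal(0.0, sigma, arr.shape)
    return np.clip(noisy, 0.0, max_intensity)


def apply_noise(image, spec: NoiseSpec):
    if spec.kind == "salt_pepper":
        return add_salt_pepper(image, spec.level, seed=spec.seed)
    return add_awgn(image, spec.level, seed=spec.seed)


def noise_sweep(
    dataset,
    descriptor: str,
    grid: list,
    k: int = 1,
    metric: str = "euclidean",
    descriptor_params: dict | None = None,
) -> pd.DataFrame:
    """Accuracy of a descriptor across a grid of noise conditions.

    For each :class:`NoiseSpec` every image is corrupted (with a per-image
    seed derived from the spec's seed), features are extracted and LOSO KNN
    is run. Returns a tidy frame with columns ``noise_kind``, ``level``,
    ``seed``, ``descriptor``, ``accuracy``.
    """
    if not grid:
        raise ValueError("noise grid is empty")
    rows = []
    for spec in grid:
        child = np.random.default_rng(spec.seed)
        image_seeds = child.integers(0, 2**31 - 1, size=dataset.n_samples)
        noisy = [
            apply_noise(img, NoiseSpec(spec.kind, spec.level, int(s)))
            for img, s in zip(dataset.images, image_seeds)
        ]
        result = evaluate_dataset(
            noisy,
            dataset.labels,
            descriptor,
            k=k,
            metric=metric,
            descriptor_params=descriptor_params,
        )
        rows.append(
            {
                "noise_kind": spec.kind,
                "level": spec.level,
                "seed": spec.seed,
                "descriptor": descriptor,
                "accuracy": result.accuracy,
            }
        )
    return pd.DataFrame(rows)


def plot_sweep(table: pd.DataFrame, path) -> None:
    """Accuracy-vs-level curves, one line per descriptor, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    mean = (
        table.groupby(["descriptor", "level"], as_index=False)["accuracy"].mean()
    )
    for name, sub in mean.groupby("descriptor"):
        sub = sub.sort_values("level")
        ax.plot(sub["level"], sub["accuracy"], marker="o", label=str(name))
    kinds = table["noise_kind"].unique()
    ax.set_xlabel("density" if "salt_pepper" in kinds else "SNR (dB)")
    ax.set_ylabel("LOSO accuracy")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
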