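"""Descriptor registry and dataset-level extraction/evaluation helpers."""

from __future__ import annotations

import numpy as np

from .baselines import BaselineConfig, cslbp_feature, lbp_feature, ldp_feature
from .evaluate import EvalResult, LabeledFeatures, loso_knn_evaluate
from .features import DescriptorConfig, extract_lddscp

__all__ = ["DESCRIPTORS", "get_extractor", "extract_matrix", "evaluate_dataset"]

DESCRIPTORS = ("lddscp", "lbp", "cslbp", "ldp")


def get_extractor(name: str, **params):
    """A callable ``image -> feature vector`` for a named descriptor.

    ``params`` are forwarded to :class:`~lddscp.features.DescriptorConfig`
    for ``lddscp`` and to :class:`~lddscp.baselines.BaselineConfig` for the
    baselines.
    """
    if name == "lddscp":
        cfg = DescriptorConfig(**params)
        return lambda image: extract_lddscp(image, cfg)
    if name in ("lbp", "cslbp", "ldp"):
        cfg = BaselineConfig(descriptor=name, **params)
        fn = {"lbp": lbp_feature, "cslbp": cslbp_feature, "ldp": ldp_feature}[name]
        return lambda image: fn(image, cfg)
    raise ValueError(f"unknown descriptor {name!r}; choose from {DESCRIPTORS}")


def extract_matrix(images, name: str = "lddscp", **params) -> np.ndarray:
    """Stack one feature row per image."""
    extractor = get_extractor(name, **params)
    return np.stack([extractor(img) for img in images])


def evaluate_dataset(
    images,
    labels,
    descriptor: str = "lddscp",
    k: int = 1,
    metric: str = "euclidean",
    ids=None,
    descriptor_params: dict | None = None,
) -> EvalResult:
    """Extract features for a labeled image set and run LOSO KNN."""
    matrix = extract_matrix(images, descriptor, **(descriptor_params or {}))
    data = LabeledFeatures(features=matrix, labels=np.asarray(labels), ids=ids)
    return loso_knn_evaluate(data, k=k, metric=metric)
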