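"""Training-set reduction: per-class K-means plus spectral-angle prototypes.

Wrapper band selection retrains an SVM thousands of times, so the labeled
training pool (hundreds of thousands of pixels in a clinical database) is
compressed to a small balanced prototype set: K-means is run independently on
each class, and for each centroid the pixels of that class closest in
spectral angle are kept.  With the defaults (K=100 clusters, 10 pixels per
centroid, 4 classes) the reduced set holds exactly 4000 original pixels,
1000 per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .types import N_CLASSES, LabeledDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReductionConfig:
    k_per_class: int = 100
    pixels_per_centroid: int = 10
    seed: int = 0
    n_init: int = 10

    def __post_init__(self) -> None:
        if self.k_per_class < 1 or self.pixels_per_centroid < 1:
            raise ValueError("cluster and per-centroid counts must be >= 1")


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral Angle Mapper distance: arccos(a.b / (|a||b|)), radians.

    Brightness-invariant — two spectra differing only by a positive gain have
    angle zero — which is why it suits prototype matching on unnormalized
    magnitudes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("undefined angle for zero spectrum")
    return float(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0)))


def _angles_to_centroid(spectra: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(spectra, axis=1)
    cn = np.linalg.norm(centroid)
    if cn == 0 or np.any(norms == 0):
        raise ValueError("undefined angle for zero spectrum")
    cosine = np.clip(spectra @ centroid / (norms * cn), -1.0, 1.0)
    return np.arccos(cosine)


def reduce_training_set(data: LabeledDataset, cfg: ReductionConfig = ReductionConfig()) -> LabeledDataset:
    """Balanced prototype selection; output rows are original input pixels.

    Per class: seeded K-means (k-means++, Euclidean) with ``k_per_class``
    clusters, then for each centroid (in index order) the
    ``pixels_per_centroid`` class pixels with smallest spectral angle to it,
    drawn without replacement across centroids of the class.  Classes with
    fewer pixels than the quota get a proportionally reduced cluster count
    and a warning.
    """
    parts: list[LabeledDataset] = []
    for class_id in range(N_CLASSES):
        mask = data.labels == class_id
        n_avail = int(mask.sum())
        if n_avail == 0:
            raise ValueError(f"class {class_id} absent from training data")
        k = cfg.k_per_class
        quota = k * cfg.pixels_per_centroid
        if n_avail < quota:
            k = max(1, n_avail // cfg.pixels_per_centroid)
            logger.warning(
                "class %d has %d pixels < quota %d; reducing clusters to %d",
                class_id, n_avail, quota, k,
            )
        class_data = data.subset(mask)
        km = KMeans(n_clusters=k, n_init=cfg.n_init, random_state=cfg.seed)
        km.fit(class_data.spectra)
        taken = np.zeros(n_avail, dtype=bool)
        chosen: list[np.ndarray] = []
        for centroid in km.cluster_centers_:
            angles = _angles_to_centroid(class_data.spectra, centroid)
            angles[taken] = np.inf
            order = np.argsort(angles, kind="stable")[: cfg.pixels_per_centroid]
            taken[order] = True
            chosen.append(order)
        parts.append(class_data.subset(np.concatenate(chosen)))
    return LabeledDataset.concatenate(parts)
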