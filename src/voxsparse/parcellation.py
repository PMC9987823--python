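"""Parcellation: K-means over component activations and agreement scores.

Clustering the voxel x K feature matrix assigns every in-mask voxel to one of
K clusters; agreement with the labeled anatomy is scored with the
chance-adjusted mutual information (AMI, max-normalized) and adjusted Rand
index (ARI).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_mutual_info_score, adjusted_rand_score

from .data import AnnotationVolume
from .decomposition import DecompositionResults

__all__ = ["Parcellation", "kmeans_cluster", "ami", "ari", "sweep_k"]


@dataclass
class Parcellation:
    """Hard cluster assignment of in-mask voxels; labels are 0..K-1."""

    labels: np.ndarray
    n_clusters: int
    seed: int
    inertia: float
    method: str = "kmeans"
    source_method: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min(initial=0) < 0 or (
                self.labels.size and self.labels.max() >= self.n_clusters):
            raise ValueError("cluster labels outside 0..K-1")

    def to_tsv(self, path: str | Path, voxel_coords: np.ndarray) -> None:
        df = pd.DataFrame(voxel_coords, columns=["x", "y", "z"])
        df["label"] = self.labels
        df.to_csv(path, sep="\t", index=False)

    def to_nifti(self, path: str | Path, voxel_coords: np.ndarray,
                 grid_dims: tuple[int, int, int]) -> None:
        vol = np.full(grid_dims, -1, dtype=np.int32)
        vol[tuple(np.asarray(voxel_coords).T)] = self.labels
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def kmeans_cluster(components: DecompositionResults, n_clusters: int,
                   seed: int = 0, n_init: int = 10) -> Parcellation:
    """Standard K-means on the voxel x K feature matrix.

    Keeps the best of ``n_init`` seeded restarts by inertia; deterministic
    given ``seed``.
    """
    features = components.features
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > features.shape[0]:
        raise ValueError(
            f"n_clusters={n_clusters} exceeds voxel count {features.shape[0]}")
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    labels = km.fit_predict(features)
    return Parcellation(labels=labels, n_clusters=n_clusters, seed=int(seed),
                        inertia=float(km.inertia_),
                        source_method=components.method)


def _as_labels(x) -> np.ndarray:
    arr = np.asarray(x.labels if isinstance(x, Parcellation) else x)
    return arr.ravel()


def ami(a, b) -> float:
    """Adjusted mutual information (max-normalized); 1 for identical
    partitions, ~0 for independent ones."""
    a, b = _as_labels(a), _as_labels(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_mutual_info_score(a, b, average_method="max"))


def ari(a, b) -> float:
    """Adjusted Rand index; 1 for identical partitions, ~0 for chance."""
    a, b = _as_labels(a), _as_labels(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


def sweep_k(components: DecompositionResults, annotation: AnnotationVolume,
            ks: list[int], seed: int = 0, n_init: int = 10) -> pd.DataFrame:
    """Cluster at every K in ``ks`` and score agreement with anatomy.

    Returns a DataFrame with columns (K, AMI, ARI, inertia), one row per K.
    The anatomy labels are read off the annotation volume at the voxel
    coordinates of the component set's expression matrix.
    """
    if not ks:
        raise ValueError("ks must be nonempty")
    if components.expression is None:
        raise ValueError("component set carries no expression matrix")
    truth = annotation.labels_at(components.expression.voxel_coords)
    rows = []
    for k in ks:
        parc = kmeans_cluster(components, k, seed=seed, n_init=n_init)
        rows.append({"K": k, "AMI": ami(parc.labels, truth),
                     "ARI": ari(parc.labels, truth),
                     "inertia": parc.inertia})
    return pd.DataFrame(rows)
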