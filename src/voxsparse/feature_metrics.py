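"""Per-feature metric suite: anatomical overlap and intrinsic spatial /
sparsity / information measures.

Each learned feature (a per-voxel activation map) is scored with:

- best Dice overlap against the labeled regions, after thresholding the
  feature by 2-means on its scalar values;
- number of connected components of its mean-level isosurface (spatial
  contiguity; ideally one component per anatomical region);
- feature sparsity (voxels / voxels above the mean) and weight sparsity
  (genes / genes above the mean weight);
- Shannon entropy of the binned activation values (total information);
- spatial entropy: Shannon entropy of the 3D gray-level co-occurrence matrix
  of the quantized volume (low when the volume is spatially homogeneous).

The Dice/contiguity pair scores fit to anatomy; the sparsity and entropy
measures are intrinsic, usable when no ground truth exists.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skimage.measure import marching_cubes
from sklearn.cluster import KMeans

from .data import AnnotationVolume, ExpressionMatrix

__all__ = [
    "dice", "threshold_feature", "match_feature_to_regions",
    "region_feature_dice",
    "feature_sparsity", "weight_sparsity", "shannon_entropy",
    "spatial_entropy", "connected_components", "report",
    "FeatureMetricReport", "DEFAULT_OFFSETS",
]

#: the 13 unique 3D neighbor offsets (one per symmetric pair of the 26)
DEFAULT_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    off for off in itertools.product((-1, 0, 1), repeat=3)
    if off > (0, 0, 0)
)


def _as_bool(a) -> np.ndarray:
    if isinstance(a, (set, frozenset)):
        raise TypeError("pass voxel sets as boolean arrays over the grid")
    return np.asarray(a, dtype=bool)


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) of two voxel sets
    (boolean masks over the same grid).  Undefined when both are empty."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("masks are over different grids")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined: both sets empty")
    return 2.0 * int((a & b).sum()) / (na + nb)


def threshold_feature(f: np.ndarray, seed: int = 0) -> tuple[np.ndarray,
                                                             np.ndarray]:
    """Binarize a per-voxel feature by 2-means on its scalar values.

    Returns both cluster-membership masks, lower-center cluster first; they
    partition the voxels.  Constant features cannot be split and raise.
    """
    f = np.asarray(f, dtype=float).ravel()
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite feature values")
    if f.max() == f.min():
        raise ValueError("constant feature: 2-means split undefined")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(f[:, None])
    lo = int(np.argmin(km.cluster_centers_.ravel()))
    return labels == lo, labels != lo


def match_feature_to_regions(
    f: np.ndarray, annotation: AnnotationVolume,
    voxel_coords: np.ndarray | None = None, seed: int = 0,
) -> tuple[int, float]:
    """Best (region, Dice) over all regions and both threshold masks.

    ``f`` is ordered like ``voxel_coords`` (default: the annotation's in-mask
    voxels in scan order).  Ties in Dice go to the smaller region id.
    """
    if voxel_coords is None:
        voxel_coords = annotation.mask_coords()
    voxel_labels = annotation.labels_at(voxel_coords)
    if not annotation.region_ids:
        raise ValueError("annotation has no nonzero regions")
    mask_lo, mask_hi = threshold_feature(f, seed=seed)
    best_region, best_dice = -1, -1.0
    for region in sorted(annotation.region_ids):
        in_region = voxel_labels == region
        if not in_region.any():
            continue
        d = max(dice(mask_lo, in_region), dice(mask_hi, in_region))
        if d > best_dice:
            best_region, best_dice = region, d
    if best_region < 0:
        raise ValueError("no region voxels found at the given coordinates")
    return best_region, best_dice


def region_feature_dice(components, annotation: AnnotationVolume,
                        expression: ExpressionMatrix | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Dice of every (region, feature) combination, regions x features.

    Each cell is the better of the two threshold-mask overlaps for that
    feature against that region; the row-wise maximum identifies the best
    feature for each region (the region-centric view of matching, the
    complement of the feature-centric :func:`match_feature_to_regions`).
    Constant features yield NaN columns.
    """
    if expression is None:
        expression = components.expression
    coords = expression.voxel_coords
    voxel_labels = annotation.labels_at(coords)
    regions = sorted(annotation.region_ids)
    table = np.full((len(regions), components.n_components), np.nan)
    for j in range(components.n_components):
        try:
            lo, hi = threshold_feature(components.features[:, j], seed=seed)
        except ValueError:
            continue
        for i, lab in enumerate(regions):
            reg = voxel_labels == lab
            if reg.any():
                table[i, j] = max(dice(lo, reg), dice(hi, reg))
    return pd.DataFrame(
        table, index=pd.Index(regions, name="region"),
        columns=[f"c{j}" for j in range(components.n_components)])


def _active_ratio(v: np.ndarray, what: str) -> float:
    v = np.asarray(v, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError(f"non-finite {what} values")
    active = int((v > v.mean()).sum())
    if active == 0:
        raise ValueError(f"no {what} above the mean: sparsity undefined")
    return v.size / active


def feature_sparsity(f: np.ndarray) -> float:
    """Total voxels / voxels strictly above the mean activation; >= 1, and
    equals the voxel count when a single voxel is active."""
    return _active_ratio(f, "voxels")


def weight_sparsity(w: np.ndarray) -> float:
    """Total genes / genes strictly above the mean weight; >= 1."""
    return _active_ratio(w, "genes")


def shannon_entropy(f: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy (nats) of the feature's values binned into
    ``n_bins`` uniform-width levels over [min, max]; 0 for constant input."""
    f = np.asarray(f, dtype=float).ravel()
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite feature values")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if f.max() == f.min():
        return 0.0
    counts, _ = np.histogram(f, bins=n_bins, range=(f.min(), f.max()))
    p = counts[counts > 0] / f.size
    return float(-(p * np.log(p)).sum())


def _quantize(values: np.ndarray, n_levels: int) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.zeros(values.shape, dtype=int)
    q = ((values - vmin) / (vmax - vmin) * n_levels).astype(int)
    return np.minimum(q, n_levels - 1)


def spatial_entropy(
    vol: np.ndarray, n_levels: int = 16,
    offsets: tuple[tuple[int, int, int], ...] = DEFAULT_OFFSETS,
    mask: np.ndarray | None = None,
) -> float:
    """Entropy (nats) of the 3D gray-level co-occurrence matrix.

    The volume is quantized to ``n_levels`` uniform levels over the in-mask
    value range; co-occurrences of level pairs are accumulated over every
    in-mask voxel pair related by one of ``offsets`` (symmetrized), and the
    Shannon entropy of the normalized matrix is returned, treating each
    (i, j) cell as one symbol.  Spatially homogeneous volumes score low.
    """
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    if not offsets or any(o == (0, 0, 0) for o in offsets):
        raise ValueError("offsets must be nonzero and nonempty")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    mask = _as_bool(mask)
    if not mask.any():
        raise ValueError("empty mask")

    q = np.zeros(vol.shape, dtype=int)
    q[mask] = _quantize(vol[mask], n_levels)

    counts = np.zeros((n_levels, n_levels))
    dims = vol.shape
    for off in offsets:
        src = tuple(slice(max(-o, 0), dims[i] - max(o, 0))
                    for i, o in enumerate(off))
        dst = tuple(slice(max(o, 0), dims[i] + min(o, 0))
                    for i, o in enumerate(off))
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        a = q[src][valid]
        b = q[dst][valid]
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurring in-mask voxel pairs at these offsets")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def connected_components(vol: np.ndarray, threshold="mean") -> int:
    """Number of connected components of the isosurface at ``threshold``.

    Runs marching cubes at the level (default: the volume's mean value),
    builds the vertex adjacency graph from shared triangle edges, and counts
    graph components.  A threshold outside the value range yields no surface:
    0 components, with a warning.
    """
    vol = np.asarray(vol, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected a 3D volume")
    if not np.all(np.isfinite(vol)):
        raise ValueError("non-finite volume values")
    level = float(vol.mean()) if threshold == "mean" else float(threshold)
    if not vol.min() < level < vol.max():
        warnings.warn(
            f"threshold {level} outside value range "
            f"[{vol.min()}, {vol.max()}]: no isosurface", stacklevel=2)
        return 0
    verts, faces, _, _ = marching_cubes(vol, level=level)
    g = nx.Graph()
    g.add_nodes_from(range(len(verts)))
    for tri in faces:
        g.add_edge(int(tri[0]), int(tri[1]))
        g.add_edge(int(tri[1]), int(tri[2]))
        g.add_edge(int(tri[2]), int(tri[0]))
    g.remove_nodes_from([n for n in range(len(verts)) if g.degree[n] == 0])
    return nx.number_connected_components(g)


@dataclass
class FeatureMetricReport:
    """Per-feature metric table plus aggregates.

    ``per_feature`` has one row per component with columns (feature,
    matched_region, dice, n_connected_components, feature_sparsity,
    weight_sparsity, shannon_entropy, spatial_entropy); failed metrics are
    NaN.  ``aggregates`` holds the unique matched-region count, per-metric
    means, and the exploratory Pearson correlation between Dice and the
    connected-components count across features.
    """

    per_feature: pd.DataFrame
    aggregates: dict

    @property
    def unique_region_count(self) -> int:
        return int(self.aggregates["unique_region_count"])

    def to_csv(self, path: str | Path) -> None:
        self.per_feature.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump(self.aggregates, fh, indent=1, default=float)


_METRIC_COLS = ("dice", "n_connected_components", "feature_sparsity",
                "weight_sparsity", "shannon_entropy", "spatial_entropy")


def report(components, annotation: AnnotationVolume,
           expression: ExpressionMatrix | None = None, seed: int = 0,
           n_bins: int = 256, n_levels: int = 16,
           offsets: tuple[tuple[int, int, int], ...] = DEFAULT_OFFSETS,
           ) -> FeatureMetricReport:
    """Score every feature of a component set with the full metric suite.

    Per-feature failures (e.g. a constant feature) are recorded as missing
    values rather than aborting the report.  Spatial metrics are computed on
    the feature embedded into the 3D grid, with out-of-mask voxels held at
    the feature's minimum so background never crosses the mean isosurface.
    """
    if expression is None:
        expression = components.expression
    if expression is None:
        raise ValueError("no expression matrix available for coordinates")
    coords = expression.voxel_coords
    mask = annotation.mask

    rows = []
    for j in range(components.n_components):
        f = components.features[:, j]
        row: dict = {"feature": j}
        try:
            region, d = match_feature_to_regions(f, annotation, coords,
                                                 seed=seed)
            row["matched_region"], row["dice"] = region, d
        except ValueError:
            row["matched_region"], row["dice"] = np.nan, np.nan
        vol = None
        try:
            vol = expression.embed(f, fill=float(np.min(f)))
        except ValueError:
            pass
        try:
            if vol is None:
                raise ValueError("no grid embedding")
            row["n_connected_components"] = connected_components(
                vol, threshold=float(np.mean(f)))
        except ValueError:
            row["n_connected_components"] = np.nan
        for name, fn, arg in (
            ("feature_sparsity", feature_sparsity, f),
            ("shannon_entropy", lambda v: shannon_entropy(v, n_bins), f),
        ):
            try:
                row[name] = fn(arg)
            except ValueError:
                row[name] = np.nan
        try:
            if components.weights is None:
                raise ValueError("no weights")
            row["weight_sparsity"] = weight_sparsity(components.weights[:, j])
        except ValueError:
            row["weight_sparsity"] = np.nan
        try:
            if vol is None:
                raise ValueError("no grid embedding")
            row["spatial_entropy"] = spatial_entropy(
                vol, n_levels=n_levels, offsets=offsets, mask=mask)
        except ValueError:
            row["spatial_entropy"] = np.nan
        rows.append(row)

    df = pd.DataFrame(rows)
    matched = df["matched_region"].dropna()
    aggregates = {
        "unique_region_count": int(matched.nunique()),
        **{f"mean_{c}": float(df[c].mean()) for c in _METRIC_COLS},
    }
    pair = df[["dice", "n_connected_components"]].dropna()
    if len(pair) >= 2 and pair["dice"].std() > 0 and \
            pair["n_connected_components"].std() > 0:
        aggregates["dice_cc_correlation"] = float(
            np.corrcoef(pair["dice"], pair["n_connected_components"])[0, 1])
    else:
        aggregates["dice_cc_correlation"] = float("nan")
    return FeatureMetricReport(per_feature=df, aggregates=aggregates)
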