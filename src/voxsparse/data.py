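"""Core data containers: the voxel-by-gene expression matrix and the labeled
anatomy volume.

An :class:`ExpressionMatrix` holds a dense matrix of expression values for the
in-mask voxels of a 3D grid, with one row per voxel (indexed by its integer
grid coordinate) and one column per gene.  An :class:`AnnotationVolume` holds
the integer region-label grid that plays the role of ground-truth anatomy; 0
marks voxels outside the tissue mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "AnnotationVolume"]

_COORD_COLS = ["x", "y", "z"]


@dataclass
class ExpressionMatrix:
    """Dense voxel x gene expression matrix over the in-mask voxels of a grid.

    Parameters
    ----------
    values : ndarray, shape (n_voxels, n_genes)
        Expression values; raw (nonnegative expression energy) or z-scored,
        depending on provenance.
    voxel_coords : ndarray of int, shape (n_voxels, 3)
        0-based (x, y, z) grid coordinate of each row.
    gene_ids : list of str
        Column identifiers, unique and ordered.
    grid_dims : tuple of int, optional
        Shape of the enclosing 3D grid; required to embed per-voxel vectors
        back into a volume.
    """

    values: np.ndarray
    voxel_coords: np.ndarray
    gene_ids: list[str]
    grid_dims: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (voxels x genes)")
        if self.voxel_coords.shape != (self.values.shape[0], 3):
            raise ValueError(
                f"voxel_coords shape {self.voxel_coords.shape} does not match "
                f"{self.values.shape[0]} rows"
            )
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError("gene_ids length does not match column count")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicated gene ids")
        coords = {tuple(c) for c in self.voxel_coords}
        if len(coords) != self.voxel_coords.shape[0]:
            raise ValueError("duplicated voxel coordinates")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_ids: list[str]) -> np.ndarray:
        """Column indices of the given genes, in the given order."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """A new matrix restricted to the given genes (kept in given order)."""
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            self.values[:, idx], self.voxel_coords.copy(), list(gene_ids),
            grid_dims=self.grid_dims,
        )

    def embed(self, per_voxel: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector into the 3D grid; `fill` outside mask."""
        if self.grid_dims is None:
            raise ValueError("grid_dims unknown; cannot embed into a volume")
        per_voxel = np.asarray(per_voxel, dtype=float)
        if per_voxel.shape != (self.n_voxels,):
            raise ValueError("per-voxel vector length mismatch")
        vol = np.full(self.grid_dims, fill, dtype=float)
        vol[tuple(self.voxel_coords.T)] = per_voxel
        return vol

    # -- TSV dialect: gene-id header, first three columns are x, y, z -------
    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.gene_ids)
        for i, c in enumerate(_COORD_COLS):
            df.insert(i, c, self.voxel_coords[:, i])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, grid_dims: tuple[int, int, int] | None = None
    ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:3]) != _COORD_COLS:
            raise ValueError("expected leading x, y, z coordinate columns")
        coords = df[_COORD_COLS].to_numpy(dtype=int)
        genes = [str(c) for c in df.columns[3:]]
        return cls(df.iloc[:, 3:].to_numpy(dtype=float), coords, genes,
                   grid_dims=grid_dims)


@dataclass
class AnnotationVolume:
    """3D integer label grid; 0 = outside the tissue mask."""

    labels: np.ndarray
    region_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        present = sorted(int(v) for v in np.unique(self.labels) if v != 0)
        if not self.region_ids:
            self.region_ids = present
        else:
            self.region_ids = sorted(int(r) for r in self.region_ids)

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def mask(self) -> np.ndarray:
        return self.labels != 0

    def mask_coords(self) -> np.ndarray:
        """(n, 3) coordinates of in-mask voxels, in C scan order."""
        return np.argwhere(self.mask)

    def labels_at(self, coords: np.ndarray) -> np.ndarray:
        """Region label of each (x, y, z) row in `coords`."""
        coords = np.asarray(coords, dtype=int)
        return self.labels[tuple(coords.T)]

    def region_mask(self, region: int) -> np.ndarray:
        return self.labels == region

    def region_size(self, region: int) -> int:
        return int(np.count_nonzero(self.labels == region))

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int32), affine=np.eye(4))
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "AnnotationVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj).astype(np.int32))
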