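"""Pre-processing: per-gene z-scoring and a consistency-based gene filter.

The analysis matrix downstream methods consume is z-scored per gene, so that
every gene has mean 0 and standard deviation 1 across in-mask voxels.  The
consistency filter mirrors the common quality-control step for replicated
spatial expression assays: each gene measured in two paired experiments is
ranked by the Pearson correlation of its two spatial profiles, and the least
reproducible fraction is dropped.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .data import ExpressionMatrix

__all__ = ["ztransform", "consistency_filter"]

logger = logging.getLogger(__name__)

#: SD convention is population (divide by n), fixed for reproducibility.
_DDOF = 0


def ztransform(raw: ExpressionMatrix, strict: bool = False) -> ExpressionMatrix:
    """Z-score each gene column to mean 0, SD 1 across voxels.

    Constant columns have undefined z-scores; by default they are dropped with
    a logged warning, with ``strict=True`` they raise ``ValueError``.  Voxel
    order and the order of surviving genes are preserved.
    """
    values = np.asarray(raw.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in expression matrix")
    sd = values.std(axis=0, ddof=_DDOF)
    constant = sd == 0.0
    if constant.any():
        dropped = [g for g, c in zip(raw.gene_ids, constant) if c]
        if strict:
            raise ValueError(f"constant gene columns: {dropped}")
        logger.warning("dropping %d constant gene column(s): %s",
                       len(dropped), dropped)
        keep = ~constant
        values = values[:, keep]
        gene_ids = [g for g, c in zip(raw.gene_ids, constant) if not c]
        sd = sd[keep]
    else:
        gene_ids = list(raw.gene_ids)
    z = (values - values.mean(axis=0)) / sd
    return ExpressionMatrix(z, raw.voxel_coords.copy(), gene_ids,
                            grid_dims=raw.grid_dims)


def consistency_filter(
    a: ExpressionMatrix, b: ExpressionMatrix, drop_fraction: float
) -> list[str]:
    """Rank shared genes by the Pearson correlation of their profiles in the
    two matrices and drop the least-correlated fraction.

    Returns the retained gene ids ordered by decreasing correlation; ties are
    broken by position in ``a.gene_ids``.  The survivor count is
    ``ceil(n_genes * (1 - drop_fraction))``.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    if set(a.gene_ids) != set(b.gene_ids):
        diff = sorted(set(a.gene_ids) ^ set(b.gene_ids))
        raise ValueError(f"gene sets differ; symmetric difference: {diff}")
    if a.n_voxels != b.n_voxels:
        raise ValueError("voxel grids differ between the two matrices")

    b_idx = b.gene_index(a.gene_ids)
    av = a.values - a.values.mean(axis=0)
    bv = b.values[:, b_idx] - b.values[:, b_idx].mean(axis=0)
    denom = np.sqrt((av**2).sum(axis=0) * (bv**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, (av * bv).sum(axis=0) / denom, np.nan)
    corr = np.where(np.isnan(corr), -np.inf, corr)  # degenerate genes rank last
    # round away last-ulp noise so exact ties (e.g. b == a) break by gene id
    corr = np.round(corr, 12)

    n_keep = math.ceil(len(a.gene_ids) * (1.0 - drop_fraction))
    # stable sort on -corr keeps gene-id (input) order among ties
    order = np.argsort(-corr, kind="stable")
    return [a.gene_ids[i] for i in order[:n_keep]]
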