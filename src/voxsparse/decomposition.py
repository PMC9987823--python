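"""Representation learning on the voxel x gene matrix.

The centrepiece is a from-scratch implementation of sparse filtering: an
unsupervised feature learner whose only structural hyperparameter is the
number of components K.  Writing the z-scored expression matrix as columns
x^(i) (one per voxel, with genes as input dimensions), each feature j is a
linear map f_j^(i) = w_j^T x^(i) passed through the smooth soft-absolute
nonlinearity g(u) = sqrt(u^2 + eps).  The activation matrix (features x
voxels) is then

  1. row-normalized: each feature divided by its l2 norm across voxels
     (lifetime-sparsity / dispersal normalization),
  2. column-normalized: each voxel's feature vector divided by its l2 norm
     (population-sparsity normalization),

and the objective is the summed l1 norm of the doubly-normalized matrix,
minimized over W by limited-memory BFGS.  Minimizing the l1 norm of unit
vectors drives each voxel's representation onto few features, while the
first normalization spreads activity evenly across features.

The comparison methods (PCA, kernel PCA, ICA, sparse PCA, dictionary
learning) are thin adapters over scikit-learn, exposed through
:func:`decompose` with the same results container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import AnnotationVolume, ExpressionMatrix

__all__ = [
    "SparseFilter", "DecompositionResults", "SparseFilterResults",
    "sparse_filter", "decompose", "sft_objective", "soft_absolute",
    "METHODS", "KPCA_KERNELS",
]

METHODS = ("sft", "pca", "kpca", "ica", "spca", "dlsc")
KPCA_KERNELS = ("quadratic", "cubic", "rbf", "sigmoid")

#: default curvature of the soft-absolute surrogate for |u|
SOFT_ABS_EPS = 1e-8


def soft_absolute(u: np.ndarray, eps: float = SOFT_ABS_EPS) -> np.ndarray:
    """Smooth surrogate for ``|u|``: sqrt(u**2 + eps)."""
    return np.sqrt(u * u + eps)


def _l2_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalize; returns (normalized matrix, row norms)."""
    norms = np.sqrt((x * x).sum(axis=1))
    if np.any(norms == 0):
        raise ValueError("zero row norm: normalization undefined")
    return x / norms[:, None], norms


def _l2_rows_grad(x: np.ndarray, norms: np.ndarray,
                  d: np.ndarray) -> np.ndarray:
    """Backpropagate through y = x / ||x||_2 (per row).

    With y_ij = x_ij / n_i, dL/dx_ik = d_ik/n_i - x_ik (sum_j d_ij x_ij)/n_i^3.
    """
    dot = (d * x).sum(axis=1)
    return d / norms[:, None] - x * (dot / norms**3)[:, None]


def sft_objective(features_raw: np.ndarray) -> float:
    """Sparse-filtering objective of a given voxel x K activation matrix.

    Applies both normalizations — each feature (column) by its l2 norm across
    voxels, then each voxel's feature vector (row) by its l2 norm — and
    returns the summed l1 norm.  Pure function of the activations; used for
    optimizer-trace verification and gradient checks.  Exactly invariant to
    scaling the input by any positive constant.
    """
    f = np.asarray(features_raw, dtype=float)
    if f.ndim != 2:
        raise ValueError("activation matrix must be 2-D (voxels x features)")
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite activations")
    # internally features are rows; the public surface is voxels x features
    ft, _ = _l2_rows(f.T)        # feature rows across examples
    fhat, _ = _l2_rows(ft.T)     # example rows across features
    return float(np.abs(fhat).sum())


class SparseFilter:
    """Sparse-filtering model of a z-scored voxel x gene expression matrix.

    Parameters
    ----------
    expression : ExpressionMatrix
        The analysis matrix (voxels x genes, z-scored per gene).
    n_components : int
        Number of features K to learn; must not exceed the voxel count.
    eps : float
        Curvature of the soft-absolute activation g(u) = sqrt(u^2 + eps).
    max_iter : int
        L-BFGS iteration cap.
    gtol : float
        Projected-gradient-norm stopping tolerance.
    init : {"kmeans", "random"}
        Start point for the weights: seeded K-means centroids of the
        expression matrix (default; deterministic and markedly more robust
        to the seed than a random start on this nonconvex objective, in the
        spirit of the SVD initialization of dictionary learning), or seeded
        standard-normal entries.

    Examples
    --------
    >>> model = SparseFilter(expr, n_components=8)
    >>> res = model.fit(seed=0)
    >>> res.features_.shape            # (n_voxels, 8)
    """

    def __init__(self, expression: ExpressionMatrix, n_components: int,
                 eps: float = SOFT_ABS_EPS, max_iter: int = 500,
                 gtol: float = 1e-6, init: str = "kmeans"):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        if n_components > expression.n_voxels:
            raise ValueError(
                f"n_components={n_components} exceeds voxel count "
                f"{expression.n_voxels}")
        if not np.all(np.isfinite(expression.values)):
            raise ValueError("non-finite values in expression matrix")
        self.expression = expression
        self.n_components = int(n_components)
        self.eps = float(eps)
        self.max_iter = int(max_iter)
        self.gtol = float(gtol)
        if init not in ("kmeans", "random"):
            raise ValueError("init must be 'kmeans' or 'random'")
        self.init = init
        # examples are voxels (columns), inputs are genes (rows)
        self._x = np.ascontiguousarray(expression.values.T)

    # -- objective & analytic gradient --------------------------------------
    def _objective_grad(self, w_flat: np.ndarray) -> tuple[float, np.ndarray]:
        k, g = self.n_components, self._x.shape[0]
        w = w_flat.reshape(k, g)
        f0 = w @ self._x                       # K x M linear activations
        fs = np.sqrt(f0 * f0 + self.eps)       # soft-absolute
        nfs, row_norms = _l2_rows(fs)          # per-feature across examples
        fhat_t, col_norms = _l2_rows(nfs.T)    # per-example across features
        obj = float(fhat_t.sum())              # entries are positive

        d = np.ones_like(fhat_t)
        d = _l2_rows_grad(nfs.T, col_norms, d).T
        d = _l2_rows_grad(fs, row_norms, d)
        d *= f0 / fs                           # through the soft-absolute
        return obj, (d @ self._x.T).ravel()

    def objective(self, w: np.ndarray) -> float:
        """Objective value at a weight matrix (K x genes or flat)."""
        return self._objective_grad(np.ravel(w))[0]

    def fit(self, seed: int = 0, w0: np.ndarray | None = None,
            ) -> "SparseFilterResults":
        """Minimize the objective by L-BFGS from a seeded Gaussian start.

        Returns a :class:`SparseFilterResults` whose ``features_`` are the
        doubly-normalized activations and whose ``objective_trace`` holds the
        objective at the start point and after every accepted iterate.
        """
        k, g = self.n_components, self._x.shape[0]
        if w0 is None:
            rng = np.random.default_rng(seed)
            if self.init == "kmeans":
                from sklearn.cluster import KMeans
                km = KMeans(n_clusters=k, n_init=10, random_state=seed)
                km.fit(self.expression.values)
                # jitter keeps rows nonzero (the K=1 centroid of z-scored
                # data is the zero vector, whose normalization is undefined)
                w0 = km.cluster_centers_ + 0.01 * rng.standard_normal((k, g))
            else:
                w0 = rng.standard_normal((k, g))
        w0 = np.asarray(w0, dtype=float).reshape(k, g)

        trace: list[float] = [self.objective(w0)]
        res = minimize(
            self._objective_grad, w0.ravel(), jac=True, method="L-BFGS-B",
            callback=lambda xk: trace.append(self.objective(xk)),
            options={"maxiter": self.max_iter, "gtol": self.gtol,
                     "maxcor": 10},
        )
        w = res.x.reshape(k, g)
        f0 = w @ self._x
        fs = np.sqrt(f0 * f0 + self.eps)
        nfs, _ = _l2_rows(fs)
        fhat_t, _ = _l2_rows(nfs.T)            # M x K doubly-normalized
        return SparseFilterResults(
            model=self,
            weights=w.T.copy(),                # genes x K
            features=fhat_t.copy(),            # voxels x K
            method="sft",
            hyperparams={"eps": self.eps, "max_iter": self.max_iter,
                         "gtol": self.gtol, "n_components": k,
                         "init": self.init},
            seed=int(seed),
            gene_ids=list(self.expression.gene_ids),
            expression=self.expression,
            objective_trace=trace,
            converged=bool(res.success),
            n_iter=int(res.nit),
        )


@dataclass
class DecompositionResults:
    """A fitted component set: per-gene loadings paired with per-voxel
    activations, plus provenance (method, hyperparameters, seed).

    ``weights`` is genes x K (None for kernel PCA, which exposes no gene
    loadings); ``features`` is voxels x K.
    """

    weights: np.ndarray | None
    features: np.ndarray
    method: str
    hyperparams: dict[str, Any]
    seed: int
    gene_ids: list[str]
    expression: ExpressionMatrix | None = None
    objective_trace: list[float] | None = None
    converged: bool | None = None
    n_iter: int | None = None
    model: Any = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape[1] != self.features.shape[1]:
                raise ValueError("weights / features column count mismatch")
            if self.weights.shape[0] != len(self.gene_ids):
                raise ValueError("weights row count != number of genes")

    @property
    def n_components(self) -> int:
        return self.features.shape[1]

    @property
    def has_weights(self) -> bool:
        return self.weights is not None

    # -- downstream stages hang off the results object ----------------------
    def parcellate(self, n_clusters: int, seed: int = 0, n_init: int = 10):
        from .parcellation import kmeans_cluster
        return kmeans_cluster(self, n_clusters, seed=seed, n_init=n_init)

    def feature_report(self, annotation: AnnotationVolume, seed: int = 0,
                       **config):
        from .feature_metrics import report
        return report(self, annotation, self.expression, seed=seed, **config)

    def rank_genes(self, rule: str = "max_abs") -> list[str]:
        from .compression import rank_genes
        return rank_genes(self, rule=rule)

    def top_genes(self, feature: int, n: int = 10) -> list[str]:
        from .probe import top_genes
        if self.weights is None:
            raise ValueError(f"method {self.method!r} exposes no gene weights")
        return top_genes(self.weights[:, feature], self.gene_ids, n)

    def summary(self) -> str:
        lines = [
            "Decomposition Results",
            "=" * 42,
            f"method:        {self.method}",
            f"components:    {self.n_components}",
            f"voxels:        {self.features.shape[0]}",
            f"genes:         {len(self.gene_ids)}",
            f"seed:          {self.seed}",
            f"hyperparams:   {json.dumps(self.hyperparams, sort_keys=True)}",
        ]
        if self.objective_trace:
            lines += [
                f"iterations:    {self.n_iter}",
                f"converged:     {self.converged}",
                f"objective:     {self.objective_trace[0]:.6g} -> "
                f"{self.objective_trace[-1]:.6g}",
            ]
        if self.weights is None:
            lines.append("gene weights:  unavailable for this method")
        return "\n".join(lines)

    # -- serialization: weights.tsv / features.tsv / meta.json --------------
    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.weights is not None:
            pd.DataFrame(
                self.weights, index=pd.Index(self.gene_ids, name="gene"),
                columns=[f"c{j}" for j in range(self.n_components)],
            ).to_csv(outdir / "weights.tsv", sep="\t")
        fdf = pd.DataFrame(
            self.features, columns=[f"c{j}" for j in range(self.n_components)])
        if self.expression is not None:
            for i, c in enumerate(("x", "y", "z")):
                fdf.insert(i, c, self.expression.voxel_coords[:, i])
        fdf.to_csv(outdir / "features.tsv", sep="\t", index=False)
        meta = {
            "method": self.method,
            "hyperparams": self.hyperparams,
            "seed": self.seed,
            "gene_ids": self.gene_ids,
            "objective_trace": self.objective_trace,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "has_weights": self.has_weights,
        }
        with open(outdir / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, outdir: str | Path,
             expression: ExpressionMatrix | None = None,
             ) -> "DecompositionResults":
        outdir = Path(outdir)
        with open(outdir / "meta.json") as fh:
            meta = json.load(fh)
        fdf = pd.read_csv(outdir / "features.tsv", sep="\t")
        feat_cols = [c for c in fdf.columns if c.startswith("c")]
        features = fdf[feat_cols].to_numpy(dtype=float)
        weights = None
        if meta.get("has_weights"):
            wdf = pd.read_csv(outdir / "weights.tsv", sep="\t", index_col=0)
            weights = wdf.to_numpy(dtype=float)
        return cls(
            weights=weights, features=features, method=meta["method"],
            hyperparams=meta["hyperparams"], seed=meta["seed"],
            gene_ids=meta["gene_ids"], expression=expression,
            objective_trace=meta.get("objective_trace"),
            converged=meta.get("converged"), n_iter=meta.get("n_iter"),
        )


class SparseFilterResults(DecompositionResults):
    """Results of a sparse-filtering fit; ``objective_trace`` is guaranteed
    non-increasing (within line-search tolerance) by the minimizer."""


def sparse_filter(expression: ExpressionMatrix, n_components: int,
                  max_iter: int = 500, seed: int = 0,
                  eps: float = SOFT_ABS_EPS,
                  init: str = "kmeans") -> SparseFilterResults:
    """Convenience wrapper: fit :class:`SparseFilter` in one call."""
    return SparseFilter(expression, n_components, eps=eps,
                        max_iter=max_iter, init=init).fit(seed=seed)


def _kpca_kernel(kernel: str) -> dict[str, Any]:
    table = {
        "quadratic": {"kernel": "poly", "degree": 2},
        "cubic": {"kernel": "poly", "degree": 3},
        "rbf": {"kernel": "rbf"},
        "sigmoid": {"kernel": "sigmoid"},
    }
    if kernel not in table:
        raise ValueError(f"unknown kernel {kernel!r}; choose {KPCA_KERNELS}")
    return table[kernel]


def decompose(expression: ExpressionMatrix, method: str, n_components: int,
              hyperparams: dict[str, Any] | None = None, seed: int = 0,
              ) -> DecompositionResults:
    """Learn K components with any supported method.

    ``method`` is one of ``sft`` (bespoke sparse filtering), ``pca``,
    ``kpca`` (needs ``kernel``), ``ica``, ``spca`` or ``dlsc`` (both need the
    l1 penalty ``alpha``).  The scikit-learn adapters populate gene weights
    whenever the method exposes loadings; kernel PCA does not, and its
    ``weights`` field is ``None`` rather than a back-projection.
    """
    hp = dict(hyperparams or {})
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "sft":
        return SparseFilter(
            expression, n_components, eps=hp.get("eps", SOFT_ABS_EPS),
            max_iter=hp.get("max_iter", 500), gtol=hp.get("gtol", 1e-6),
            init=hp.get("init", "kmeans"),
        ).fit(seed=seed)

    x = expression.values
    k = n_components
    alpha = hp.get("alpha")
    if method in ("spca", "dlsc"):
        if alpha is None:
            raise ValueError(f"{method} requires the l1 penalty 'alpha'")
        if alpha < 0:
            raise ValueError("alpha must be nonnegative")

    if method == "pca":
        from sklearn.decomposition import PCA
        est = PCA(n_components=k, random_state=seed)
        features = est.fit_transform(x)
        weights = est.components_.T
    elif method == "kpca":
        from sklearn.decomposition import KernelPCA
        kernel = hp.get("kernel")
        if kernel is None:
            raise ValueError("kpca requires a 'kernel' hyperparameter")
        est = KernelPCA(n_components=k, random_state=seed,
                        **_kpca_kernel(kernel))
        features = est.fit_transform(x)
        weights = None
    elif method == "ica":
        from sklearn.decomposition import FastICA
        est = FastICA(n_components=k, random_state=seed,
                      max_iter=hp.get("max_iter", 500))
        features = est.fit_transform(x)
        weights = est.components_.T
    elif method == "spca":
        from sklearn.decomposition import SparsePCA
        est = SparsePCA(n_components=k, alpha=alpha, random_state=seed,
                        max_iter=hp.get("max_iter", 1000))
        features = est.fit_transform(x)
        weights = est.components_.T
    else:  # dlsc
        from sklearn.decomposition import DictionaryLearning
        est = DictionaryLearning(
            n_components=k, alpha=alpha, random_state=seed,
            max_iter=hp.get("max_iter", 500),
            transform_algorithm="lasso_lars", transform_alpha=alpha,
        )
        features = est.fit_transform(x)
        weights = est.components_.T

    hp_out = {"n_components": k}
    hp_out.update({key: v for key, v in hp.items()})
    return DecompositionResults(
        weights=weights, features=features, method=method,
        hyperparams=hp_out, seed=int(seed),
        gene_ids=list(expression.gene_ids), expression=expression,
    )
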