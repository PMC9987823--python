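"""Minimal marker-gene probes: classify a region from a 10-gene panel.

The gene weights of a feature matched to an anatomical region are compressed
further with a supervised step: take the genes with the largest absolute
weights, mean-center and standard-scale them, and train an l2-regularized
logistic regression from those genes to voxel-in-region membership under
shuffled, stratified 5-fold cross-validation.  Held-out AUROC and AUPRC per
fold quantify how well the minimal panel probes for its region; AUPRC is
read against the region's base rate (its fraction of in-mask voxels), which
is the chance level under class imbalance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .data import AnnotationVolume, ExpressionMatrix

__all__ = ["top_genes", "train_probe", "ProbePanel"]


def top_genes(weights: np.ndarray, gene_ids: list[str], n: int = 10,
              ) -> list[str]:
    """The ``n`` genes with the largest absolute weights, descending;
    ties break by gene-id order.  All-zero weights warn of degeneracy."""
    weights = np.asarray(weights, dtype=float).ravel()
    if len(weights) != len(gene_ids):
        raise ValueError("weights / gene_ids length mismatch")
    if n > len(gene_ids):
        raise ValueError(f"n={n} exceeds gene count {len(gene_ids)}")
    if np.all(weights == 0):
        warnings.warn("all weights are zero: top-gene order is degenerate",
                      stacklevel=2)
    order = np.argsort(-np.abs(weights), kind="stable")
    return [gene_ids[i] for i in order[:n]]


@dataclass
class ProbePanel:
    """A trained gene panel for one region with cross-validated scores."""

    region: int
    gene_ids: list[str]
    fold_auroc: list[float]
    fold_auprc: list[float]
    base_rate: float
    seed: int
    coefficients: list[list[float]] = field(default_factory=list)

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.fold_auroc))

    @property
    def mean_auprc(self) -> float:
        return float(np.mean(self.fold_auprc))

    def summary(self) -> str:
        return "\n".join([
            f"Probe panel for region {self.region}",
            f"genes ({len(self.gene_ids)}): {', '.join(self.gene_ids)}",
            f"base rate: {self.base_rate:.4f}",
            "fold AUROC: " + ", ".join(f"{s:.3f}" for s in self.fold_auroc)
            + f"  (mean {self.mean_auroc:.3f})",
            "fold AUPRC: " + ", ".join(f"{s:.3f}" for s in self.fold_auprc)
            + f"  (mean {self.mean_auprc:.3f})",
        ])

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "region": self.region, "gene_ids": self.gene_ids,
                "fold_auroc": self.fold_auroc,
                "fold_auprc": self.fold_auprc,
                "mean_auroc": self.mean_auroc,
                "mean_auprc": self.mean_auprc,
                "base_rate": self.base_rate, "seed": self.seed,
            }, fh, indent=1)


def train_probe(expression: ExpressionMatrix, annotation: AnnotationVolume,
                region: int, genes: list[str], folds: int = 5,
                seed: int = 0, C: float = 1.0) -> ProbePanel:
    """Cross-validate a logistic-regression probe of ``region`` from the
    given gene panel.

    Scaling statistics are fit on each training split only (no leakage);
    folds are stratified so small regions keep positives in every fold.
    """
    voxel_labels = annotation.labels_at(expression.voxel_coords)
    y = (voxel_labels == region).astype(int)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError(f"region {region} absent from the annotation")
    if n_pos < folds:
        raise ValueError(
            f"region {region} has {n_pos} voxels, fewer than {folds} folds")
    x = expression.values[:, expression.gene_index(genes)]

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aurocs, auprcs, coefs = [], [], []
    for train_idx, test_idx in cv.split(x, y):
        scaler = StandardScaler().fit(x[train_idx])
        clf = LogisticRegression(C=C, max_iter=1000)  # l2 penalty (default)
        clf.fit(scaler.transform(x[train_idx]), y[train_idx])
        scores = clf.predict_proba(scaler.transform(x[test_idx]))[:, 1]
        aurocs.append(float(roc_auc_score(y[test_idx], scores)))
        auprcs.append(float(average_precision_score(y[test_idx], scores)))
        coefs.append([float(c) for c in clf.coef_.ravel()])

    return ProbePanel(
        region=int(region), gene_ids=list(genes),
        fold_auroc=aurocs, fold_auprc=auprcs,
        base_rate=float(n_pos / len(y)), seed=int(seed),
        coefficients=coefs,
    )
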