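"""Hierarchical clustering of pooled samples on the final receptor panel.

Samples are clustered on their reference-relative (% of housekeeping gene)
expression of the final targets; agglomeration is delegated to
scipy.cluster.hierarchy behind this module's surface, with the full merge
history retained so the dendrogram can be re-cut at any k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .io_core import ValidationError
from .normalize import ExpressionMatrix

logger = logging.getLogger("gpcrhunt")

_LINKAGES = ("ward", "average", "complete")
_DISTANCES = ("euclidean", "correlation")


@dataclass
class ClusterConfig:
    k: int = 12
    distance: str = "euclidean"
    linkage: str = "ward"
    missing_policy: str = "zero_impute"  # or "pairwise_scale"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if self.distance not in _DISTANCES:
            raise ValidationError(f"unknown distance {self.distance!r}")
        if self.linkage not in _LINKAGES:
            raise ValidationError(f"unknown linkage {self.linkage!r}")
        if self.missing_policy not in ("zero_impute", "pairwise_scale"):
            raise ValidationError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k, ordered by first appearance of samples) plus the
    merge history needed to re-cut the tree at any k."""

    labels: pd.Series  # sample_id -> cluster label
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge history
    k: int

    def cut(self, k: int) -> pd.Series:
        """Re-cut the stored dendrogram at k clusters."""
        raw = sch.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return _relabel_first_appearance(raw, self.labels.index)


def _relabel_first_appearance(raw: np.ndarray, index) -> pd.Series:
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return pd.Series(out, index=index, name="cluster")


def sample_distance(pct: ExpressionMatrix, cfg: ClusterConfig | None = None
                    ) -> pd.DataFrame:
    """Symmetric sample-by-sample distance matrix on the configured metric.

    missing_policy="zero_impute" treats unavailable cells as 0 (not
    expressed); "pairwise_scale" computes each pair's distance over the
    features available in both samples, rescaled to the full feature count.
    """
    cfg = cfg or ClusterConfig()
    X = pct.values.T.to_numpy(dtype=float)  # samples x genes
    if X.shape[0] < 2:
        raise ValidationError("sample_distance requires >= 2 samples")
    all_missing = ~np.isfinite(X).any(axis=1)
    if all_missing.any():
        bad = pct.values.columns[all_missing].tolist()
        raise ValidationError(f"samples with all values unavailable: {bad}")
    if cfg.missing_policy == "zero_impute":
        X = np.nan_to_num(X, nan=0.0)
        d = ssd.squareform(ssd.pdist(X, metric=cfg.distance))
    else:  # pairwise_scale
        n, p = X.shape
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = np.isfinite(X[i]) & np.isfinite(X[j])
                if not ok.any():
                    raise ValidationError(
                        f"no shared available feature between samples "
                        f"{pct.values.columns[i]!r} and {pct.values.columns[j]!r}")
                if cfg.distance == "euclidean":
                    dij = np.sqrt(np.sum((X[i, ok] - X[j, ok]) ** 2) * p / ok.sum())
                else:
                    dij = ssd.correlation(X[i, ok], X[j, ok])
                d[i, j] = d[j, i] = dij
    return pd.DataFrame(d, index=pct.values.columns, columns=pct.values.columns)


def hierarchical_clusters(d: pd.DataFrame, cfg: ClusterConfig | None = None
                          ) -> ClusterAssignment:
    """Agglomerative clustering of a distance matrix, cut to k clusters.

    Labels are 1..k in order of first appearance over the input sample order;
    ties in merge heights resolve deterministically (scipy's ordering).
    """
    cfg = cfg or ClusterConfig()
    n = d.shape[0]
    if cfg.k > n:
        raise ValidationError(f"k={cfg.k} exceeds number of samples {n}")
    condensed = ssd.squareform(d.to_numpy(), checks=False)
    Z = sch.linkage(condensed, method=cfg.linkage)
    raw = sch.fcluster(Z, t=cfg.k, criterion="maxclust")
    labels = _relabel_first_appearance(raw, d.index)
    n_found = labels.nunique()
    if n_found != cfg.k:
        raise ValidationError(
            f"requested {cfg.k} clusters but cut produced {n_found} "
            "(tied merge heights); choose a different k")
    sizes = labels.value_counts().sort_index()
    logger.info("clustering: %d clusters, sizes %s", cfg.k, sizes.tolist())
    return ClusterAssignment(labels=labels, linkage_matrix=Z, k=cfg.k)
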