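"""Clustering of DMR methylation trajectories across stages.

Each DMR is summarised by the level in the first stage (L0) and the changes
over the two following transitions (d1, d2), all in percentage points.
Agglomerative hierarchical clustering with Euclidean distance and complete
linkage, cut into k groups (k = 6 by default, the number of trajectory
archetypes the screen distinguishes), recovers the archetype structure.
Cluster numbers are canonicalised by sorting the cluster mean trajectories
lexicographically in descending order (high-start, stable, late-loss
trajectories first), so labels are reproducible across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

from .core import methylation_level
from .io import CytosineCallTable


def build_trajectories(
    dmrs: pd.DataFrame,
    stage_tables: dict[str, CytosineCallTable],
    stages: list[str] | None = None,
) -> pd.DataFrame:
    """Per-DMR trajectory matrix (L0, d1, d2, ...) in percentage points.

    ``stage_tables`` maps stage name to a pooled, filtered CG call table.
    L0 is the pooled level in the first stage; each following column is the
    change over one transition. Rows where any stage level is undefined
    (no covered site in the DMR) are dropped with a warning.
    """
    if stages is None:
        stages = list(stage_tables)
    levels = np.full((len(dmrs), len(stages)), np.nan)
    for j, stage in enumerate(stages):
        table = stage_tables[stage]
        for i, row in enumerate(dmrs.itertuples()):
            levels[i, j] = methylation_level(
                table, region=(row.chrom, row.start, row.end), context="CG"
            )
    levels *= 100.0
    cols = {"L0": levels[:, 0]}
    for j in range(1, len(stages)):
        cols[f"d{j}"] = levels[:, j] - levels[:, j - 1]
    mat = pd.DataFrame(cols, index=dmrs.index)
    ok = mat.notna().all(axis=1)
    if (~ok).any():
        import logging

        logging.getLogger(__name__).warning(
            "%d DMRs dropped from trajectory matrix (missing stage level)", (~ok).sum()
        )
    return mat[ok]


class TrajectoryClustering(BaseEstimator, ClusterMixin):
    """Complete-linkage hierarchical clustering of DMR trajectories.

    Parameters
    ----------
    n_clusters : int
        Number of groups to cut the dendrogram into (default 6).

    Attributes
    ----------
    labels_ : ndarray of canonical cluster labels (1..k)
    cluster_means_ : DataFrame of per-cluster mean trajectories, indexed by
        canonical label
    linkage_ : the scipy linkage matrix
    """

    def __init__(self, n_clusters: int = 6):
        self.n_clusters = n_clusters

    def fit(self, X, y=None) -> "TrajectoryClustering":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("trajectory matrix must be 2-D")
        if len(X) < self.n_clusters:
            raise ValueError(
                f"cannot cut {len(X)} trajectories into {self.n_clusters} clusters"
            )
        self.linkage_ = linkage(X, method="complete", metric="euclidean")
        raw = fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust")
        # canonical numbering: sort cluster mean trajectories lexicographically,
        # descending, so high-start/stable/late-loss archetypes come first
        means = {lab: X[raw == lab].mean(axis=0) for lab in np.unique(raw)}
        order = sorted(means, key=lambda lab: tuple(-v for v in means[lab]))
        relabel = {old: new for new, old in enumerate(order, start=1)}
        self.labels_ = np.array([relabel[lab] for lab in raw])
        self.cluster_means_ = pd.DataFrame(
            [means[old] for old in order],
            index=pd.Index(range(1, len(order) + 1), name="cluster"),
        )
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def cluster_trajectories(matrix: pd.DataFrame, k: int = 6) -> pd.Series:
    """Cluster a trajectory matrix into k canonical groups (labels 1..k)."""
    model = TrajectoryClustering(n_clusters=k).fit(matrix.to_numpy())
    return pd.Series(model.labels_, index=matrix.index, name="cluster")


def select_k_silhouette(
    matrix: pd.DataFrame | np.ndarray, k_range: range | list[int] = range(2, 11)
) -> tuple[int, dict[int, float]]:
    """Pick k maximising the mean silhouette width under the same
    distance/linkage; returns (best k, silhouette per k)."""
    X = np.asarray(matrix, dtype=float)
    scores: dict[int, float] = {}
    for k in k_range:
        if not 2 <= k <= len(X) - 1:
            continue
        labels = TrajectoryClustering(n_clusters=k).fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(X, labels, metric="euclidean"))
    if not scores:
        raise ValueError("no valid k in range")
    best = max(scores, key=scores.get)
    return best, scores
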