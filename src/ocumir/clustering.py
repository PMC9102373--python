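"""Supervised hierarchical clustering with uncentered correlation distance.

Reproduces the Cluster 3.0 behaviour the study's heatmaps rely on: samples
are clustered on a significant-miRNA subset using the uncentered correlation

    r(x, y) = sum(x_i * y_i) / sqrt(sum(x_i^2) * sum(y_i^2))

as similarity, distance d = 1 - r in [0, 2], and average linkage (UPGMA).
Missing values are handled pairwise-complete: each distance uses only the
positions present in both vectors; pairs with fewer than ``min_overlap``
shared positions (or a vector that is all-zero on the overlap, where the
correlation is undefined) fall back to distance 1 with a logged warning.

Merging is deterministic: at each step the cluster pair with the minimal mean
pairwise inter-cluster distance merges; ties break on the lexicographically
smallest (key_a, key_b) pair of cluster keys, a cluster's key being its
lexicographically smallest leaf id.  Leaf order places the child containing
the smaller key on the left, so trees are reproducible across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "uncentered_distance",
    "distance_matrix",
    "average_linkage",
    "supervised_cluster",
]

DEFAULT_MIN_OVERLAP = 3


@dataclass
class ClusteringResult:
    """A dendrogram over named items.

    ``merges`` lists the n-1 agglomerations bottom-up as (child_a, child_b,
    height); a child is a leaf item id or the label ``NODE{j}`` of the cluster
    created by the j-th (1-based) merge.  ``leaf_order`` is the left-to-right
    dendrogram order.
    """

    items: list[str]
    merges: list[tuple[str, str, float]]
    leaf_order: list[str]
    assay_subset: list[str] = field(default_factory=list)

    def root_split(self) -> tuple[list[str], list[str]]:
        """Leaf sets of the two children of the root (the two-cluster cut)."""
        if not self.merges:
            raise ValueError("no merges: need >= 2 items")
        members: dict[str, list[str]] = {it: [it] for it in self.items}
        for j, (a, b, _h) in enumerate(self.merges, start=1):
            members[f"NODE{j}"] = members[a] + members[b]
        a, b, _ = self.merges[-1]
        return members[a], members[b]


def uncentered_distance(x, y, min_overlap: int = DEFAULT_MIN_OVERLAP) -> float:
    """Uncentered-correlation distance 1 - r over pairwise-complete positions.

    Returns 1.0 (with a logged warning) when the overlap is smaller than
    ``min_overlap`` or either vector is all-zero on the overlap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    if int(ok.sum()) < min_overlap:
        logger.warning("overlap %d below min_overlap %d; distance set to 1",
                       int(ok.sum()), min_overlap)
        return 1.0
    xs, ys = x[ok], y[ok]
    nx = float(np.dot(xs, xs))
    ny = float(np.dot(ys, ys))
    if nx == 0.0 or ny == 0.0:
        logger.warning("all-zero vector on overlap; correlation undefined, "
                       "distance set to 1")
        return 1.0
    r = float(np.dot(xs, ys)) / np.sqrt(nx * ny)
    return float(np.clip(1.0 - r, 0.0, 2.0))


def distance_matrix(expr: pd.DataFrame,
                    min_overlap: int = DEFAULT_MIN_OVERLAP) -> pd.DataFrame:
    """Symmetric uncentered-correlation distances between the rows of ``expr``."""
    ids = list(expr.index)
    values = expr.to_numpy(dtype=float)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = uncentered_distance(values[i], values[j],
                                                    min_overlap)
    return pd.DataFrame(d, index=ids, columns=ids)


def _validate_distance(dist: pd.DataFrame) -> None:
    v = dist.to_numpy(dtype=float)
    if dist.shape[0] != dist.shape[1] or list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix must be square with matching ids")
    if not np.allclose(v, v.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(v), 0.0):
        raise ValueError("distance matrix must have zero diagonal")


def average_linkage(dist: pd.DataFrame) -> ClusteringResult:
    """UPGMA agglomeration of a distance matrix.

    At each step the pair of clusters with minimal mean pairwise inter-cluster
    distance merges; the merge height is that mean.  Ties break on the
    lexicographically smallest (key_a, key_b); within a merge the child with
    the smaller key goes left in the leaf order.
    """
    _validate_distance(dist)
    ids = [str(i) for i in dist.index]
    n = len(ids)
    if n < 2:
        raise ValueError("need >= 2 items to cluster")
    d = dist.to_numpy(dtype=float)

    # Active clusters: label -> (key, leaf row indices, leaf order).
    clusters: dict[str, tuple[str, list[int], list[str]]] = {
        item: (item, [i], [item]) for i, item in enumerate(ids)
    }
    merges: list[tuple[str, str, float]] = []
    for step in range(1, n):
        best: tuple[float, str, str] | None = None
        best_pair: tuple[str, str] | None = None
        labels = list(clusters)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                la, lb = labels[i], labels[j]
                ka, ra, _ = clusters[la]
                kb, rb, _ = clusters[lb]
                h = float(d[np.ix_(ra, rb)].mean())
                key = (h, *sorted((ka, kb)))
                if best is None or key < best:
                    best = key
                    best_pair = (la, lb) if ka <= kb else (lb, la)
        assert best is not None and best_pair is not None
        la, lb = best_pair  # la holds the smaller key: left child
        height = best[0]
        ka, ra, oa = clusters.pop(la)
        kb, rb, ob = clusters.pop(lb)
        merges.append((la, lb, height))
        clusters[f"NODE{step}"] = (min(ka, kb), ra + rb, oa + ob)

    (_, _, leaf_order), = clusters.values()
    return ClusteringResult(items=ids, merges=merges, leaf_order=leaf_order)


def supervised_cluster(
    expr: pd.DataFrame,
    annot: pd.DataFrame,
    assay_subset,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[ClusteringResult, pd.DataFrame]:
    """Cluster samples on a restricted (typically significant) assay subset.

    Returns the clustering plus a purity summary of the two-cluster cut at
    the root: per branch, its size, group composition, and the fraction of
    its majority group.
    """
    assay_subset = list(assay_subset)
    if not assay_subset:
        raise ValueError("assay_subset must be non-empty")
    missing = [a for a in assay_subset if a not in expr.columns]
    if missing:
        raise ValueError("assay_subset not in expression matrix: "
                         + ", ".join(map(str, missing)))
    sub = expr[assay_subset]
    result = average_linkage(distance_matrix(sub, min_overlap))
    result.assay_subset = assay_subset

    groups = annot.set_index("sample_id")["group"] if "sample_id" in annot.columns \
        else annot["group"]
    rows = []
    for branch, leaves in zip(("left", "right"), result.root_split()):
        counts = groups.loc[leaves].value_counts()
        rows.append(
            {
                "branch": branch,
                "n": len(leaves),
                "majority_group": counts.idxmax(),
                "purity": float(counts.max() / len(leaves)),
                "composition": "; ".join(f"{g}={c}" for g, c in counts.items()),
            }
        )
    return result, pd.DataFrame(rows)
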