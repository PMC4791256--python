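"""Clustering diagnostics for secretome samples.

Three views of sample structure are used before and after feature
selection: hierarchical clustering of z-scored counts under the Pearson
distance (the heat-map view), an unrooted neighbor-joining tree built
from Euclidean distances between samples, and silhouette coefficients
computed both directly from the data distances and from the tree's
leaf-to-leaf path lengths.  Improved silhouettes after selection are the
diagnostic that the retained proteins genuinely discriminate the classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples
from skbio import TreeNode

from .counts import SampleAnnotation, SpectralCountMatrix, zscore_rows

__all__ = [
    "DistanceMatrix",
    "pearson_distance",
    "euclidean_distance",
    "sample_distances",
    "hierarchical_cluster",
    "nj_tree",
    "silhouette_from_data",
    "silhouette_from_tree",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape must match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be >= 0")
        object.__setattr__(self, "values", (v + v.T) / 2.0)

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


def pearson_distance(X: np.ndarray, ids: tuple[str, ...] | None = None,
                     axis: Literal["rows", "columns"] = "rows") -> DistanceMatrix:
    """d = 1 - r over row vectors (or column vectors), so d in [0, 2].

    A constant vector has no defined correlation; its distance to every
    other vector is set to 1 (the uncorrelated value), and 0 to itself.
    """
    X = np.asarray(X, dtype=float)
    if axis == "columns":
        X = X.T
    n = X.shape[0]
    if ids is None:
        ids = tuple(f"v{i}" for i in range(n))
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    d = 1.0 - r
    const = sd == 0
    d[const, :] = 1.0
    d[:, const] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return DistanceMatrix(tuple(ids), d)


def euclidean_distance(X: np.ndarray,
                       ids: tuple[str, ...] | None = None) -> DistanceMatrix:
    """Plain Euclidean distances between row vectors."""
    X = np.asarray(X, dtype=float)
    if ids is None:
        ids = tuple(f"v{i}" for i in range(X.shape[0]))
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(ids), d)


def sample_distances(m: SpectralCountMatrix) -> DistanceMatrix:
    """Euclidean distances between runs on z-scored protein profiles.

    This is the distance fed to the NJ tree: proteins are z-scored across
    runs so high-abundance proteins do not dominate, then runs are
    compared in that standardized space.
    """
    z = zscore_rows(m)
    return euclidean_distance(z.T, ids=m.run_ids)


def hierarchical_cluster(d: DistanceMatrix,
                         linkage: Literal["average", "complete", "ward"] = "average",
                         ) -> tuple[np.ndarray, tuple[str, ...]]:
    """Agglomerative clustering of a distance matrix.

    Returns the scipy merge matrix and the dendrogram leaf order
    (deterministic; scipy breaks ties by cluster index, i.e. input order,
    so pre-sorting ids lexicographically fixes residual ties).
    """
    order0 = sorted(range(len(d)), key=lambda i: d.ids[i])
    ids = [d.ids[i] for i in order0]
    values = d.values[np.ix_(order0, order0)]
    condensed = squareform(values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    leaves = hierarchy.leaves_list(Z)
    return Z, tuple(ids[i] for i in leaves)


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree of the samples.

    The pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is joined at
    each step, with branch lengths from the standard NJ formulas; for an
    additive input the leaf-to-leaf path lengths of the result reproduce
    the input distances exactly.  A negative branch-length estimate is
    clamped to zero and its deficit moved to the sibling branch so path
    lengths through the new node are preserved.  Ties in Q are broken on
    the lexicographically smallest clade labels, making the topology
    independent of input taxon order.
    """
    n = len(d)
    if n < 2:
        raise ValueError("need >=2 samples")
    if n == 2:
        a, b = d.ids
        root = TreeNode(name=None)
        root.extend([TreeNode(name=a, length=0.0),
                     TreeNode(name=b, length=float(d.values[0, 1]))])
        return root

    nodes: dict[str, TreeNode] = {s: TreeNode(name=s) for s in d.ids}
    # active[key] -> representative label (min leaf name) used for tie-breaks
    dist: dict[tuple[str, str], float] = {}
    active = sorted(d.ids)
    pos = {s: i for i, s in enumerate(d.ids)}
    for i, a in enumerate(active):
        for b in active[i + 1:]:
            dist[_key(a, b)] = float(d.values[pos[a], pos[b]])

    counter = 0
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist[_key(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * dist[_key(a, b)] - r[a] - r[b]
                cand = (q, *(_key(a, b)))
                if best is None or cand < best:
                    best = cand
                    pair = (a, b)
        a, b = pair
        dab = dist[_key(a, b)]
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        new_label = min(a, b)
        counter += 1
        parent = TreeNode(name=None)
        ca, cb = nodes.pop(a), nodes.pop(b)
        ca.length, cb.length = la, lb
        parent.extend([ca, cb])
        nodes[new_label] = parent
        for c in active:
            if c in (a, b):
                continue
            duc = (dist[_key(a, c)] + dist[_key(b, c)] - dab) / 2.0
            dist[_key(new_label, c)] = duc
        active = sorted(set(active) - {a, b} | {new_label})

    a, b, c = active
    dab, dac, dbc = dist[_key(a, b)], dist[_key(a, c)], dist[_key(b, c)]
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    root = TreeNode(name=None)
    for label, ln in ((a, la), (b, lb), (c, lc)):
        child = nodes.pop(label)
        child.length = max(ln, 0.0)
        root.append(child)
    return root


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb += la
        la = 0.0
    if lb < 0:
        la = max(la + lb, 0.0)
        lb = 0.0
    return la, lb


def tree_distances(t: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances (sum of branch lengths)."""
    dm = t.tip_tip_distances()
    ids = tuple(str(i) for i in dm.ids)
    return DistanceMatrix(ids, np.asarray(dm.data, dtype=float))


def silhouette_from_data(d: DistanceMatrix, labels: dict[str, str] | np.ndarray,
                         ) -> tuple[pd.Series, float]:
    """Per-sample silhouettes s(i) = (b-a)/max(a,b) and their mean SC.

    a(i) is the mean distance to the sample's own class (excluding
    itself), b(i) the smallest mean distance to any other class.  A
    sample alone in its class scores 0 (Rousseeuw's convention).  SC near
    1 means tight, well-separated classes; near 0, overlapping classes;
    below 0, samples closer to another class than their own.
    """
    lab = _as_label_array(d.ids, labels)
    if len(set(lab)) < 2:
        raise ValueError("silhouette needs >=2 classes")
    s = silhouette_samples(d.values, lab, metric="precomputed")
    series = pd.Series(s, index=list(d.ids))
    return series, float(series.mean())


def silhouette_from_tree(t: TreeNode, labels: dict[str, str] | np.ndarray,
                         ) -> float:
    """Overall silhouette of the class labeling under tree path distances."""
    _, sc = silhouette_from_data(tree_distances(t), labels)
    return sc


def _as_label_array(ids: tuple[str, ...], labels) -> np.ndarray:
    if isinstance(labels, dict):
        return np.array([labels[i] for i in ids])
    if isinstance(labels, SampleAnnotation):
        return labels.labels_for(ids)
    arr = np.asarray(labels)
    if len(arr) != len(ids):
        raise ValueError("one label per sample required")
    return arr
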