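"""Hierarchical subcluster extraction and cross-condition alignment.

Cells (and, for the reference condition, regulons) are clustered by
average-linkage (UPGMA) agglomeration on correlation distance of their
standardized AUC profiles.  The merge order uses a fixed deterministic
tie-break — among equal-height candidate merges, the pair whose sorted
member-id tuples compare lexicographically smallest merges first — so the
dendrogram is exactly invariant to input row permutation.

Alignment embeds both conditions' cells jointly (shared regulons, column
standardization after concatenation, PCA then UMAP) and matches subclusters
across conditions by mutual nearest centroids in the 2-D embedding;
subclusters without a mutual match, or whose nearest counterpart is far
beyond the matched distances, are flagged unique.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .aucell import standardize_auc

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_distance",
    "correlation_distance_matrix",
    "Dendrogram",
    "hcluster",
    "cut_subclusters",
    "suggest_k",
    "reorder_by_reference",
    "embed_joint",
    "AlignmentResult",
    "align_by_centroids",
]


def correlation_distance(u, v, centered: bool = True) -> float:
    """1 - Pearson correlation (in [0, 2]); uncentered cosine similarity
    when ``centered=False``.  A constant vector has correlation defined as 0
    (distance 1) with a warning."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    if u.size < 2:
        raise ValueError("vectors must have length >= 2")
    if centered:
        u = u - u.mean()
        v = v - v.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        logger.warning("correlation with a constant vector defined as 0")
        return 1.0
    return float(1.0 - np.dot(u, v) / (nu * nv))


def correlation_distance_matrix(X: np.ndarray, centered: bool = True) -> np.ndarray:
    """Pairwise correlation distance between the rows of X."""
    X = np.asarray(X, dtype=float)
    if centered:
        X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    constant = norms == 0
    if constant.any():
        logger.warning("%d constant rows: correlation defined as 0", int(constant.sum()))
    safe = np.where(constant, 1.0, norms)
    C = (X / safe[:, None]) @ (X / safe[:, None]).T
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


@dataclass
class Dendrogram:
    """UPGMA merge tree.  Leaves are 0..n-1 in the order of ``ids``; internal
    node n+i is created by the i-th entry of ``merges``."""

    ids: list[str]
    merges: list[tuple[int, int, float]]  # (left node, right node, height)
    leaf_order: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_json_dict(self) -> dict:
        return {
            "ids": self.ids,
            "merges": [[l, r, h] for l, r, h in self.merges],
            "leaf_order": self.leaf_order,
        }


def hcluster(matrix: pd.DataFrame, axis: str = "rows", centered: bool = True) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration on correlation distance.

    Equal-height candidate merges are resolved by comparing the pair's
    sorted member-id tuples lexicographically; leaf order is a recursive
    traversal visiting the subtree with the smaller minimum member id first.
    """
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    ids = [str(i) for i in matrix.index]
    n = len(ids)
    if n < 2:
        raise ValueError("hcluster requires >= 2 items")
    D = correlation_distance_matrix(matrix.to_numpy())

    # active cluster -> sorted tuple of member leaf indices
    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): D[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_node = n
    eps = 1e-12

    def pair_key(a: int, b: int) -> tuple:
        ka = tuple(sorted(ids[i] for i in members[a]))
        kb = tuple(sorted(ids[i] for i in members[b]))
        return min(ka, kb), max(ka, kb)

    while len(members) > 1:
        best = min(dist.values())
        candidates = [p for p, d in dist.items() if d <= best + eps]
        a, b = min(candidates, key=lambda p: pair_key(*p))
        h = dist[(a, b)]
        na, nb = len(members[a]), len(members[b])
        merges.append((a, b, h))
        new = next_node
        next_node += 1
        members[new] = tuple(sorted(members.pop(a) + members.pop(b)))
        del dist[(a, b)]
        for other in list(members):
            if other == new:
                continue
            da = dist.pop((min(a, other), max(a, other)))
            db = dist.pop((min(b, other), max(b, other)))
            dist[(min(new, other), max(new, other))] = (na * da + nb * db) / (na + nb)

    # leaf order: recursive traversal, smaller-min-member-id subtree first
    children = {n + i: (l, r) for i, (l, r, _) in enumerate(merges)}
    min_id: dict[int, str] = {}

    def fill_min(node: int) -> str:
        if node < n:
            min_id[node] = ids[node]
        else:
            l, r = children[node]
            min_id[node] = min(fill_min(l), fill_min(r))
        return min_id[node]

    root = next_node - 1
    fill_min(root)
    order: list[str] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node < n:
            order.append(ids[node])
        else:
            l, r = children[node]
            first, second = (l, r) if min_id[l] <= min_id[r] else (r, l)
            stack.append(second)
            stack.append(first)
    return Dendrogram(ids=ids, merges=merges, leaf_order=order)


def cut_subclusters(dend: Dendrogram, k: int) -> pd.Series:
    """Cut the tree into k clusters by removing the k-1 highest merges.

    Labels are integers 1..k, numbered by the leaf-order position of each
    cluster's first member.
    """
    n = dend.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent: dict[int, int] = {}
    for i, (l, r, _) in enumerate(dend.merges[: n - k]):
        parent[l] = n + i
        parent[r] = n + i

    def find(x: int) -> int:
        while x in parent:
            x = parent[x]
        return x

    roots = {i: find(i) for i in range(n)}
    pos = {cid: p for p, cid in enumerate(dend.leaf_order)}
    first_pos: dict[int, int] = {}
    for i in range(n):
        r = roots[i]
        p = pos[dend.ids[i]]
        first_pos[r] = min(first_pos.get(r, n), p)
    ordered_roots = sorted(first_pos, key=first_pos.get)
    label_of = {r: li + 1 for li, r in enumerate(ordered_roots)}
    return pd.Series({dend.ids[i]: label_of[roots[i]] for i in range(n)}).reindex(dend.ids)


def suggest_k(matrix: pd.DataFrame, k_min: int = 2, k_max: int = 8) -> int:
    """Suggest a subcluster count by silhouette score over dendrogram cuts.

    Advisory only: the pipeline takes k per condition from its
    configuration, mirroring how subcluster counts are reported per group.
    """
    from sklearn.metrics import silhouette_score

    dend = hcluster(matrix, axis="rows")
    D = correlation_distance_matrix(matrix.to_numpy())
    best_k, best_s = k_min, -np.inf
    for k in range(k_min, min(k_max, len(matrix) - 1) + 1):
        labels = cut_subclusters(dend, k).reindex([str(i) for i in matrix.index])
        s = silhouette_score(D, labels.to_numpy(), metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def reorder_by_reference(matrix: pd.DataFrame, reference_order: list[str]) -> pd.DataFrame:
    """Permute columns to follow a reference regulon ordering.

    Columns absent from the reference are appended at the end in their
    original order with a warning; values are untouched.
    """
    present = [c for c in reference_order if c in matrix.columns]
    if not present:
        raise ValueError("reference order shares no columns with the matrix")
    extra = [c for c in matrix.columns if c not in set(present)]
    if extra:
        logger.warning("%d columns absent from the reference appended at the end", len(extra))
    return matrix[present + extra]


def embed_joint(
    auc_a: pd.DataFrame,
    auc_b: pd.DataFrame,
    n_pcs: int = 15,
    n_neighbors: int = 30,
    min_dist: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Joint 2-D embedding of both conditions' cells.

    Shared regulon columns are intersected by TF, the cell rows stacked,
    the combined matrix column-standardized, reduced by PCA to ``n_pcs``
    (deterministic sign: each component's largest-magnitude loading is
    positive) and embedded by UMAP with Euclidean metric and a fixed seed.
    Identical input rows receive identical coordinates.
    """
    shared = [c for c in auc_a.columns if c in set(auc_b.columns)]
    if not shared:
        raise ValueError("conditions share no regulon columns")
    combined = pd.concat([auc_a[shared], auc_b[shared]], axis=0)
    std = standardize_auc(combined)
    n_pcs_eff = min(n_pcs, len(shared), len(std) - 1)
    if n_pcs_eff < n_pcs:
        logger.warning("reducing n_pcs from %d to %d", n_pcs, n_pcs_eff)
    pca = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed)
    pca.fit(std.to_numpy())
    for c in range(pca.components_.shape[0]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[c] = -load
    # transform (a row-wise matrix product) keeps identical rows identical
    pcs = pca.transform(std.to_numpy())

    # embed unique PC rows only, so duplicated cells share coordinates exactly
    uniq, inverse = np.unique(pcs, axis=0, return_inverse=True)
    import umap  # deferred: importing umap is slow

    nn = min(n_neighbors, max(2, len(uniq) - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=nn,
            min_dist=min_dist,
            metric="euclidean",
            random_state=seed,
        )
        coords_uniq = reducer.fit_transform(uniq)
    coords = coords_uniq[inverse]
    return pd.DataFrame(coords, index=combined.index, columns=["umap_1", "umap_2"])


@dataclass
class AlignmentResult:
    """Cross-condition subcluster correspondence from centroid distances."""

    centroids_a: dict[str, tuple[float, float]]
    centroids_b: dict[str, tuple[float, float]]
    distance_matrix: pd.DataFrame  # A subclusters x B subclusters, Euclidean
    matches: list[tuple[str, str]]  # mutual nearest-centroid pairs
    unique_a: list[str]
    unique_b: list[str]

    def to_json_dict(self) -> dict:
        return {
            "centroids_a": {k: list(v) for k, v in self.centroids_a.items()},
            "centroids_b": {k: list(v) for k, v in self.centroids_b.items()},
            "distance_matrix": {
                "index": list(self.distance_matrix.index),
                "columns": list(self.distance_matrix.columns),
                "values": self.distance_matrix.to_numpy().tolist(),
            },
            "matches": [list(m) for m in self.matches],
            "unique_a": self.unique_a,
            "unique_b": self.unique_b,
        }


def align_by_centroids(
    embedding: pd.DataFrame,
    labels_a: pd.Series,
    labels_b: pd.Series,
    unique_margin: float = 1.5,
) -> AlignmentResult:
    """Match subclusters across conditions by mutual nearest centroids.

    Each subcluster's centroid is the mean 2-D coordinate of its member
    cells.  Matches are mutual nearest neighbors in the pairwise Euclidean
    centroid-distance matrix; a subcluster is unique iff it has no mutual
    match OR its nearest cross-condition distance exceeds ``unique_margin``
    times the largest distance among matched pairs.
    """
    if labels_a.empty or labels_b.empty:
        raise ValueError("each condition needs at least one labeled subcluster")

    def centroids(labels: pd.Series) -> dict[str, np.ndarray]:
        out = {}
        for lab in sorted(labels.unique(), key=str):
            cells = labels.index[labels == lab]
            out[str(lab)] = embedding.loc[cells].to_numpy().mean(axis=0)
        return out

    ca, cb = centroids(labels_a), centroids(labels_b)
    a_keys, b_keys = list(ca), list(cb)
    D = pd.DataFrame(
        [[float(np.linalg.norm(ca[i] - cb[j])) for j in b_keys] for i in a_keys],
        index=a_keys,
        columns=b_keys,
    )
    matches: list[tuple[str, str]] = []
    for i in a_keys:
        j = D.loc[i].idxmin()
        if D[j].idxmin() == i:
            matches.append((i, j))
    max_matched = max((D.loc[i, j] for i, j in matches), default=0.0)
    threshold = unique_margin * max_matched
    matched_a = {i for i, _ in matches}
    matched_b = {j for _, j in matches}
    unique_a = [i for i in a_keys if i not in matched_a or D.loc[i].min() > threshold]
    unique_b = [j for j in b_keys if j not in matched_b or D[j].min() > threshold]
    final_matches = [
        (i, j) for i, j in matches if i not in set(unique_a) and j not in set(unique_b)
    ]
    return AlignmentResult(
        centroids_a={k: (float(v[0]), float(v[1])) for k, v in ca.items()},
        centroids_b={k: (float(v[0]), float(v[1])) for k, v in cb.items()},
        distance_matrix=D,
        matches=final_matches,
        unique_a=unique_a,
        unique_b=unique_b,
    )
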