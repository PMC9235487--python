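"""Clustering of prediction splits and selection of cluster medoids.

Each prediction split is clustered separately so that representative
samples — the cluster medoids — can be explained one by one.  Partitioning
(k-medoids), agglomerative and density (OPTICS) algorithms accept a
precomputed distance matrix; BIRCH is registered for vector features only.
A sweep utility scores a parameter grid by silhouette or Davies-Bouldin
and returns the best clustering, and a consensus builder merges several
clusterings through their co-association matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import OPTICS, AgglomerativeClustering, Birch
from sklearn.manifold import TSNE, LocallyLinearEmbedding
from sklearn.metrics import davies_bouldin_score, silhouette_samples

from .distances import DistanceMatrix
from .samples import ContractViolation

logger = logging.getLogger(__name__)

NOISE = -1


@dataclass
class Clustering:
    """Cluster labels over one prediction split, with one medoid per cluster."""

    split: str | None
    labels: dict[str, int]
    medoids: dict[int, str]
    algorithm: str
    params: dict = field(default_factory=dict)
    criterion_scores: dict[str, float] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len({c for c in self.labels.values() if c != NOISE})

    def members(self, cluster: int) -> list[str]:
        return sorted(sid for sid, c in self.labels.items() if c == cluster)

    def to_frame(self) -> pd.DataFrame:
        medoid_ids = set(self.medoids.values())
        rows = [
            {"id": sid, "split": self.split, "cluster": c,
             "is_medoid": sid in medoid_ids}
            for sid, c in self.labels.items()
        ]
        return pd.DataFrame(rows, columns=["id", "split", "cluster", "is_medoid"])


def write_clusterings(clusterings: Sequence[Clustering], path: str | Path) -> None:
    pd.concat([c.to_frame() for c in clusterings], ignore_index=True).to_csv(
        path, sep="\t", index=False)


def read_clusterings(path: str | Path) -> dict[str, Clustering]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "split": str})
    out = {}
    for split, grp in df.groupby("split", sort=False):
        labels = dict(zip(grp["id"], grp["cluster"].astype(int)))
        medoids = {int(row["cluster"]): row["id"]
                   for _, row in grp[grp["is_medoid"]].iterrows()}
        out[split] = Clustering(split=split, labels=labels, medoids=medoids,
                                algorithm="loaded")
    return out


def _contiguous(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster indices to 0..k-1 in order of first appearance,
    keeping the noise label -1."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, c in enumerate(raw):
        if c == NOISE:
            out[i] = NOISE
            continue
        if c not in mapping:
            mapping[c] = len(mapping)
        out[i] = mapping[c]
    return out


def compute_medoids(labels: Mapping[str, int], d: DistanceMatrix) -> dict[int, str]:
    """Per cluster, the member minimising total distance to the other
    members; ties broken by lexicographically smallest id.  Noise points
    (label -1) receive no medoid."""
    missing = set(labels) - set(d.ids)
    if missing or set(d.ids) - set(labels):
        raise ContractViolation("labels and distance matrix cover different ids")
    pos = {sid: i for i, sid in enumerate(d.ids)}
    clusters: dict[int, list[str]] = {}
    for sid, c in labels.items():
        if c != NOISE:
            clusters.setdefault(c, []).append(sid)
    medoids = {}
    for c, members in clusters.items():
        if not members:
            raise ContractViolation(f"cluster {c} is empty")
        members = sorted(members)
        idx = np.array([pos[sid] for sid in members])
        sums = d.d[np.ix_(idx, idx)].sum(axis=0)
        medoids[c] = members[int(np.argmin(sums))]  # argmin → first minimum → smallest id
    return medoids


def _kmedoids_labels(d: np.ndarray, k: int, rng: np.random.Generator,
                     max_iter: int = 300) -> np.ndarray:
    n = d.shape[0]
    medoid_idx = np.sort(rng.choice(n, size=k, replace=False))
    for _ in range(max_iter):
        assign = np.argmin(d[:, medoid_idx], axis=1)
        new_idx = medoid_idx.copy()
        for c in range(k):
            members = np.where(assign == c)[0]
            if len(members) == 0:
                # re-seed an emptied cluster with the worst-served point
                worst = int(np.argmax(d[np.arange(n), medoid_idx[assign]]))
                new_idx[c] = worst
                continue
            sums = d[np.ix_(members, members)].sum(axis=0)
            new_idx[c] = members[int(np.argmin(sums))]
        if np.array_equal(new_idx, medoid_idx):
            break
        medoid_idx = new_idx
        assign = np.argmin(d[:, medoid_idx], axis=1)
    return assign


def run_clustering(d: DistanceMatrix | None, algorithm: str, *,
                   features: np.ndarray | None = None,
                   ids: Sequence[str] | None = None,
                   k: int | None = None, eps: float | None = None,
                   linkage_method: str = "average", min_samples: int = 2,
                   split: str | None = None, seed: int = 0) -> Clustering:
    """Cluster one split under a precomputed distance matrix (k-medoids,
    agglomerative, optics) or vector features (birch)."""
    if algorithm == "birch":
        if d is not None or features is None:
            raise ContractViolation(
                "birch requires vector features, not a precomputed distance matrix")
        if ids is None:
            raise ContractViolation("birch needs explicit sample ids")
        if k is None or not (0 < k <= len(ids)):
            raise ContractViolation(f"invalid number of clusters k={k}")
        raw = Birch(n_clusters=k).fit_predict(np.asarray(features, dtype=float))
        labels = dict(zip(ids, (int(c) for c in _contiguous(raw))))
        return Clustering(split=split, labels=labels, medoids={},
                          algorithm=algorithm, params={"k": k})

    if d is None:
        raise ContractViolation(f"algorithm {algorithm!r} requires a DistanceMatrix")
    n = d.n
    if algorithm in ("k-medoids", "agglomerative"):
        if k is None or not (0 < k <= n):
            raise ContractViolation(f"invalid number of clusters k={k} for n={n}")
    if algorithm == "k-medoids":
        raw = _kmedoids_labels(d.d, k, np.random.default_rng(seed))
        params = {"k": k, "seed": seed}
    elif algorithm == "agglomerative":
        if k == n:
            raw = np.arange(n)
        else:
            raw = AgglomerativeClustering(
                n_clusters=k, metric="precomputed", linkage=linkage_method
            ).fit_predict(d.d)
        params = {"k": k, "linkage": linkage_method}
    elif algorithm == "optics":
        if eps is None or eps <= 0:
            raise ContractViolation(f"optics requires a positive eps, got {eps}")
        raw = OPTICS(metric="precomputed", cluster_method="dbscan", eps=eps,
                     max_eps=np.inf, min_samples=min_samples).fit_predict(d.d)
        params = {"eps": eps, "min_samples": min_samples}
    else:
        raise ContractViolation(
            f"unknown algorithm {algorithm!r}; choose from "
            "k-medoids, agglomerative, optics, birch")
    raw = _contiguous(np.asarray(raw))
    labels = {sid: int(c) for sid, c in zip(d.ids, raw)}
    medoids = compute_medoids(labels, d) if any(c != NOISE for c in raw) else {}
    return Clustering(split=split, labels=labels, medoids=medoids,
                      algorithm=algorithm, params=params)


def evaluate_clustering(c: Clustering, d: DistanceMatrix | None = None,
                        features: np.ndarray | None = None,
                        criterion: str = "silhouette") -> float:
    """Score a clustering; silhouette accepts precomputed distances,
    Davies-Bouldin requires vector features.  Noise points are excluded."""
    if criterion == "silhouette":
        if d is None:
            raise ContractViolation("silhouette needs a DistanceMatrix")
        ids = [sid for sid in d.ids if c.labels[sid] != NOISE]
        labels = np.array([c.labels[sid] for sid in ids])
        if len(set(labels)) < 2:
            raise ContractViolation(
                "silhouette undefined for fewer than two clusters")
        sub = d.subset(ids)
        scores = silhouette_samples(sub.d, labels, metric="precomputed")
        # a sample alone in its cluster contributes 0 by convention
        sizes = pd.Series(labels).value_counts()
        singleton = np.isin(labels, sizes[sizes == 1].index.to_numpy())
        scores = np.where(singleton, 0.0, scores)
        return float(scores.mean())
    if criterion == "davies-bouldin":
        if features is None:
            raise ContractViolation("davies-bouldin requires vector features")
        order = sorted(c.labels)
        labels = np.array([c.labels[sid] for sid in order])
        keep = labels != NOISE
        if len(set(labels[keep])) < 2:
            raise ContractViolation(
                "davies-bouldin undefined for fewer than two clusters")
        return float(davies_bouldin_score(np.asarray(features)[keep], labels[keep]))
    raise ContractViolation(
        f"unknown criterion {criterion!r}; choose silhouette or davies-bouldin")


def sweep_clustering(d: DistanceMatrix, algorithm: str,
                     grid: Sequence[int | float], *, criterion: str = "silhouette",
                     features: np.ndarray | None = None, split: str | None = None,
                     linkage_method: str = "average", seed: int = 0) -> Clustering:
    """Run one algorithm over a hyperparameter grid (k or eps values) and
    return the best clustering by the criterion (silhouette maximised,
    Davies-Bouldin minimised)."""
    best: Clustering | None = None
    best_score = None
    for value in grid:
        kwargs = {"eps": float(value)} if algorithm == "optics" else {"k": int(value)}
        try:
            cand = run_clustering(d, algorithm, split=split, seed=seed,
                                  linkage_method=linkage_method, **kwargs)
            score = evaluate_clustering(cand, d=d, features=features,
                                        criterion=criterion)
        except ContractViolation as exc:
            logger.debug("sweep skips %s=%s: %s", algorithm, value, exc)
            continue
        cand.criterion_scores[criterion] = score
        better = (best_score is None
                  or (criterion == "silhouette" and score > best_score)
                  or (criterion == "davies-bouldin" and score < best_score))
        if better:
            best, best_score = cand, score
    if best is None:
        raise ContractViolation(
            f"no valid clustering found for {algorithm!r} over grid {list(grid)}")
    return best


def consensus_clustering(clusterings: Sequence[Clustering],
                         d: DistanceMatrix | None = None) -> Clustering:
    """Consensus of several clusterings over the same id set.

    The co-association matrix (fraction of inputs placing each pair in a
    common cluster) is turned into a dissimilarity (1 - co-association)
    and grouped agglomeratively with average linkage, cut at the median
    of the input cluster counts (rounded down).  Invariant to relabeling
    of the input cluster indices.
    """
    if len(clusterings) < 2:
        raise ContractViolation("consensus needs at least two clusterings")
    ids = sorted(clusterings[0].labels)
    for c in clusterings[1:]:
        if sorted(c.labels) != ids:
            raise ContractViolation("clusterings cover different id sets")
    n = len(ids)
    coassoc = np.zeros((n, n))
    for c in clusterings:
        lab = np.array([c.labels[sid] for sid in ids])
        same = (lab[:, None] == lab[None, :]) & (lab[:, None] != NOISE)
        coassoc += same
    coassoc /= len(clusterings)
    np.fill_diagonal(coassoc, 1.0)
    k = max(1, int(np.median([c.n_clusters for c in clusterings])))
    if k >= n:
        raw = np.arange(n)
    else:
        Z = linkage(squareform(1.0 - coassoc, checks=False), method="average")
        raw = fcluster(Z, t=k, criterion="maxclust") - 1
    labels = {sid: int(c) for sid, c in zip(ids, _contiguous(raw))}
    medoids = compute_medoids(labels, d) if d is not None else {}
    return Clustering(split=clusterings[0].split, labels=labels, medoids=medoids,
                      algorithm="consensus",
                      params={"k": k, "n_inputs": len(clusterings)})


def project_2d(d: DistanceMatrix | None = None, *, features: np.ndarray | None = None,
               ids: Sequence[str] | None = None, method: str = "tsne",
               seed: int = 0) -> dict[str, tuple[float, float]]:
    """2-D embedding for qualitative cluster inspection (no geometric
    guarantees).  t-SNE accepts precomputed distances; LLE needs features."""
    if method == "tsne":
        if d is not None:
            ids_, X, metric = list(d.ids), d.d, "precomputed"
        elif features is not None and ids is not None:
            ids_, X, metric = list(ids), np.asarray(features, float), "euclidean"
        else:
            raise ContractViolation("tsne needs a DistanceMatrix or features+ids")
        n = len(ids_)
        if n == 0:
            return {}
        if n == 1:
            return {ids_[0]: (0.0, 0.0)}
        if n <= 3:
            # classical-scaling fallback for degenerate sizes where a
            # perplexity cannot be chosen
            D2 = X ** 2 if metric == "precomputed" else (
                np.linalg.norm(X[:, None] - X[None, :], axis=-1) ** 2)
            J = np.eye(n) - np.ones((n, n)) / n
            B = -0.5 * J @ D2 @ J
            w, v = np.linalg.eigh(B)
            coords = v[:, ::-1][:, :2] * np.sqrt(np.maximum(w[::-1][:2], 0.0))
            return {sid: (float(x), float(y)) for sid, (x, y) in zip(ids_, coords)}
        emb = TSNE(n_components=2, metric=metric, init="random",
                   random_state=seed, perplexity=min(30.0, (n - 1) / 3)).fit_transform(X)
        return {sid: (float(x), float(y)) for sid, (x, y) in zip(ids_, emb)}
    if method == "lle":
        if features is None or ids is None:
            raise ContractViolation("lle requires vector features, not distances")
        X = np.asarray(features, float)
        n = len(X)
        if n == 1:
            return {list(ids)[0]: (0.0, 0.0)}
        emb = LocallyLinearEmbedding(
            n_components=2, n_neighbors=min(5, n - 1),
            random_state=seed).fit_transform(X)
        return {sid: (float(x), float(y)) for sid, (x, y) in zip(ids, emb)}
    raise ContractViolation(f"unknown projection method {method!r}; choose tsne or lle")
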