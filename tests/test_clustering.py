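"""Clustering, medoid selection, scoring, consensus and projection."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from anchorseq import (Clustering, ContractViolation, DistanceMatrix,
                       SequenceSample, compute_medoids, consensus_clustering,
                       evaluate_clustering, pairwise_distances, project_2d,
                       run_clustering, sweep_clustering)

from .oracles import best_two_partition_complete, exhaustive_medoid


def _dm(ids, d):
    return DistanceMatrix(tuple(ids), np.asarray(d, dtype=float))


def _two_group_samples():
    frames = ["AAAAAA", "AAAAAA", "AAAAAA", "GGGGGG", "GGGGGG", "GGGGGG"]
    return [SequenceSample(id=f"s{i}", frame=f) for i, f in enumerate(frames)]


@pytest.mark.parametrize("algorithm, kwargs", [
    ("k-medoids", {"k": 2}),
    ("agglomerative", {"k": 2}),
    ("optics", {"eps": 1.0}),
])
def test_identical_groups_are_separated(algorithm, kwargs):
    samples = _two_group_samples()
    d = pairwise_distances(samples)
    c = run_clustering(d, algorithm, seed=0, **kwargs)
    groups = {frozenset(c.members(cl)) for cl in set(c.labels.values())}
    assert groups == {frozenset({"s0", "s1", "s2"}), frozenset({"s3", "s4", "s5"})}
    for cl, medoid in c.medoids.items():
        assert c.labels[medoid] == cl


def test_k_equals_n_gives_singletons():
    samples = _two_group_samples()[:4]
    d = pairwise_distances(samples)
    c = run_clustering(d, "agglomerative", k=4)
    assert sorted(c.labels.values()) == [0, 1, 2, 3]
    assert sorted(c.medoids.values()) == [s.id for s in samples]


def test_invalid_k_rejected():
    d = _dm(["a", "b"], [[0, 1], [1, 0]])
    for bad_k in (0, 3):
        with pytest.raises(ContractViolation):
            run_clustering(d, "k-medoids", k=bad_k)


def test_birch_incompatible_with_precomputed():
    d = _dm(["a", "b"], [[0, 1], [1, 0]])
    with pytest.raises(ContractViolation, match="birch"):
        run_clustering(d, "birch", k=2)


def test_birch_on_features():
    X = np.array([[0.0], [0.1], [5.0], [5.1]])
    c = run_clustering(None, "birch", features=X, ids=["a", "b", "c", "d"], k=2)
    assert c.labels["a"] == c.labels["b"]
    assert c.labels["c"] == c.labels["d"]
    assert c.labels["a"] != c.labels["c"]


def test_agglomerative_matches_exhaustive_two_partition():
    """Complete-linkage cut at k=2 equals the global min-diameter bipartition
    on a clearly separated 6-sequence fixture."""
    frames = ["AAAA", "AAAT", "AATT", "GGGG", "GGGC", "GGCC"]
    samples = [SequenceSample(id=f"s{i}", frame=f) for i, f in enumerate(frames)]
    d = pairwise_distances(samples)
    dist = {(a.id, b.id): d.d[i, j]
            for i, a in enumerate(samples) for j, b in enumerate(samples)}
    expected = best_two_partition_complete([s.id for s in samples], dist)
    c = run_clustering(d, "agglomerative", k=2, linkage_method="complete")
    got = frozenset(frozenset(c.members(cl)) for cl in set(c.labels.values()))
    assert got == expected


def test_medoid_examples():
    d = _dm(["x", "y", "z"], [[0, 1, 1], [1, 0, 4], [1, 4, 0]])
    assert compute_medoids({"x": 0, "y": 0, "z": 0}, d) == {0: "x"}
    # singleton cluster is its own medoid
    assert compute_medoids({"x": 0, "y": 1, "z": 1}, d)[0] == "x"
    # all-equal distances: lexicographic tie-break
    d_eq = _dm(["c", "a", "b"], [[0, 2, 2], [2, 0, 2], [2, 2, 0]])
    assert compute_medoids({"c": 0, "a": 0, "b": 0}, d_eq) == {0: "a"}


def test_medoids_match_exhaustive_search(rng):
    """Random clusters of size <= 12: returned medoid minimises the total
    intra-cluster distance, checked by trying every member."""
    for _ in range(20):
        n = int(rng.integers(2, 13))
        ids = [f"m{i}" for i in range(n)]
        mat = rng.integers(0, 9, size=(n, n)).astype(float)
        mat = np.triu(mat, 1)
        mat = mat + mat.T
        d = _dm(ids, mat)
        medoids = compute_medoids({i: 0 for i in ids}, d)
        dist = {(a, b): mat[i, j] for i, a in enumerate(ids)
                for j, b in enumerate(ids)}
        assert medoids[0] == exhaustive_medoid(ids, dist)


def test_silhouette_perfect_and_zero():
    d = _dm(list("abcd"), [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]])
    c = Clustering(None, {"a": 0, "b": 0, "c": 1, "d": 1}, {}, "x")
    assert evaluate_clustering(c, d=d) == pytest.approx(1.0)
    # symmetric arrangement where every a(i) == b(i)
    d_sym = _dm(list("abcd"), (np.ones((4, 4)) - np.eye(4)) * 2)
    c_sym = Clustering(None, {"a": 0, "b": 1, "c": 0, "d": 1}, {}, "x")
    assert evaluate_clustering(c_sym, d=d_sym) == pytest.approx(0.0)


def test_silhouette_matches_per_sample_hand_computation(rng):
    """8-point fixture, k=2: mean of hand-computed (b - a)/max(a, b)."""
    n = 8
    mat = rng.integers(1, 9, size=(n, n)).astype(float)
    mat = np.triu(mat, 1)
    mat = mat + mat.T
    ids = [f"p{i}" for i in range(n)]
    labels = {ids[i]: (0 if i < 4 else 1) for i in range(n)}
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[ids[j]] == labels[ids[i]] and j != i]
        other = [j for j in range(n) if labels[ids[j]] != labels[ids[i]]]
        a = sum(mat[i, j] for j in own) / len(own)
        b = sum(mat[i, j] for j in other) / len(other)
        scores.append((b - a) / max(a, b))
    c = Clustering(None, labels, {}, "x")
    got = evaluate_clustering(c, d=_dm(ids, mat))
    assert got == pytest.approx(float(np.mean(scores)))


def test_single_cluster_score_undefined():
    d = _dm(["a", "b"], [[0, 1], [1, 0]])
    c = Clustering(None, {"a": 0, "b": 0}, {}, "x")
    with pytest.raises(ContractViolation):
        evaluate_clustering(c, d=d)


def test_davies_bouldin_requires_features():
    c = Clustering(None, {"a": 0, "b": 0, "c": 1, "d": 1}, {}, "x")
    with pytest.raises(ContractViolation):
        evaluate_clustering(c, d=_dm(list("abcd"), np.zeros((4, 4))),
                            criterion="davies-bouldin")
    X = np.array([[0.0], [0.1], [5.0], [5.1]])
    assert evaluate_clustering(c, features=X, criterion="davies-bouldin") >= 0


def test_sweep_picks_best_silhouette():
    samples = _two_group_samples()
    d = pairwise_distances(samples)
    best = sweep_clustering(d, "agglomerative", [2, 3], criterion="silhouette")
    assert best.params["k"] == 2
    assert best.criterion_scores["silhouette"] == pytest.approx(1.0)


def test_consensus_of_identical_and_permuted_inputs():
    labels = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 2, "f": 2}
    permuted = {sid: (c + 1) % 3 for sid, c in labels.items()}
    c1 = Clustering(None, labels, {}, "x")
    c2 = Clustering(None, permuted, {}, "x")
    cons = consensus_clustering([c1, c2])
    order = sorted(labels)
    ari = adjusted_rand_score([labels[i] for i in order],
                              [cons.labels[i] for i in order])
    assert ari == pytest.approx(1.0)


def test_consensus_matches_hand_computed_coassociation():
    """Three clusterings over 6 ids: consensus equals an explicit
    co-association matrix cut with scipy's average linkage."""
    ids = list("abcdef")
    partitions = [
        {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1},
        {"a": 0, "b": 0, "c": 1, "d": 1, "e": 1, "f": 1},
        {"a": 0, "b": 1, "c": 0, "d": 1, "e": 1, "f": 0},
    ]
    coassoc = np.zeros((6, 6))
    for part in partitions:
        for i, j in itertools.product(range(6), repeat=2):
            coassoc[i, j] += part[ids[i]] == part[ids[j]]
    coassoc /= 3
    k = int(np.median([2, 2, 2]))
    Z = linkage(squareform(1 - coassoc, checks=False), method="average")
    expected = fcluster(Z, t=k, criterion="maxclust")
    cons = consensus_clustering([Clustering(None, p, {}, "x") for p in partitions])
    got = [cons.labels[i] for i in ids]
    assert adjusted_rand_score(expected, got) == pytest.approx(1.0)


def test_consensus_requires_matching_ids():
    c1 = Clustering(None, {"a": 0, "b": 0}, {}, "x")
    c2 = Clustering(None, {"a": 0, "c": 0}, {}, "x")
    with pytest.raises(ContractViolation):
        consensus_clustering([c1, c2])


def test_projection_contracts():
    samples = _two_group_samples() + _two_group_samples()
    for i, s in enumerate(samples[6:], start=6):
        samples[i] = SequenceSample(id=f"s{i}", frame=s.frame)
    d = pairwise_distances(samples)
    p1 = project_2d(d, seed=3)
    p2 = project_2d(d, seed=3)
    assert p1 == p2  # fixed seed, identical coordinates
    one = project_2d(d.subset(["s0"]))
    assert one == {"s0": (0.0, 0.0)}
    with pytest.raises(ContractViolation):
        project_2d(d, method="lle")


def test_projection_separates_far_groups():
    frames = ["AAAAAAAA"] * 6 + ["GGGGGGGG"] * 6
    samples = [SequenceSample(id=f"s{i}", frame=f) for i, f in enumerate(frames)]
    d = pairwise_distances(samples)
    coords = project_2d(d, seed=0)
    a = np.array([coords[f"s{i}"] for i in range(6)])
    b = np.array([coords[f"s{i}"] for i in range(6, 12)])
    spread = max(np.linalg.norm(a - a.mean(0), axis=1).max(),
                 np.linalg.norm(b - b.mean(0), axis=1).max())
    between = np.linalg.norm(a.mean(0) - b.mean(0))
    assert spread < between
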