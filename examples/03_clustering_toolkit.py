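"""Compare clusterings of a repertoire and build a consensus.

Sweeps the cluster count for two algorithms on the binding split of a
small repertoire, scores each by silhouette, merges the winners into a
consensus partition, and embeds the split in 2-D with t-SNE.
"""

import numpy as np

from anchorseq import (consensus_clustering, evaluate_clustering,
                       generate_repertoire, pairwise_distances, project_2d,
                       run_clustering, sweep_clustering)
from anchorseq.synthetic import RepertoireConfig

samples, _, _ = generate_repertoire(
    RepertoireConfig(n_samples=120, n_seed_sequences=3, mutation_rate=0.05,
                     seed=1))
d = pairwise_distances(samples)

results = []
for algorithm in ("agglomerative", "k-medoids"):
    best = sweep_clustering(d, algorithm, grid=range(2, 7),
                            criterion="silhouette", seed=0)
    score = best.criterion_scores["silhouette"]
    results.append(best)
    print(f"{algorithm:14s} best k = {best.params['k']}  silhouette = {score:.3f}")

consensus = consensus_clustering(results, d=d)
score = evaluate_clustering(consensus, d=d)
print(f"{'consensus':14s} k = {consensus.n_clusters}  silhouette = {score:.3f}")
# The repertoire has 3 mutated clones, so sweeps should settle near k = 3
# and the consensus should keep that structure (silhouette close to the
# best single algorithm).

coords = project_2d(d, method="tsne", seed=0)
labels = np.array([consensus.labels[s.id] for s in samples])
xy = np.array([coords[s.id] for s in samples])
for c in sorted(set(labels)):
    centroid = xy[labels == c].mean(axis=0)
    print(f"t-SNE centroid of consensus cluster {c}: "
          f"({centroid[0]:8.2f}, {centroid[1]:8.2f}), "
          f"{int((labels == c).sum())} sequences")
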