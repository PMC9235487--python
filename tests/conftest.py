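import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from anchorseq import BINDING, NON_BINDING, Clustering, SequenceSample
from anchorseq.anchors import AnchorRule, Predicate


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_rule(predicates, prediction=BINDING, split=None, cluster=0, medoid="m"):
    """AnchorRule with dummy quality fields, for evaluation tests."""
    return AnchorRule(
        predicates=tuple(Predicate(p, s) for p, s in predicates),
        prediction=prediction,
        precision_estimate=1.0,
        precision_lower_bound=0.0,
        coverage=0.0,
        source=(split if split is not None else prediction, cluster, medoid),
    )


def random_fixture(rng, n_samples=None, n_rules=None, frame=8, alphabet="ABCD"):
    """A random small universe: samples, split labels, clusterings, rules.

    Used to compare the vectorised evaluation layer against the brute-force
    enumerator.
    """
    from anchorseq.models import split_by_prediction

    n_samples = n_samples or int(rng.integers(4, 51))
    n_rules = n_rules or int(rng.integers(1, 7))
    letters = np.array(list(alphabet))
    samples = [
        SequenceSample(id=f"s{i:03d}", frame="".join(rng.choice(letters, frame)))
        for i in range(n_samples)
    ]
    labels = [BINDING if rng.random() < 0.5 else NON_BINDING for _ in samples]
    split = split_by_prediction(samples, labels)
    clusterings = {}
    for split_name in (BINDING, NON_BINDING):
        ids = split.ids_of(split_name)
        k = int(rng.integers(1, 4))
        assign = {sid: int(rng.integers(0, k)) for sid in ids}
        present = sorted(set(assign.values()))
        relabel = {c: i for i, c in enumerate(present)}
        assign = {sid: relabel[c] for sid, c in assign.items()}
        medoids = {}
        for c in sorted(set(assign.values())):
            members = sorted(sid for sid, cc in assign.items() if cc == c)
            medoids[c] = members[0]
        clusterings[split_name] = Clustering(
            split=split_name, labels=assign, medoids=medoids, algorithm="random")
    rules = []
    for j in range(n_rules):
        split_name = BINDING if rng.random() < 0.5 else NON_BINDING
        clustering = clusterings[split_name]
        if not clustering.labels:
            split_name = BINDING if split_name == NON_BINDING else NON_BINDING
            clustering = clusterings[split_name]
            if not clustering.labels:
                continue
        cluster = int(rng.choice(sorted(set(clustering.labels.values()))))
        n_preds = int(rng.integers(0, 4))
        positions = rng.choice(frame, size=n_preds, replace=False)
        rules.append(make_rule(
            [(int(p), str(rng.choice(letters))) for p in positions],
            prediction=split_name, split=split_name, cluster=cluster,
            medoid=clustering.medoids[cluster]))
    return samples, split, clusterings, rules
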