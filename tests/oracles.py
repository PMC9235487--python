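"""Independent brute-force oracles used to verify the package's fast paths.

Everything here is written as plainly as possible — explicit loops over
every (sample, rule) pair, full dynamic programming, exhaustive
enumeration — and never calls the implementation it checks.
"""

from __future__ import annotations

import itertools

from anchorseq.models import BINDING, NON_BINDING


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook dynamic program over the full edit lattice."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[m]


def exhaustive_medoid(members: list[str], dist: dict[tuple[str, str], float]) -> str:
    """Try every member as medoid; ties to the lexicographically smallest."""
    best = None
    best_sum = None
    for cand in sorted(members):
        total = sum(dist[(cand, other)] for other in members if other != cand)
        if best_sum is None or total < best_sum:
            best, best_sum = cand, total
    return best


def best_two_partition_complete(ids: list[str],
                                dist: dict[tuple[str, str], float]) -> frozenset:
    """All 2-partitions, minimising the larger intra-cluster diameter."""
    n = len(ids)
    best = None
    best_obj = None
    # fix ids[0] in group a to enumerate each bipartition once
    for bits in range(2 ** (n - 1)):
        a = [ids[0]] + [ids[i] for i in range(1, n) if (bits >> (i - 1)) & 1]
        b = [i for i in ids if i not in a]
        if not b:
            continue
        def diameter(group):
            return max((dist[(x, y)] for x in group for y in group if x < y),
                       default=0.0)
        obj = max(diameter(a), diameter(b))
        if best_obj is None or obj < best_obj:
            best, best_obj = frozenset({frozenset(a), frozenset(b)}), obj
    return best


def sat(rule, sample) -> bool:
    return all(sample.frame[p.position] == p.symbol for p in rule.predicates)


def brute_force_counts(rules, samples, label_of, clusterings, level,
                       exclusive=True):
    """Per-scope (tp, fp, tn, fn) by looping over every (sample, rule) pair."""
    counts = {}
    if level == "CL":
        for i, rule in enumerate(rules):
            split_name, cluster, _ = rule.source
            tp = fp = tn = fn = 0
            for s in samples:
                in_cluster = clusterings[split_name].labels.get(s.id, None) == cluster
                fulfills = sat(rule, s)
                if exclusive:
                    fulfills = fulfills and not any(
                        sat(other, s) for j, other in enumerate(rules) if j != i)
                if in_cluster and fulfills:
                    tp += 1
                elif in_cluster:
                    fn += 1
                elif sat(rule, s):
                    fp += 1
                else:
                    tn += 1
            counts[i] = (tp, fp, tn, fn)
    elif level == "CS":
        for i, rule in enumerate(rules):
            split_name = rule.source[0]
            tp = fp = tn = fn = 0
            for s in samples:
                fulfills = sat(rule, s)
                same = label_of[s.id] == split_name
                if fulfills and same:
                    tp += 1
                elif fulfills:
                    fp += 1
                elif same:
                    fn += 1
                else:
                    tn += 1
            counts[i] = (tp, fp, tn, fn)
    elif level == "SP":
        for split_name in (NON_BINDING, BINDING):
            split_rules = [r for r in rules if r.source[0] == split_name]
            tp = fp = tn = fn = 0
            for s in samples:
                fulfills_any = any(sat(r, s) for r in split_rules)
                same = label_of[s.id] == split_name
                if fulfills_any and same:
                    tp += 1
                elif fulfills_any:
                    fp += 1
                elif same:
                    fn += 1
                else:
                    tn += 1
            counts[split_name] = (tp, fp, tn, fn)
    return counts


def brute_force_overlap(rules):
    k = len(rules)
    mat = [[0] * k for _ in range(k)]
    for i, j in itertools.product(range(k), repeat=2):
        shared = 0
        for p in rules[i].predicates:
            for q in rules[j].predicates:
                if p.position == q.position and p.symbol == q.symbol:
                    shared += 1
        mat[i][j] = shared
    return mat


def brute_force_cofulfillment(rules, samples):
    k = len(rules)
    mat = [[0] * k for _ in range(k)]
    for i, j in itertools.product(range(k), repeat=2):
        mat[i][j] = sum(1 for s in samples if sat(rules[i], s) and sat(rules[j], s))
    return mat


def brute_force_histogram(rules, samples):
    hist = {}
    for s in samples:
        n = sum(1 for r in rules if sat(r, s))
        hist[n] = hist.get(n, 0) + 1
    for k in range(max(hist, default=0) + 1):
        hist.setdefault(k, 0)
    return hist
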