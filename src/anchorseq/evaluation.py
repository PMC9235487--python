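"""Auditing a rule set for faithfulness, overlap and completeness.

A good global rule set should (i) replicate the model's predictions on
samples it applies to, (ii) not have rules from opposite splits apply to
the same sample, and (iii) cover the whole dataset.  These desiderata are
measured with accuracy/precision/recall confusion counts at three levels:

* **CL** (cluster level), per rule: a true positive is a sample of the
  rule's own cluster that fulfills *only* that rule (exclusive semantics;
  an inclusive variant is available behind ``exclusive=False``);
* **CS** (cluster-split level), per rule: a true positive is any sample
  fulfilling the rule whose model prediction matches the rule's split;
* **SP** (split level), per split: a true positive is a sample predicted
  as the split that fulfills at least one of the split's rules.

The evaluation universe at every level is the full test set (both splits),
so false positives can come from the opposite split.  Zero-denominator
ratios are reported as NaN with a logged warning, never silently as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anchors import AnchorRule, rule_applies
from .clustering import Clustering
from .models import BINDING, NON_BINDING, PredictionSplit
from .samples import ContractViolation, SequenceSample

logger = logging.getLogger(__name__)

LEVELS = ("CL", "CS", "SP")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    level: str
    scope: str

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn,
                           "accuracy")

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp, "precision")

    @property
    def recall(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn, "recall")

    def _ratio(self, num: int, den: int, name: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator) for %s at %s",
                           name, self.scope, self.level)
            return float("nan")
        return num / den


@dataclass
class MetricsReport:
    """Confusion counts and derived metrics for any subset of levels."""

    counts: list[ConfusionCounts]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"scope": c.scope, "level": c.level, "tp": c.tp, "fp": c.fp,
             "tn": c.tn, "fn": c.fn, "accuracy": c.accuracy,
             "precision": c.precision, "recall": c.recall}
            for c in self.counts
        ]
        return pd.DataFrame(rows, columns=["scope", "level", "tp", "fp", "tn", "fn",
                                           "accuracy", "precision", "recall"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class OverlapMatrix:
    """Rule-by-rule overlap, non-binding rules first then binding."""

    rule_ids: list[str]
    predicate_overlap: np.ndarray
    cofulfillment: np.ndarray

    def frame(self, which: str) -> pd.DataFrame:
        mat = self.predicate_overlap if which == "predicates" else self.cofulfillment
        return pd.DataFrame(mat, index=self.rule_ids, columns=self.rule_ids)


@dataclass
class CompletenessHistogram:
    """How many samples fulfill how many anchors (bin 0 included)."""

    counts: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_anchors": list(self.counts), "n_samples": list(self.counts.values())})


def _satisfaction_matrix(rules: Sequence[AnchorRule],
                         samples: Sequence[SequenceSample]) -> np.ndarray:
    """Boolean (n_samples, n_rules) rule-application matrix."""
    S = np.zeros((len(samples), len(rules)), dtype=bool)
    for j, rule in enumerate(rules):
        for i, s in enumerate(samples):
            S[i, j] = rule_applies(rule, s)
    return S


def order_rules(rules: Sequence[AnchorRule]) -> list[AnchorRule]:
    """Non-binding rules first, then binding, by cluster index within split."""
    def key(rule: AnchorRule):
        split, cluster, _ = rule.source
        return (0 if split == NON_BINDING else 1, cluster if cluster is not None else -1)
    return sorted(rules, key=key)


def level_metrics(rules: Sequence[AnchorRule], samples: Sequence[SequenceSample],
                  split: PredictionSplit,
                  clustering_by_split: Mapping[str, Clustering] | None,
                  level: str, *, exclusive: bool = True) -> MetricsReport:
    """Confusion counts and metrics for one level over the full universe."""
    if level not in LEVELS:
        raise ContractViolation(f"unknown level {level!r}; choose from {LEVELS}")
    n = len(samples)
    S = _satisfaction_matrix(rules, samples)
    predicted = np.array([split.label_of[s.id] for s in samples])
    counts: list[ConfusionCounts] = []

    if level == "CL":
        if clustering_by_split is None:
            raise ContractViolation("CL metrics need the clusterings per split")
        n_applied = S.sum(axis=1)
        for j, rule in enumerate(rules):
            rule_split, cluster, _ = rule.source
            if rule_split not in clustering_by_split:
                raise ContractViolation(
                    f"rule {rule.rule_id} references unknown split {rule_split!r}")
            clustering = clustering_by_split[rule_split]
            if cluster not in clustering.medoids and cluster not in set(
                    clustering.labels.values()):
                raise ContractViolation(
                    f"rule {rule.rule_id} references unknown cluster {cluster!r}")
            in_cluster = np.array(
                [clustering.labels.get(s.id, NOISE_SENTINEL) == cluster
                 for s in samples])
            fulfills = S[:, j] & (n_applied == 1) if exclusive else S[:, j]
            tp = int(np.sum(in_cluster & fulfills))
            fn = int(np.sum(in_cluster)) - tp
            fp = int(np.sum(~in_cluster & S[:, j]))
            counts.append(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=n - tp - fp - fn,
                                          level="CL", scope=rule.rule_id))
    elif level == "CS":
        for j, rule in enumerate(rules):
            rule_split = rule.source[0]
            same_split = predicted == rule_split
            tp = int(np.sum(S[:, j] & same_split))
            fp = int(np.sum(S[:, j] & ~same_split))
            fn = int(np.sum(~S[:, j] & same_split))
            counts.append(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=n - tp - fp - fn,
                                          level="CS", scope=rule.rule_id))
    else:  # SP
        for split_name in (NON_BINDING, BINDING):
            cols = [j for j, r in enumerate(rules) if r.source[0] == split_name]
            any_rule = S[:, cols].any(axis=1) if cols else np.zeros(n, dtype=bool)
            same_split = predicted == split_name
            tp = int(np.sum(any_rule & same_split))
            fp = int(np.sum(any_rule & ~same_split))
            fn = int(np.sum(~any_rule & same_split))
            counts.append(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=n - tp - fp - fn,
                                          level="SP", scope=split_name))
    return MetricsReport(counts=counts)


NOISE_SENTINEL = -2  # samples of the other split can never match a cluster index


def full_metrics(rules: Sequence[AnchorRule], samples: Sequence[SequenceSample],
                 split: PredictionSplit,
                 clustering_by_split: Mapping[str, Clustering],
                 *, exclusive: bool = True) -> MetricsReport:
    """All three levels in one report (rules in canonical order)."""
    rules = order_rules(rules)
    counts = []
    for level in LEVELS:
        counts.extend(level_metrics(rules, samples, split, clustering_by_split,
                                    level, exclusive=exclusive).counts)
    return MetricsReport(counts=counts)


def predicate_overlap(a: AnchorRule, b: AnchorRule) -> int:
    """Number of compatible sub-rules: predicates identical in both
    position and symbol."""
    return len(set(a.predicates) & set(b.predicates))


def cofulfillment_matrix(rules: Sequence[AnchorRule],
                         samples: Sequence[SequenceSample]) -> OverlapMatrix:
    """Symmetric matrices of shared predicates and co-fulfilled samples."""
    rules = order_rules(rules)
    k = len(rules)
    pred = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            pred[i, j] = predicate_overlap(rules[i], rules[j])
    S = _satisfaction_matrix(rules, samples).astype(int)
    cof = S.T @ S
    return OverlapMatrix(rule_ids=[r.rule_id for r in rules],
                         predicate_overlap=pred, cofulfillment=cof)


def completeness_histogram(rules: Sequence[AnchorRule],
                           samples: Sequence[SequenceSample]) -> CompletenessHistogram:
    """Histogram of the number of applicable anchors per sample."""
    S = _satisfaction_matrix(rules, samples)
    per_sample = S.sum(axis=1)
    top = int(per_sample.max()) if len(per_sample) else 0
    counts = {k: int(np.sum(per_sample == k)) for k in range(top + 1)}
    return CompletenessHistogram(counts=counts)
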