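"""Sequence distances for repertoire clustering.

The built-in metric is the Levenshtein edit distance, computed on the
biological residues only — reserved frame tokens (PAD/START/STOP) are
stripped first, so two identical receptors of different padded length are
at distance zero.  The actual edit-lattice computation is delegated to
edlib; additional metrics can be registered by name.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import edlib
import numpy as np
import pandas as pd

from .samples import AMINO_ACIDS, RESERVED, ContractViolation, SequenceSample


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distances over an ordered id list."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ContractViolation(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if n and (not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0)
                  or np.any(self.d < 0)):
            raise ContractViolation("distance matrix must be symmetric, non-negative, "
                                    "with zero diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, sid: str) -> int:
        return self.ids.index(sid)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {sid: i for i, sid in enumerate(self.ids)}
        idx = np.array([pos[sid] for sid in ids], dtype=int)
        return DistanceMatrix(tuple(ids), self.d[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def _strip_and_check(seq: str, alphabet: str) -> str:
    stripped = "".join(c for c in seq if c not in RESERVED)
    bad = set(stripped) - set(alphabet)
    if bad:
        raise ContractViolation(
            f"symbols {sorted(bad)} outside alphabet {alphabet!r}")
    return stripped


def levenshtein_distance(a: str, b: str, alphabet: str = AMINO_ACIDS) -> int:
    """Minimal number of insertions, deletions and substitutions turning
    ``a`` into ``b`` (reserved padding tokens stripped first)."""
    a = _strip_and_check(a, alphabet)
    b = _strip_and_check(b, alphabet)
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


MetricFn = Callable[[str, str], float]

_METRICS: dict[str, MetricFn] = {"levenshtein": levenshtein_distance}


def register_metric(name: str, fn: MetricFn) -> None:
    """Register a user metric ``fn(seq_a, seq_b) -> distance`` by name."""
    _METRICS[name] = fn


def pairwise_distances(samples: Sequence[SequenceSample],
                       metric: str = "levenshtein") -> DistanceMatrix:
    """Pairwise distance matrix over samples under a registered metric."""
    if metric not in _METRICS:
        raise ContractViolation(
            f"unknown metric {metric!r}; registered: {sorted(_METRICS)}")
    fn = _METRICS[metric]
    n = len(samples)
    d = np.zeros((n, n), dtype=float)
    frames = [s.frame for s in samples]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(frames[i], frames[j])
    return DistanceMatrix(tuple(s.id for s in samples), d)
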