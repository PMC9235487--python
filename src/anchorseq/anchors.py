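"""Anchor rules: high-precision if-then explanations of a black-box model.

An anchor for a cluster medoid is a conjunction of (position, amino-acid)
predicates, all drawn from the medoid's own frame, such that perturbed
sequences satisfying the conjunction receive the medoid's predicted class
with high probability (the rule's *precision*).  The search is bottom-up:
starting from the empty rule, a beam of candidate rules is extended one
predicate at a time, and at each round the best extension is identified by
a multi-armed bandit (KL-LUCB best-arm identification) whose pulls are
batches of perturbations scored by the model.  The search stops as soon as
a rule's lower confidence bound on precision clears the requested
threshold.

Perturbations are drawn by position-wise resampling: every position not
fixed by the candidate rule is, independently with probability 1/2,
replaced by a symbol drawn from the perturbation pool's empirical
distribution at that position, and otherwise kept.  This preserves the
positional composition of the repertoire while exploring the model's
behaviour around the medoid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .models import BlackBoxModel, predict_labels
from .samples import ContractViolation, SequenceSample, check_frame


@dataclass(frozen=True, order=True)
class Predicate:
    """One conjunct: the frame symbol at ``position`` must equal ``symbol``."""

    position: int
    symbol: str


@dataclass(frozen=True)
class AnchorRule:
    """An if-then rule with its estimated quality.

    ``precision_estimate`` is the fraction of perturbations satisfying the
    rule that were predicted as ``prediction``; ``precision_lower_bound``
    the matching KL lower confidence bound; ``coverage`` the fraction of
    the perturbation pool satisfying the rule.
    """

    predicates: tuple[Predicate, ...]
    prediction: str
    precision_estimate: float
    precision_lower_bound: float
    coverage: float
    source: tuple[str | None, int | None, str | None] = (None, None, None)
    n_samples_used: int = 0
    below_threshold: bool = False

    def __post_init__(self) -> None:
        positions = [p.position for p in self.predicates]
        if len(set(positions)) != len(positions):
            raise ContractViolation("anchor rule has two predicates on one position")
        if self.precision_lower_bound > self.precision_estimate + 1e-12:
            raise ContractViolation("precision lower bound exceeds estimate")

    @property
    def rule_id(self) -> str:
        split, cluster, _ = self.source
        return f"{split}/c{cluster}"

    def to_text(self) -> str:
        """Human-readable IF/AND/THEN rendering."""
        if not self.predicates:
            return f"IF (anything) THEN the sample is {self.prediction.upper()}"
        parts = [f"(amino acid {p.symbol} is in position {p.position})"
                 for p in sorted(self.predicates)]
        body = "IF " + "\n   AND ".join(parts)
        return f"{body}\nTHEN the sample is {self.prediction.upper()}"

    def to_json(self) -> str:
        split, cluster, medoid = self.source
        return json.dumps({
            "split": split, "cluster": cluster, "medoid": medoid,
            "predicates": [[p.position, p.symbol] for p in sorted(self.predicates)],
            "prediction": self.prediction,
            "precision_estimate": round(self.precision_estimate, 6),
            "precision_lower_bound": round(self.precision_lower_bound, 6),
            "coverage": round(self.coverage, 6),
            "n_samples_used": self.n_samples_used,
            "below_threshold": self.below_threshold,
        }, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "AnchorRule":
        d = json.loads(line)
        return cls(
            predicates=tuple(Predicate(int(p), s) for p, s in d["predicates"]),
            prediction=d["prediction"],
            precision_estimate=d["precision_estimate"],
            precision_lower_bound=d["precision_lower_bound"],
            coverage=d["coverage"],
            source=(d["split"], d["cluster"], d["medoid"]),
            n_samples_used=d["n_samples_used"],
            below_threshold=d["below_threshold"],
        )


def write_rules(rules: Sequence[AnchorRule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rule in rules:
            fh.write(rule.to_json() + "\n")


def read_rules(path: str | Path) -> list[AnchorRule]:
    with open(path) as fh:
        return [AnchorRule.from_json(line) for line in fh if line.strip()]


@dataclass(frozen=True)
class AnchorParams:
    """Hyperparameters of the anchor search.

    ``delta`` is the bandit's error probability, ``tau`` its best-arm
    tolerance, ``precision_threshold`` the lower-bound target at which a
    rule is accepted.  ``batch_size`` perturbations are drawn per bandit
    pull, and ``max_pulls`` caps the total pulls per anchor (on exhaustion
    the best rule so far is returned flagged below-threshold).
    """

    precision_threshold: float = 0.9
    delta: float = 0.3
    tau: float = 0.3
    beam_width: int = 1
    batch_size: int = 100
    max_predicates: int | None = None
    max_pulls: int = 2000
    #: after a rule clears the threshold, drop every predicate whose removal
    #: keeps the lower bound above it (anchors should be minimal: a shorter
    #: sufficient conjunction is more general and covers more samples)
    minimize_rule: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.precision_threshold <= 1):
            raise ContractViolation("precision_threshold must be in (0, 1]")
        if not (0 < self.delta < 1):
            raise ContractViolation("delta must be in (0, 1)")
        if not (0 < self.tau < 1):
            raise ContractViolation("tau must be in (0, 1)")


# ---------------------------------------------------------------------------
# rule application


def _predicates_of(rule: "AnchorRule | Iterable[Predicate]") -> tuple[Predicate, ...]:
    if isinstance(rule, AnchorRule):
        return rule.predicates
    return tuple(rule)


def rule_applies(rule: "AnchorRule | Iterable[Predicate]", s: SequenceSample) -> bool:
    """True iff every predicate's frame symbol matches the sample."""
    return all(s.frame[p.position] == p.symbol for p in _predicates_of(rule))


def rule_coverage(rule: "AnchorRule | Iterable[Predicate]",
                  samples: Sequence[SequenceSample]) -> float:
    """Fraction of samples the rule applies to."""
    if not samples:
        raise ContractViolation("coverage undefined on an empty sample list")
    return sum(rule_applies(rule, s) for s in samples) / len(samples)


# ---------------------------------------------------------------------------
# perturbation sampling


class PositionSampler:
    """Per-position empirical symbol distributions of a perturbation pool.

    Sampling replaces every unfixed position, independently with
    probability ``keep_prob`` complement, by a draw from the pool's
    distribution at that position; fixed positions always keep the
    instance's symbol.
    """

    def __init__(self, pool: Sequence[SequenceSample], keep_prob: float = 0.5):
        if not pool:
            raise ContractViolation("perturbation pool must be non-empty")
        self.frame_length = check_frame(pool)
        self.keep_prob = keep_prob
        symbols = sorted({c for s in pool for c in s.frame})
        self._symbols = np.array(symbols)
        code = {c: i for i, c in enumerate(symbols)}
        mat = np.array([[code[c] for c in s.frame] for s in pool], dtype=np.int64)
        counts = np.zeros((self.frame_length, len(symbols)))
        for j in range(self.frame_length):
            counts[j] = np.bincount(mat[:, j], minlength=len(symbols))
        self.frequencies = counts / counts.sum(axis=1, keepdims=True)
        self._cum = np.cumsum(self.frequencies, axis=1)

    def sample(self, instance: SequenceSample, fixed: Iterable[int], n: int,
               rng: np.random.Generator) -> list[SequenceSample]:
        if n <= 0:
            raise ContractViolation("number of perturbations must be positive")
        if instance.frame_length != self.frame_length:
            raise ContractViolation(
                f"instance frame {instance.frame_length} != pool frame {self.frame_length}")
        fixed = set(fixed)
        if not all(0 <= p < self.frame_length for p in fixed):
            raise ContractViolation("fixed position outside the frame")
        L = self.frame_length
        base = np.array(list(instance.frame))
        frames = np.tile(base, (n, 1))
        free = np.array([j for j in range(L) if j not in fixed], dtype=int)
        if free.size:
            resample = rng.random((n, free.size)) >= self.keep_prob
            # inverse-CDF draw from each free position's pool distribution
            u = rng.random((n, free.size))
            idx = np.empty((n, free.size), dtype=np.int64)
            for jj, j in enumerate(free):
                idx[:, jj] = np.searchsorted(self._cum[j], u[:, jj], side="right")
            idx = np.minimum(idx, len(self._symbols) - 1)
            drawn = self._symbols[idx]
            frames[:, free] = np.where(resample, drawn, frames[:, free])
        return [
            SequenceSample(id=f"{instance.id}~p{i}", frame="".join(row))
            for i, row in enumerate(frames)
        ]


def sample_perturbations(instance: SequenceSample, fixed: Iterable[int],
                         pool: Sequence[SequenceSample], n: int,
                         seed: int | np.random.Generator = 0) -> list[SequenceSample]:
    """Draw ``n`` perturbations of ``instance`` keeping ``fixed`` positions."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return PositionSampler(pool).sample(instance, fixed, n, rng)


# ---------------------------------------------------------------------------
# Bernoulli KL confidence bounds


def _kl_bernoulli(p: float, q: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    q = min(max(q, 1e-12), 1 - 1e-12)
    return p * math.log(p / q) + (1 - p) * math.log((1 - p) / (1 - q))


def kl_upper_bound(p_hat: float, n: int, beta: float) -> float:
    """Largest q ≥ p_hat with n·KL(p_hat, q) ≤ beta (bisection)."""
    if n == 0:
        return 1.0
    level = beta / n
    lo, hi = p_hat, 1.0
    for _ in range(40):
        mid = (lo + hi) / 2
        if _kl_bernoulli(p_hat, mid) > level:
            hi = mid
        else:
            lo = mid
    return lo


def kl_lower_bound(p_hat: float, n: int, beta: float) -> float:
    """Smallest q ≤ p_hat with n·KL(p_hat, q) ≤ beta (bisection)."""
    if n == 0:
        return 0.0
    level = beta / n
    lo, hi = 0.0, p_hat
    for _ in range(40):
        mid = (lo + hi) / 2
        if _kl_bernoulli(p_hat, mid) > level:
            lo = mid
        else:
            hi = mid
    return hi


# ---------------------------------------------------------------------------
# precision estimation


def estimate_precision(predicates: Iterable[Predicate], target: str,
                       model: BlackBoxModel, instance: SequenceSample,
                       pool: Sequence[SequenceSample], n: int,
                       delta: float = 0.3,
                       seed: int | np.random.Generator = 0) -> tuple[float, float, float]:
    """Monte-Carlo precision of a predicate set with two-sided (1 - delta)
    KL confidence bounds on the Bernoulli mean."""
    if n < 1:
        raise ContractViolation("precision estimation needs n >= 1")
    predicates = tuple(predicates)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perturbations = sample_perturbations(
        instance, (p.position for p in predicates), pool, n, rng)
    labels = predict_labels(model, perturbations)
    estimate = sum(lab == target for lab in labels) / n
    beta = math.log(2.0 / delta)
    return (estimate,
            kl_lower_bound(estimate, n, beta),
            kl_upper_bound(estimate, n, beta))


# ---------------------------------------------------------------------------
# anchor search


class _ArmStats:
    """Bernoulli pull statistics for one candidate rule."""

    __slots__ = ("positions", "successes", "pulls_n")

    def __init__(self, positions: tuple[int, ...]):
        self.positions = positions
        self.successes = 0
        self.pulls_n = 0

    @property
    def mean(self) -> float:
        return self.successes / self.pulls_n if self.pulls_n else 0.0

    def bounds(self, beta: float) -> tuple[float, float]:
        return (kl_lower_bound(self.mean, self.pulls_n, beta),
                kl_upper_bound(self.mean, self.pulls_n, beta))


class _Budget:
    def __init__(self, max_pulls: int):
        self.remaining = max_pulls
        self.samples_used = 0

    def take(self) -> bool:
        if self.remaining <= 0:
            return False
        self.remaining -= 1
        return True


def find_anchor(medoid: SequenceSample, model: BlackBoxModel,
                pool: Sequence[SequenceSample],
                params: AnchorParams = AnchorParams(), *,
                source: tuple[str | None, int | None] = (None, None)) -> AnchorRule:
    """Bottom-up beam search for a high-precision anchor on ``medoid``.

    Candidate predicates are the medoid's own (position, symbol) pairs —
    including positions holding reserved tokens, so a rule may require
    padding and thereby capture length information.  Ties between
    equal-mean candidate extensions are broken by higher pool coverage,
    then by lower position index.
    """
    sampler = PositionSampler(pool)
    if medoid.frame_length != sampler.frame_length:
        raise ContractViolation(
            f"medoid {medoid.id!r} frame length {medoid.frame_length} does not "
            f"match the pool frame {sampler.frame_length}")
    rng = np.random.default_rng(params.seed)
    target = predict_labels(model, [medoid])[0]
    threshold = params.precision_threshold
    beta_fixed = math.log(2.0 / params.delta)
    budget = _Budget(params.max_pulls)
    L = medoid.frame_length
    max_preds = params.max_predicates if params.max_predicates is not None else L

    # pool coverage of a position set (all predicates equal medoid symbols)
    pool_frames = np.array([list(s.frame) for s in pool])
    medoid_arr = np.array(list(medoid.frame))

    _coverage_cache: dict[tuple[int, ...], float] = {}

    def coverage_of(positions: tuple[int, ...]) -> float:
        if not positions:
            return 1.0
        if positions not in _coverage_cache:
            idx = np.array(positions)
            _coverage_cache[positions] = float(
                np.mean(np.all(pool_frames[:, idx] == medoid_arr[idx], axis=1)))
        return _coverage_cache[positions]

    def pull(stats: _ArmStats) -> None:
        perturbations = sampler.sample(medoid, stats.positions, params.batch_size, rng)
        labels = model.predict(perturbations)
        stats.successes += sum(lab == target for lab in labels)
        stats.pulls_n += params.batch_size
        budget.samples_used += params.batch_size

    def to_rule(stats: _ArmStats, below: bool) -> AnchorRule:
        lb, _ = stats.bounds(beta_fixed)
        return AnchorRule(
            predicates=tuple(Predicate(p, medoid.frame[p])
                             for p in sorted(stats.positions)),
            prediction=target,
            precision_estimate=stats.mean,
            precision_lower_bound=lb,
            coverage=coverage_of(stats.positions),
            source=(source[0], source[1], medoid.id),
            n_samples_used=budget.samples_used,
            below_threshold=below,
        )

    def refine_against_threshold(stats: _ArmStats) -> bool:
        """Pull until the threshold is decided; True iff lb >= threshold."""
        lb, ub = stats.bounds(beta_fixed)
        while lb < threshold <= ub and budget.take():
            pull(stats)
            lb, ub = stats.bounds(beta_fixed)
        return lb >= threshold

    all_stats: dict[tuple[int, ...], _ArmStats] = {}

    def stats_for(positions: tuple[int, ...]) -> _ArmStats:
        if positions not in all_stats:
            all_stats[positions] = _ArmStats(positions)
        return all_stats[positions]

    def minimize(stats: _ArmStats) -> _ArmStats:
        """Drop predicates whose removal keeps the rule above threshold."""
        current = stats
        changed = True
        while changed and current.positions:
            changed = False
            for pos in sorted(current.positions):
                reduced = stats_for(
                    tuple(p for p in current.positions if p != pos))
                if reduced.pulls_n == 0 and budget.take():
                    pull(reduced)
                if refine_against_threshold(reduced):
                    current = reduced
                    changed = True
                    break
        return current

    # the empty rule first: a constant-enough model needs no predicates
    empty = stats_for(())
    if budget.take():
        pull(empty)
    if refine_against_threshold(empty):
        return to_rule(empty, below=False)

    best_so_far = empty
    beam: list[tuple[int, ...]] = [()]

    for _ in range(max_preds):
        candidates: list[_ArmStats] = []
        seen: set[tuple[int, ...]] = set()
        for base in beam:
            for pos in range(L):
                if pos in base:
                    continue
                positions = tuple(sorted(base + (pos,)))
                if positions in seen:
                    continue
                seen.add(positions)
                candidates.append(stats_for(positions))
        if not candidates:
            break

        for arm in candidates:
            if arm.pulls_n == 0 and budget.take():
                pull(arm)

        def order_key(arm: _ArmStats) -> tuple:
            # highest mean; ties → higher coverage, then lowest new position
            return (-arm.mean, -coverage_of(arm.positions), arm.positions)

        # KL-LUCB: pull the empirical best and its strongest contender until
        # the contender's upper bound drops within tau of the best's lower bound
        t = 1
        n_arms = len(candidates)
        while budget.remaining > 0:
            candidates.sort(key=order_key)
            top = candidates[:params.beam_width]
            rest = candidates[params.beam_width:]
            if not rest:
                break
            beta_t = math.log(max(1.0, n_arms * (t ** 1.1)) / params.delta)
            lb_top = min(arm.bounds(beta_t)[0] for arm in top)
            contender = max(rest, key=lambda a: a.bounds(beta_t)[1])
            ub_cont = contender.bounds(beta_t)[1]
            if ub_cont - lb_top < params.tau:
                break
            weakest = min(top, key=lambda a: a.bounds(beta_t)[0])
            if budget.take():
                pull(weakest)
            if budget.take():
                pull(contender)
            t += 1

        candidates.sort(key=order_key)
        chosen = candidates[:params.beam_width]

        for arm in chosen:
            if refine_against_threshold(arm):
                if params.minimize_rule:
                    arm = minimize(arm)
                return to_rule(arm, below=False)
            if arm.bounds(beta_fixed)[0] > best_so_far.bounds(beta_fixed)[0]:
                best_so_far = arm

        # a candidate whose upper bound is below the threshold is not an
        # anchor itself (refine decided that), but its extensions can still
        # gain precision, so the beam keeps the chosen arms
        beam = [arm.positions for arm in chosen]
        if budget.remaining <= 0:
            break

    return to_rule(best_so_far, below=True)
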