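"""Synthetic TCR-beta-like repertoires with a planted-rule oracle model.

The generator emulates the cluster structure of an expanded repertoire at
desk scale: a handful of random seed sequences ("clones") are copied
round-robin and mutated position-wise, every position independently
replaced with probability ``mutation_rate`` by a uniformly random alphabet
symbol (possibly identical — so expectation formulas stay exact).  All
sequences share one fixed-length padded frame and one region-interval
template (FR1..FR4, CDR1..CDR3, PAD tail).

The black box to explain is a :class:`PlantedRuleModel`: binding iff any of
a list of planted conjunctive (position, symbol) rules is satisfied,
optionally XOR a per-sample Bernoulli label flip.  Because the ground-truth
rules are known, rule recovery by the anchor search becomes testable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .anchors import Predicate, rule_applies
from .models import BINDING, NON_BINDING
from .samples import AMINO_ACIDS, PAD, ContractViolation, Region, SequenceSample


def default_region_template(frame_length: int = 20) -> tuple[Region, ...]:
    """FR/CDR interval layout used by the desk-scale benchmark.

    Sixteen residue positions split into FR1..FR4 and CDR1..CDR3, followed
    by a PAD tail filling the frame.
    """
    if frame_length < 17:
        raise ContractViolation("default template needs a frame of at least 17")
    return (
        ("FR1", 0, 2), ("CDR1", 2, 5), ("FR2", 5, 7), ("CDR2", 7, 10),
        ("FR3", 10, 12), ("CDR3", 12, 15), ("FR4", 15, 16),
        ("PAD", 16, frame_length),
    )


@dataclass(frozen=True)
class RepertoireConfig:
    """Generator settings; defaults are the desk-scale benchmark."""

    n_samples: int = 1000
    frame_length: int = 20
    alphabet: str = AMINO_ACIDS
    n_seed_sequences: int = 4
    mutation_rate: float = 0.05
    region_template: tuple[Region, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ContractViolation("mutation_rate must be in [0, 1]")
        if self.n_seed_sequences > self.n_samples:
            raise ContractViolation("n_seed_sequences must not exceed n_samples")
        if len(set(self.alphabet)) < 2:
            raise ContractViolation("alphabet needs at least 2 symbols")

    @property
    def template(self) -> tuple[Region, ...]:
        return (self.region_template if self.region_template is not None
                else default_region_template(self.frame_length))

    @property
    def residue_positions(self) -> list[int]:
        return [p for label, start, end in self.template if label
                not in ("PAD", "Start", "Stop") for p in range(start, end)]


def generate_repertoire(config: RepertoireConfig
                        ) -> tuple[list[SequenceSample], dict[str, tuple[Region, ...]],
                                   list[str]]:
    """Generate a repertoire; returns (samples, region map, seed frames)."""
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(config.alphabet))
    residue_pos = np.array(config.residue_positions, dtype=int)
    seeds = []
    for _ in range(config.n_seed_sequences):
        frame = np.full(config.frame_length, PAD, dtype="<U1")
        frame[residue_pos] = rng.choice(alphabet, size=residue_pos.size)
        seeds.append("".join(frame))
    samples = []
    region_map = {}
    for i in range(config.n_samples):
        seed_frame = np.array(list(seeds[i % config.n_seed_sequences]))
        mutate = rng.random(residue_pos.size) < config.mutation_rate
        new_symbols = rng.choice(alphabet, size=residue_pos.size)
        seed_frame[residue_pos[mutate]] = new_symbols[mutate]
        sid = f"s{i:05d}"
        sample = SequenceSample(id=sid, frame="".join(seed_frame),
                                regions=config.template)
        samples.append(sample)
        region_map[sid] = config.template
    return samples, region_map, seeds


@dataclass(frozen=True)
class PlantedRuleModel:
    """Ground-truth black box: binding iff any planted conjunction holds.

    With ``label_noise`` > 0, each sample's label is flipped with that
    probability — deterministically per sample content (a salted hash), so
    repeated predictions of one batch always agree.
    """

    planted_rules: tuple[tuple[Predicate, ...], ...]
    label_noise: float = 0.0
    seed: int = 0
    metadata: str = "planted-rule oracle"

    def __post_init__(self) -> None:
        if not (0.0 <= self.label_noise < 0.5):
            raise ContractViolation("label_noise must be in [0, 0.5)")

    def _flip(self, frame: str) -> bool:
        digest = hashlib.blake2b(f"{self.seed}:{frame}".encode(),
                                 digest_size=8).digest()
        u = int.from_bytes(digest, "big") / 2 ** 64
        return u < self.label_noise

    def predict(self, samples: Sequence[SequenceSample]) -> list[str]:
        labels = []
        for s in samples:
            bound = any(rule_applies(rule, s) for rule in self.planted_rules)
            if self.label_noise > 0.0 and self._flip(s.frame):
                bound = not bound
            labels.append(BINDING if bound else NON_BINDING)
        return labels


def planted_predict(model: PlantedRuleModel,
                    samples: Sequence[SequenceSample]) -> list[str]:
    """Functional alias for :meth:`PlantedRuleModel.predict`."""
    return model.predict(samples)


@dataclass
class Benchmark:
    """A generated repertoire bundled with its planted-rule black box."""

    config: RepertoireConfig
    samples: list[SequenceSample]
    region_map: dict[str, tuple[Region, ...]]
    seeds: list[str]
    model: PlantedRuleModel
    planted_rules: tuple[tuple[Predicate, ...], ...]


#: CDR positions at which the benchmark plants its rules (one per CDR)
BENCHMARK_RULE_POSITIONS = (3, 8, 13)


def make_benchmark(seed: int = 0, *, config: RepertoireConfig | None = None,
                   label_noise: float = 0.0,
                   n_rules: int = 2,
                   rule_positions: tuple[int, ...] = BENCHMARK_RULE_POSITIONS
                   ) -> Benchmark:
    """Default benchmark: the standard repertoire plus ``n_rules`` planted
    binding rules, rule *i* matching seed sequence *i* at the given CDR
    positions (so each rule is carried by one clone of the repertoire)."""
    if config is None:
        config = RepertoireConfig(seed=seed)
    else:
        config = replace(config, seed=seed)
    if n_rules > config.n_seed_sequences:
        raise ContractViolation("cannot plant more rules than seed sequences")
    # The planted conjunctions must be pairwise distinct at every planted
    # position: if two carrier clones shared a symbol there, that predicate
    # would be fixed across the whole binding pool and unidentifiable by any
    # perturbation scheme.  Redraw the repertoire (deterministically) until
    # the carrier seeds differ at all rule positions.
    samples, region_map, seeds = generate_repertoire(config)
    for attempt in range(1, 1000):
        collision = any(
            seeds[i][p] == seeds[j][p]
            for p in rule_positions
            for i in range(n_rules) for j in range(i + 1, n_rules)
        )
        if not collision:
            break
        alt = int(np.random.SeedSequence([config.seed, attempt])
                  .generate_state(1)[0] % (2 ** 31))
        samples, region_map, seeds = generate_repertoire(replace(config, seed=alt))
    planted = tuple(
        tuple(Predicate(p, seeds[i][p]) for p in rule_positions)
        for i in range(n_rules)
    )
    model = PlantedRuleModel(planted_rules=planted, label_noise=label_noise,
                             seed=seed)
    return Benchmark(config=config, samples=samples, region_map=region_map,
                     seeds=seeds, model=model, planted_rules=planted)
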