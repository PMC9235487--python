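"""Region-resolved rule analysis and motif-style visualization.

Receptor variable domains decompose into framework regions (FR1-4, the
structural scaffold) and complementarity-determining regions (CDR1-3, the
binding contacts).  Mapping rule predicates onto these regions shows where
in the sequence a model's decision logic concentrates; densities are
length-normalised so short CDRs are comparable with long FRs.  Region
annotations are an *input* (per-sequence intervals in frame coordinates);
germline numbering and alignment are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .anchors import AnchorRule
from .samples import PAD, ContractViolation, Region, SequenceSample, check_frame

logger = logging.getLogger(__name__)

RegionMap = Mapping[str, tuple[Region, ...]]


@dataclass
class RegionDensity:
    """Per region: predicate count, summed region length, count / length."""

    split: str | None
    counts: dict[str, float]
    lengths: dict[str, int]

    @property
    def densities(self) -> dict[str, float]:
        return {label: (self.counts[label] / self.lengths[label]
                        if self.lengths[label] else float("nan"))
                for label in self.counts}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"split": self.split, "region": label, "count": self.counts[label],
             "length": self.lengths[label], "density": self.densities[label]}
            for label in sorted(self.counts)
        ]
        return pd.DataFrame(rows, columns=["split", "region", "count", "length",
                                           "density"])


def _region_at(intervals: tuple[Region, ...], position: int) -> str | None:
    for label, start, end in intervals:
        if start <= position < end:
            return label
    return None


def region_rule_distribution(rules: Sequence[AnchorRule], region_map: RegionMap,
                             split: str, *, mode: str = "predicate") -> RegionDensity:
    """Length-normalised distribution of a split's rule predicates over regions.

    Each predicate is assigned to the region containing its position in the
    rule's own medoid annotation; counts are divided by the summed length of
    that region across the split's medoids.  ``mode='rule'`` weights each
    predicate by 1/|predicates| so every rule contributes one unit in total.
    """
    if mode not in ("predicate", "rule"):
        raise ContractViolation(f"unknown counting mode {mode!r}")
    split_rules = [r for r in rules if r.source[0] == split]
    counts: dict[str, float] = {}
    lengths: dict[str, int] = {}
    for rule in split_rules:
        medoid_id = rule.source[2]
        if medoid_id not in region_map:
            raise ContractViolation(
                f"medoid {medoid_id!r} has no region annotation")
        intervals = region_map[medoid_id]
        for label, start, end in intervals:
            lengths[label] = lengths.get(label, 0) + (end - start)
        weight = 1.0 / len(rule.predicates) if (mode == "rule" and rule.predicates) else 1.0
        for pred in rule.predicates:
            label = _region_at(intervals, pred.position)
            if label is None:
                logger.warning(
                    "predicate position %d of rule %s not covered by any region "
                    "interval; assigned to 'Other'", pred.position, rule.rule_id)
                label = "Other"
                lengths.setdefault(label, 0)
            counts[label] = counts.get(label, 0.0) + weight
    for label in lengths:
        counts.setdefault(label, 0.0)
    return RegionDensity(split=split, counts=counts, lengths=lengths)


@dataclass
class FrequencyMatrix:
    """Column-stochastic position x symbol frequencies over non-PAD symbols.

    Positions where every contributing sample holds PAD are flagged empty
    (their column is all zero).
    """

    positions: np.ndarray
    symbols: list[str]
    freq: np.ndarray
    empty: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq, index=self.positions, columns=self.symbols)


def split_frequency_matrix(samples: Sequence[SequenceSample],
                           region: str | None = None) -> FrequencyMatrix:
    """Per-position symbol frequencies of a split (optionally one region).

    With ``region`` given, each sample contributes only at the frame
    positions its own annotation assigns to that region.
    """
    if not samples:
        raise ContractViolation("frequency matrix of an empty sample list")
    L = check_frame(samples)
    if region is not None:
        for s in samples:
            if s.regions is None:
                raise ContractViolation(
                    f"sample {s.id!r} lacks the region annotation needed "
                    f"to restrict to {region!r}")
    symbols = sorted({c for s in samples for c in s.frame if c != PAD})
    code = {c: i for i, c in enumerate(symbols)}
    counts = np.zeros((L, len(symbols)))
    for s in samples:
        if region is None:
            covered = range(L)
        else:
            covered = [p for label, start, end in s.regions if label == region
                       for p in range(start, end)]
        for p in covered:
            c = s.frame[p]
            if c != PAD:
                counts[p, code[c]] += 1
    totals = counts.sum(axis=1)
    empty = totals == 0
    freq = np.divide(counts, totals[:, None], out=np.zeros_like(counts),
                     where=totals[:, None] > 0)
    return FrequencyMatrix(positions=np.arange(L), symbols=symbols,
                           freq=freq, empty=empty)


# ---------------------------------------------------------------------------
# motif rendering

_LOGO_COLORS = {
    # polar / non-polar / acidic / basic amino-acid colouring
    "G": "#109648", "S": "#109648", "T": "#109648", "Y": "#109648", "C": "#109648",
    "Q": "#109648", "N": "#109648",
    "A": "#5e5e5e", "V": "#5e5e5e", "L": "#5e5e5e", "I": "#5e5e5e", "P": "#5e5e5e",
    "W": "#5e5e5e", "F": "#5e5e5e", "M": "#5e5e5e",
    "D": "#d62839", "E": "#d62839",
    "K": "#255c99", "R": "#255c99", "H": "#255c99",
}


def _draw_letter(ax, char: str, x: float, y: float, width: float, height: float) -> None:
    """Draw one glyph stretched to a (width, height) box at (x, y)."""
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    if height <= 0:
        return
    path = TextPath((0, 0), char, size=1.0,
                    prop=FontProperties(family="DejaVu Sans", weight="bold"))
    bbox = path.get_extents()
    if bbox.width == 0 or bbox.height == 0:
        return
    transform = (Affine2D()
                 .translate(-bbox.x0, -bbox.y0)
                 .scale(width / bbox.width, height / bbox.height)
                 .translate(x, y))
    ax.add_patch(PathPatch(transform.transform_path(path), lw=0,
                           facecolor=_LOGO_COLORS.get(char, "#a26f2a")))


def draw_logo(ax, freq: FrequencyMatrix, positions: Sequence[int] | None = None) -> None:
    """Frequency-height sequence logo on a matplotlib axes."""
    if positions is None:
        positions = list(freq.positions)
    for i, p in enumerate(positions):
        stack = sorted(
            ((freq.freq[p, j], sym) for j, sym in enumerate(freq.symbols)
             if freq.freq[p, j] > 0),
            key=lambda t: (t[0], t[1]))
        y = 0.0
        for f, sym in stack:
            _draw_letter(ax, sym, i + 0.05, y, 0.9, f)
            y += f
    ax.set_xlim(0, len(positions))
    ax.set_ylim(0, 1.02)
    ax.set_xticks([i + 0.5 for i in range(len(positions))])
    ax.set_xticklabels([str(p) for p in positions], fontsize=7)
    ax.set_ylabel("frequency")


def render_rule_motif(rule: AnchorRule, region_map: RegionMap, freq: FrequencyMatrix,
                      path: str | Path, region: str | None = None) -> None:
    """Two-row motif figure: rule predicates above the split's sequence logo.

    With ``region`` given, the view is restricted to that region of the
    rule's medoid annotation.  Deterministic for fixed input.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    positions = list(freq.positions)
    if region is not None:
        medoid_id = rule.source[2]
        intervals = region_map.get(medoid_id) if medoid_id is not None else None
        if intervals is None:
            raise ContractViolation(f"no region annotation for medoid {medoid_id!r}")
        positions = [p for label, start, end in intervals if label == region
                     for p in range(start, end)]
        if not positions:
            raise ContractViolation(f"region {region!r} absent from the annotation")
    by_position = {p.position: p.symbol for p in rule.predicates}

    fig, (ax_rule, ax_logo) = plt.subplots(
        2, 1, figsize=(max(3.0, 0.42 * len(positions)), 3.2), sharex=True,
        gridspec_kw={"height_ratios": [1, 2]})
    for i, p in enumerate(positions):
        if p in by_position:
            _draw_letter(ax_rule, by_position[p], i + 0.05, 0.0, 0.9, 1.0)
    ax_rule.set_xlim(0, len(positions))
    ax_rule.set_ylim(0, 1.05)
    ax_rule.set_yticks([])
    ax_rule.set_ylabel("rule")
    ax_rule.set_title(f"{rule.rule_id or 'rule'}: {rule.prediction}", fontsize=9)
    draw_logo(ax_logo, freq, positions)
    ax_logo.set_xlabel("frame position")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
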