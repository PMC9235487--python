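"""Sequence samples in a fixed-length padded frame.

Every sample handled by the pipeline lives in the same coordinate frame: a
string of exactly ``frame_length`` symbols, where trailing positions beyond
the biological sequence hold the PAD token.  Rule predicates, region
annotations and perturbations all address positions of this frame, which is
what makes rules from different clusters comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: canonical amino-acid alphabet (one-letter codes, alphabetical)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: reserved frame symbols
PAD = "-"
START = "^"
STOP = "$"
RESERVED = PAD + START + STOP

#: closed vocabulary of region labels
REGION_LABELS = frozenset(
    {"FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4",
     "Other", "PAD", "Start", "Stop"}
)

Region = tuple[str, int, int]


class ContractViolation(ValueError):
    """An input violated a documented contract of the pipeline."""


@dataclass(frozen=True)
class SequenceSample:
    """One amino-acid sequence in the fixed padded frame.

    Parameters
    ----------
    id:
        Unique identifier.
    frame:
        The padded representation: residues (plus optional START/STOP
        tokens) followed by PAD fill.  All samples of a run share one
        frame length.
    regions:
        Optional ordered ``(label, start, end)`` intervals, 0-based and
        half-open, non-overlapping, within the frame.
    """

    id: str
    frame: str
    regions: tuple[Region, ...] | None = None

    def __post_init__(self) -> None:
        if self.regions is not None:
            prev_end = None
            for label, start, end in sorted(self.regions, key=lambda r: r[1]):
                if label not in REGION_LABELS:
                    raise ContractViolation(
                        f"sample {self.id!r}: unknown region label {label!r}"
                    )
                if not (0 <= start <= end <= len(self.frame)):
                    raise ContractViolation(
                        f"sample {self.id!r}: region {label} [{start},{end}) "
                        f"outside frame of length {len(self.frame)}"
                    )
                if prev_end is not None and start < prev_end:
                    raise ContractViolation(
                        f"sample {self.id!r}: overlapping region intervals"
                    )
                prev_end = end

    @property
    def frame_length(self) -> int:
        return len(self.frame)

    @property
    def residues(self) -> str:
        """The sequence with reserved tokens removed."""
        return "".join(c for c in self.frame if c not in RESERVED)

    @property
    def raw_length(self) -> int:
        return len(self.residues)

    def region_at(self, position: int) -> str | None:
        """Label of the annotated region covering ``position`` (or None)."""
        if self.regions is None:
            return None
        for label, start, end in self.regions:
            if start <= position < end:
                return label
        return None


def pad_to_frame(sequence: str, frame_length: int, *, add_start_stop: bool = False) -> str:
    """Embed a raw sequence into the fixed frame, PAD-filling the tail."""
    body = f"{START}{sequence}{STOP}" if add_start_stop else sequence
    if len(body) > frame_length:
        raise ContractViolation(
            f"sequence of length {len(body)} does not fit frame {frame_length}"
        )
    return body + PAD * (frame_length - len(body))


def check_frame(samples: Sequence[SequenceSample], frame_length: int | None = None) -> int:
    """Assert all samples share one frame length; return it."""
    for s in samples:
        if frame_length is None:
            frame_length = s.frame_length
        elif s.frame_length != frame_length:
            raise ContractViolation(
                f"sample {s.id!r} has frame length {s.frame_length}, expected {frame_length}"
            )
    if frame_length is None:
        raise ContractViolation("cannot infer frame length from an empty sample list")
    return frame_length


# ---------------------------------------------------------------------------
# region-map helpers


def parse_region_string(text: str) -> tuple[Region, ...]:
    """Parse ``"FR1:0-2;CDR1:2-5"`` into region intervals."""
    regions = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        label, _, span = chunk.partition(":")
        start_s, _, end_s = span.partition("-")
        regions.append((label.strip(), int(start_s), int(end_s)))
    return tuple(regions)


def format_region_string(regions: Iterable[Region]) -> str:
    return ";".join(f"{label}:{start}-{end}" for label, start, end in regions)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path, frame_length: int, *, add_start_stop: bool = False) -> list[SequenceSample]:
    """Read sequences from FASTA; the first header token becomes the id."""
    from Bio import SeqIO

    samples = []
    for record in SeqIO.parse(str(path), "fasta"):
        samples.append(
            SequenceSample(id=record.id, frame=pad_to_frame(str(record.seq), frame_length,
                                                            add_start_stop=add_start_stop))
        )
    return samples


def read_sample_table(path: str | Path, frame_length: int | None = None, *,
                      add_start_stop: bool = False) -> list[SequenceSample]:
    """Read a delimited table with columns ``id``, ``sequence`` [, ``regions``].

    Sequences already at the frame length are taken as frames verbatim;
    shorter ones are PAD-filled to ``frame_length``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "sequence"} <= set(df.columns):
        raise ContractViolation("sample table needs 'id' and 'sequence' columns")
    if frame_length is None:
        frame_length = int(df["sequence"].str.len().max())
    samples = []
    for _, row in df.iterrows():
        seq = row["sequence"]
        frame = seq if len(seq) == frame_length else pad_to_frame(
            seq, frame_length, add_start_stop=add_start_stop)
        regions = None
        if "regions" in df.columns and isinstance(row.get("regions"), str):
            regions = parse_region_string(row["regions"])
        samples.append(SequenceSample(id=str(row["id"]), frame=frame, regions=regions))
    return samples


def write_sample_table(samples: Sequence[SequenceSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        row = {"id": s.id, "sequence": s.frame}
        if s.regions is not None:
            row["regions"] = format_region_string(s.regions)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_region_map(path: str | Path) -> dict[str, tuple[Region, ...]]:
    """Read a region map table (id, label, start, end; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "label": str})
    region_map: dict[str, list[Region]] = {}
    for _, row in df.iterrows():
        region_map.setdefault(row["id"], []).append(
            (row["label"], int(row["start"]), int(row["end"])))
    return {k: tuple(v) for k, v in region_map.items()}


def write_region_map(region_map: Mapping[str, tuple[Region, ...]], path: str | Path) -> None:
    rows = [
        {"id": sid, "label": label, "start": start, "end": end}
        for sid in sorted(region_map)
        for label, start, end in region_map[sid]
    ]
    pd.DataFrame(rows, columns=["id", "label", "start", "end"]).to_csv(
        path, sep="\t", index=False)


def write_fasta(samples: Sequence[SequenceSample], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(f">{s.id}\n{s.residues}\n")
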