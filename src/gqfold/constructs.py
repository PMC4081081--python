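"""DNA construct table, loop descriptors and G-quadruplex motif detection.

All constructs share an 18 nt duplex-forming stem followed by a structured
single-stranded overhang.  Coordinates are 0-based half-open, sequences are
stored uppercase, and only the sense strand is scanned (the overhangs are
single stranded).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

__all__ = [
    "Construct",
    "MotifHit",
    "LoopSpec",
    "STEM",
    "load_construct_table",
    "detect_gq_motif",
    "parse_loop_descriptor",
]

#: Duplex-forming stem common to every construct (5' portion of the oligo).
STEM = "TGGCGACGGCAGCGAGGC"

_VALID_BASES = frozenset("ACGT")

#: Loop-sequence names resolved via the packaged table.
_NAMED_LOOPS = {"TTT": "TTT", "TTA": "TTA", "TAA": "TAA", "AAA": "AAA"}


class MotifHit(NamedTuple):
    """One G-quadruplex motif occurrence: [start, end) plus loop lengths."""

    start: int
    end: int
    loop_lengths: tuple[int, int, int]


class LoopSpec(NamedTuple):
    lengths: tuple[int, int, int]
    sequences: tuple[str, str, str]


@dataclass(frozen=True)
class Construct:
    """A single oligonucleotide from the packaged construct table."""

    name: str
    sequence: str  # full 5'->3' sequence, uppercase, annotations stripped
    junction: int  # index where the ss overhang starts (stem excluded before)
    gq_forming: bool
    loop_lengths: tuple[int, int, int] | None = None
    loop_sequences: tuple[str, str, str] | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def overhang(self) -> str:
        return self.sequence[self.junction:]

    @property
    def total_loop_length(self) -> int:
        if self.loop_lengths is None:
            return 0
        return sum(self.loop_lengths)

    def __post_init__(self) -> None:
        if self.loop_lengths is not None and self.loop_sequences is not None:
            if tuple(len(s) for s in self.loop_sequences) != tuple(self.loop_lengths):
                raise ValueError(
                    f"{self.name}: loop_lengths {self.loop_lengths} disagree "
                    f"with loop_sequences {self.loop_sequences}"
                )


class ConstructTableError(RuntimeError):
    """Raised when the packaged construct fixture is missing or malformed."""


def _fixture_text() -> str:
    try:
        return (
            resources.files("gqfold.data").joinpath("constructs.tsv").read_text()
        )
    except (FileNotFoundError, ModuleNotFoundError) as exc:  # pragma: no cover
        raise ConstructTableError(
            "packaged fixture gqfold/data/constructs.tsv is missing"
        ) from exc


def _g_runs(sequence: str, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of G with length >= min_run, as (start, end) pairs."""
    return [
        (m.start(), m.end())
        for m in re.finditer("G+", sequence)
        if m.end() - m.start() >= min_run
    ]


def detect_gq_motif(
    sequence: str, min_run: int = 3, max_loop: int = 7
) -> list[MotifHit]:
    """Scan ``sequence`` for the four-G-run quadruplex motif.

    G-runs are maximal (greedy) with leftmost tie-breaking; hits are
    reported left-greedily and do not overlap.  Note that runs longer than
    ``min_run`` admit alternative registrations which are not enumerated.

    Parameters
    ----------
    sequence : str
        DNA over {A, C, G, T}; lowercase accepted.
    min_run : int
        Minimum G-run length (>= 2).
    max_loop : int
        Maximum loop length between consecutive runs (>= 1).
    """
    sequence = sequence.upper()
    bad = set(sequence) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if max_loop < 1:
        raise ValueError("max_loop must be >= 1")

    runs = _g_runs(sequence, min_run)
    hits: list[MotifHit] = []
    i = 0
    while i + 3 < len(runs):
        window = runs[i : i + 4]
        loops = tuple(
            window[j + 1][0] - window[j][1] for j in range(3)
        )
        if all(1 <= L <= max_loop for L in loops):
            hits.append(MotifHit(window[0][0], window[3][1], loops))
            i += 4  # left-greedy, non-overlapping
        else:
            i += 1
    return hits


def parse_loop_descriptor(name: str) -> LoopSpec:
    """Resolve a construct label like ``"233"`` or ``"TAA"`` to its loops.

    Three digits map to thymine loops of those lengths; three-letter names
    map to the repeated loop sequence from the packaged table.
    """
    if re.fullmatch(r"[1-9]{3}", name):
        lengths = tuple(int(c) for c in name)
        return LoopSpec(lengths, tuple("T" * n for n in lengths))
    if name in _NAMED_LOOPS:
        seq = _NAMED_LOOPS[name]
        return LoopSpec((len(seq),) * 3, (seq,) * 3)
    raise KeyError(f"unknown loop descriptor: {name!r}")


def _build_construct(name: str, sequence: str, notes: str) -> Construct:
    metadata: dict[str, str] = {}
    for token in filter(None, notes.split(";")):
        if "=" in token:
            key, _, val = token.partition("=")
            metadata[key] = val
        else:
            metadata[token] = ""
    junction = len(STEM) if sequence.startswith(STEM) else 0
    overhang = sequence[junction:]
    hits = detect_gq_motif(overhang, max_loop=9) if junction else []
    if hits:
        hit = hits[0]
        starts_ends = _g_runs(overhang, 3)
        # recover the literal loop strings between the four runs of the hit
        runs = [r for r in starts_ends if hit.start <= r[0] and r[1] <= hit.end][:4]
        loop_seqs = tuple(
            overhang[runs[j][1] : runs[j + 1][0]] for j in range(3)
        )
        return Construct(
            name=name,
            sequence=sequence,
            junction=junction,
            gq_forming=True,
            loop_lengths=hit.loop_lengths,
            loop_sequences=loop_seqs,
            metadata=metadata,
        )
    return Construct(
        name=name,
        sequence=sequence,
        junction=junction,
        gq_forming=False,
        metadata=metadata,
    )


def load_construct_table() -> dict[str, Construct]:
    """Load every oligonucleotide from the packaged fixture, keyed by name."""
    text = _fixture_text()
    lines = text.rstrip("\n").split("\n")
    header = lines[0].split("\t")
    if header != ["name", "sequence", "notes"]:
        raise ConstructTableError(
            f"constructs.tsv: unexpected header {header!r}"
        )
    table: dict[str, Construct] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ConstructTableError(
                f"constructs.tsv line {lineno}: expected 3 columns, got {len(fields)}"
            )
        name, sequence, notes = fields
        if set(sequence) - _VALID_BASES:
            raise ConstructTableError(
                f"constructs.tsv line {lineno}: invalid bases in {name}"
            )
        table[name] = _build_construct(name, sequence, notes)
    return table


def serialize_construct_table(table: dict[str, Construct]) -> str:
    """Inverse of :func:`load_construct_table` (byte-stable round trip)."""
    rows = ["name\tsequence\tnotes"]
    for c in table.values():
        notes = ";".join(
            k if v == "" else f"{k}={v}" for k, v in c.metadata.items()
        )
        rows.append(f"{c.name}\t{c.sequence}\t{notes}")
    return "\n".join(rows) + "\n"
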