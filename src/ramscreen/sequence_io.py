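"""Genome and enhancer-coordinate input, and centered window extraction.

Coordinates are 0-based half-open throughout.  Windows are expressed in a
center-relative frame: relative position ``r`` in ``[-half_width,
half_width)`` maps to absolute position ``start + half_width + r``, with
relative 0 at the enhancer center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")
# IUPAC ambiguity codes are legal FASTA but carry no usable information for
# exact matching; they are normalized to N.
_AMBIGUOUS = set("RYSWKMBDHV")
_NORMALIZE = str.maketrans({c: "N" for c in _AMBIGUOUS})


class ParseError(ValueError):
    """Malformed FASTA/BED input; the message names the offending line."""


@dataclass
class GenomeMap:
    """Named contigs with uppercase sequences over {A,C,G,T,N}."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __len__(self) -> int:
        return len(self.contigs)

    def items(self):
        return self.contigs.items()


@dataclass(frozen=True)
class EnhancerCenter:
    """A single enhancer summit/midpoint position (0-based)."""

    contig: str
    center: int

    def __post_init__(self) -> None:
        if self.center < 0:
            raise ValueError(f"negative center {self.center} on {self.contig}")


@dataclass(frozen=True)
class SequenceWindow:
    """A fixed-width window of sequence centered on an enhancer."""

    enhancer_id: str | int
    contig: str
    start: int  # absolute 0-based start of the window
    sequence: str
    half_width: int = 1000

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.half_width:
            raise ValueError(
                f"window sequence length {len(self.sequence)} != "
                f"2*half_width = {2 * self.half_width}"
            )

    @property
    def center(self) -> int:
        return self.start + self.half_width

    def to_absolute(self, rel: int) -> int:
        """Map a center-relative position to an absolute contig position."""
        if not -self.half_width <= rel < self.half_width:
            raise ValueError(f"relative position {rel} outside window")
        return self.start + self.half_width + rel


def read_genome(path: str | Path) -> GenomeMap:
    """Read a (multi-record) FASTA file into a GenomeMap.

    Headers are truncated at the first whitespace; sequences are uppercased,
    ambiguity codes become N, and any non-IUPAC character is a ParseError
    naming the line.
    """
    contigs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []

    def _flush(lineno: int) -> None:
        if name is None:
            return
        if not chunks:
            raise ParseError(f"line {lineno}: contig {name!r} has no sequence")
        contigs[name] = "".join(chunks)

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ParseError(f"line {lineno}: empty contig name")
                if name in contigs:
                    raise ParseError(f"line {lineno}: duplicate contig {name!r}")
                chunks = []
            else:
                if name is None:
                    raise ParseError(f"line {lineno}: sequence before any header")
                seq = line.upper().translate(_NORMALIZE)
                bad = set(seq) - _VALID_BASES
                if bad:
                    raise ParseError(
                        f"line {lineno}: non-IUPAC character(s) {sorted(bad)}"
                    )
                chunks.append(seq)
        _flush(lineno)
    if not contigs:
        raise ParseError("empty FASTA file")
    return GenomeMap(contigs)


def read_enhancer_centers(path: str | Path) -> list[EnhancerCenter]:
    """Read BED3+ intervals and reduce each to its midpoint.

    The center is floor((start + end) / 2); header lines beginning with
    '#', 'track' or 'browser' are skipped; record order is preserved.
    """
    centers: list[EnhancerCenter] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >=3 BED columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from None
            if end <= start:
                raise ParseError(f"line {lineno}: end {end} <= start {start}")
            if start < 0:
                raise ParseError(f"line {lineno}: negative start {start}")
            centers.append(EnhancerCenter(contig, (start + end) // 2))
    return centers


def extract_window(
    genome: GenomeMap, center: EnhancerCenter, half_width: int = 1000,
    enhancer_id: str | int | None = None,
) -> SequenceWindow | None:
    """Extract the forward-strand window [center-half_width, center+half_width).

    Returns None when the window would overrun either contig end (such
    windows are dropped rather than clipped, so downstream bin counts are
    uniform across windows).
    """
    if center.contig not in genome:
        raise KeyError(f"contig {center.contig!r} not in genome")
    contig_seq = genome[center.contig]
    start = center.center - half_width
    end = center.center + half_width
    if start < 0 or end > len(contig_seq):
        return None
    return SequenceWindow(
        enhancer_id=enhancer_id if enhancer_id is not None else center.center,
        contig=center.contig,
        start=start,
        sequence=contig_seq[start:end],
        half_width=half_width,
    )


def extract_windows(
    genome: GenomeMap, centers: Iterable[EnhancerCenter], half_width: int = 1000
) -> tuple[list[SequenceWindow], int]:
    """Extract all retainable windows; returns (windows, n_dropped)."""
    windows: list[SequenceWindow] = []
    n_dropped = 0
    for i, c in enumerate(centers):
        w = extract_window(genome, c, half_width, enhancer_id=i)
        if w is None:
            n_dropped += 1
        else:
            windows.append(w)
    if n_dropped:
        logger.info(
            "dropped %d window(s) overrunning contig ends (%d retained)",
            n_dropped, len(windows),
        )
    return windows, n_dropped
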