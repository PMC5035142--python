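"""IUPAC motif patterns, AP-1 10mer enumeration, and exact-match scanning.

Patterns are plain uppercase strings over the 15-letter IUPAC nucleotide
alphabet.  A pattern and its reverse complement describe the same
double-stranded motif; the *canonical form* (the lexicographically smaller of
the two under ASCII order) is used as the representative everywhere a set of
patterns is built.

Matching is exact: a window position matches a pattern iff every window base
is among the bases the pattern symbol allows.  An ``N`` in the *genome* is an
unknown base and matches nothing, not even a pattern ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import SequenceWindow

#: Ambiguity-code expansion: IUPAC symbol -> set of concrete bases.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Bitmask encoding: A=1, C=2, G=4, T=8.  A genome 'N' (or any unexpected
# byte) encodes to 0 and therefore never matches any pattern symbol.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_SYMBOL_MASK = {
    sym: np.uint8(sum(_BASE_BIT[b] for b in bases))
    for sym, bases in IUPAC_BASES.items()
}
_ENCODE_TABLE = np.zeros(256, dtype=np.uint8)
for _b, _bit in _BASE_BIT.items():
    _ENCODE_TABLE[ord(_b)] = _bit

#: AP-1 (FOS/JUN) binding-site consensus.
AP1_CONSENSUS = "TGANTCA"
#: NPAS4 response element.
NRE = "TCGTG"


def _validate_pattern(pattern: str) -> str:
    if not pattern:
        raise ValueError("motif pattern must be non-empty")
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC_BASES)
    if bad:
        raise ValueError(
            f"invalid IUPAC symbol(s) {sorted(bad)} in pattern {pattern!r}"
        )
    return pattern


def reverse_complement(pattern: str) -> str:
    """IUPAC-aware reverse complement (an involution)."""
    return _validate_pattern(pattern).translate(_COMPLEMENT)[::-1]


def canonical_form(pattern: str) -> str:
    """Representative of {pattern, reverse complement}: the ASCII-smaller one."""
    pattern = _validate_pattern(pattern)
    return min(pattern, reverse_complement(pattern))


def is_palindromic(pattern: str) -> bool:
    """True if the pattern equals its own reverse complement symbol-by-symbol."""
    pattern = _validate_pattern(pattern)
    return pattern == reverse_complement(pattern)


def pattern_matches(pattern: str, sequence: str) -> bool:
    """Exact IUPAC match of ``pattern`` against an equal-length concrete sequence."""
    pattern = _validate_pattern(pattern)
    if len(pattern) != len(sequence):
        return False
    return all(b in IUPAC_BASES[s] for s, b in zip(pattern, sequence.upper()))


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string to the uint8 bitmask alphabet used for scanning."""
    return _ENCODE_TABLE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def merge_motifs(a: str, b: str, overlap: int) -> str:
    """Fuse two motifs so the last ``overlap`` symbols of ``a`` coincide with the
    first ``overlap`` symbols of ``b``.

    Overlapped positions carry the intersection of the two symbols' allowed
    bases; an empty intersection raises ``ValueError`` naming the first
    conflicting position (0-based within the overlap).

    >>> merge_motifs("TCGTG", "TGANTCA", 2)
    'TCGTGANTCA'
    """
    a, b = _validate_pattern(a), _validate_pattern(b)
    if not 0 < overlap <= min(len(a), len(b)):
        raise ValueError(f"overlap must be in (0, {min(len(a), len(b))}]")
    merged_overlap = []
    for i, (sa, sb) in enumerate(zip(a[len(a) - overlap:], b[:overlap])):
        allowed = IUPAC_BASES[sa] & IUPAC_BASES[sb]
        if not allowed:
            raise ValueError(
                f"incompatible overlap at position {i}: {sa} vs {sb}"
            )
        merged_overlap.append(_bases_to_symbol(allowed))
    return a[: len(a) - overlap] + "".join(merged_overlap) + b[overlap:]


_BASES_TO_SYMBOL = {bases: sym for sym, bases in IUPAC_BASES.items()}


def _bases_to_symbol(bases: frozenset[str]) -> str:
    return _BASES_TO_SYMBOL[frozenset(bases)]


@dataclass(frozen=True)
class KmerSet:
    """A reverse-complement-collapsed collection of length-``k`` patterns."""

    k: int
    patterns: tuple[str, ...]
    mode: str = "wildcard-N"

    def __post_init__(self) -> None:
        for p in self.patterns:
            if len(p) != self.k:
                raise ValueError(f"pattern {p!r} does not have length {self.k}")
            if canonical_form(p) != p:
                raise ValueError(f"pattern {p!r} is not in canonical form")

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self):
        return iter(self.patterns)

    def __contains__(self, pattern: str) -> bool:
        return canonical_form(pattern) in set(self.patterns)

    def matching_patterns(self, sequence: str) -> list[str]:
        """Members matched by a concrete k-mer on either strand."""
        rc = reverse_complement(sequence)
        return [
            p for p in self.patterns
            if pattern_matches(p, sequence) or pattern_matches(p, rc)
        ]

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self.patterns:
                fh.write(f"{p}\t{self.mode}\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "KmerSet":
        patterns, modes = [], set()
        with open(path) as fh:
            for line in fh:
                pattern, mode = line.split()
                patterns.append(canonical_form(pattern))
                modes.add(mode)
        if len(modes) != 1:
            raise ValueError(f"expected a single mode column value, got {modes}")
        return cls(k=len(patterns[0]), patterns=tuple(sorted(set(patterns))),
                   mode=modes.pop())


def enumerate_ap1_kmers(
    consensus: str = AP1_CONSENSUS, k: int = 10, mode: str = "wildcard-N"
) -> KmerSet:
    """Enumerate all k-mer patterns containing the AP-1 consensus.

    The consensus heptamer is slid across every offset of the k-mer and the
    remaining positions take each concrete base, giving (k-6)*4**(k-7)
    raw patterns that are then deduplicated after reverse-complement
    collapsing.

    ``wildcard-N`` (default) keeps the consensus ``N`` as a wildcard; because
    TGANTCA is its own reverse complement, offset pairs collapse two-to-one
    and the default (k=10) set has exactly 128 members.  ``fixed-core``
    resolves the ``N`` to C (TGACTCA, the resolution in every characterized
    core used for promoter construction); the resolved core is no longer
    self-reverse-complementary, so no two enumerated patterns collapse and
    the k=10 set has 256 members.
    """
    consensus = _validate_pattern(consensus)
    if k < len(consensus):
        raise ValueError(f"k={k} shorter than consensus ({len(consensus)} nt)")
    if mode == "wildcard-N":
        core = consensus
    elif mode == "fixed-core":
        core = consensus.replace("N", "C")
    else:
        raise ValueError(f"unknown enumeration mode {mode!r}")

    n_free = k - len(core)
    out: set[str] = set()
    for offset in range(n_free + 1):
        for fill in product("ACGT", repeat=n_free):
            flat = list(fill)
            pattern = (
                "".join(flat[:offset]) + core + "".join(flat[offset:])
            )
            out.add(canonical_form(pattern))
    return KmerSet(k=k, patterns=tuple(sorted(out)), mode=mode)


@dataclass(frozen=True)
class MatchHit:
    """A perfect match of a pattern inside a window.

    ``rel_start`` is the start of the matched k bases on the forward strand,
    in the window's center-relative frame, for both strands.
    """

    window_id: str | int
    rel_start: int
    strand: str  # '+' or '-'


def scan_encoded(enc: np.ndarray, pattern: str) -> np.ndarray:
    """Start indices (along the last axis) where ``pattern`` matches exactly.

    ``enc`` is a 1-D encoded sequence or a 2-D (windows x length) matrix; for
    2-D input returns an (n_hits, 2) array of (row, start) pairs.
    """
    pattern = _validate_pattern(pattern)
    k = len(pattern)
    n = enc.shape[-1]
    if k > n:
        return (np.empty((0, 2), dtype=np.intp) if enc.ndim == 2
                else np.empty(0, dtype=np.intp))
    ok = (enc[..., : n - k + 1] & _SYMBOL_MASK[pattern[0]]) > 0
    for j in range(1, k):
        ok &= (enc[..., j : n - k + 1 + j] & _SYMBOL_MASK[pattern[j]]) > 0
    if enc.ndim == 2:
        rows, cols = np.nonzero(ok)
        return np.column_stack([rows, cols])
    return np.nonzero(ok)[0]


def find_matches(
    pattern: str, window: SequenceWindow, both_strands: bool = True
) -> list[MatchHit]:
    """All perfect matches of ``pattern`` in a window, on both strands.

    Reverse-strand hits are found by scanning the reverse complement of the
    pattern along the forward strand, so every hit is reported at the
    forward-strand start of the matched bases.  A self-reverse-complementary
    pattern yields a single '+' hit per position, not two.
    """
    pattern = _validate_pattern(pattern)
    enc = encode_sequence(window.sequence)
    hw = window.half_width
    hits = [
        MatchHit(window.enhancer_id, int(i) - hw, "+")
        for i in scan_encoded(enc, pattern)
    ]
    if both_strands and not is_palindromic(pattern):
        hits += [
            MatchHit(window.enhancer_id, int(i) - hw, "-")
            for i in scan_encoded(enc, reverse_complement(pattern))
        ]
    return sorted(hits, key=lambda h: (h.rel_start, h.strand))
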