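"""Enhancer-module anatomy and synthetic-promoter assembly.

An enhancer module is a 24 bp unit: a 10 nt core motif embedded in the CME
(central midline element) backbone, 12 nt to the left and 2 nt to the right.
A synthetic promoter is a tandem array of identical modules, an optional
linker, and a minimal promoter; the canonical design — four RAM modules on
the 99 bp human FOS minimal promoter — totals 199 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .motifs import (
    _validate_pattern,
    encode_sequence,
    is_palindromic,
    reverse_complement,
    scan_encoded,
)

#: CME backbone flanks of the 24 bp module built around a 10 nt core.
DEFAULT_LEFT_FLANK = "CTAGAAGTTTGT"
DEFAULT_RIGHT_FLANK = "GA"

#: The RAM core: NRE (TCGTG) overlapping the AP-1 site by two base pairs.
RAM_CORE = "TCGTGACTCA"

#: Printed 24 nt module oligos.  The NRE+AP-1 module keeps the two motifs
#: separate with a spacer and does not follow the 12/10/2 anatomy, so it is
#: stored verbatim rather than built from parts.
NRE_AP1_MODULE = "CTTCGTGACTAGTCTTGACTCAGA"
MODULE_CORES = {
    "P_RAM": ("CTAGAAGTTTGT", "TCGTGACTCA", "GA"),
    "E1": ("CTAGAAGTTTGT", "TGACTCACCC", "GA"),
    "E2": ("CTAGAAGTTTGT", "TGACTCATTA", "GA"),
    "E3": ("CTAGAAGTTTGT", "GTATGACTCA", "GA"),
    "CME": ("CTAGAAATTTGT", "ACGTGCCACA", "GA"),
}

#: Minimal promoters used downstream of the module array; sequences are not
#: part of the design and must be supplied by the user when a concrete
#: assembly is needed (lengths in bp are published).
MINIMAL_PROMOTER_LENGTHS = {"fos": 99, "arc": 421, "hbg": 49, "cmv": 226}


def _validate_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-ACGT character(s) {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class EnhancerModule:
    """A 24 bp enhancer module: 12 nt left flank + 10 nt core + 2 nt right flank."""

    left: str
    core: str
    right: str

    def __post_init__(self) -> None:
        for name, part, n in (("left flank", self.left, 12),
                              ("core", self.core, 10),
                              ("right flank", self.right, 2)):
            if len(part) != n:
                raise ValueError(f"{name} must be {n} nt, got {len(part)}")

    @property
    def sequence(self) -> str:
        return self.left + self.core + self.right


@dataclass(frozen=True)
class MinimalPromoter:
    """A named minimal promoter; sequence optional, declared length required."""

    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"declared length {self.length} != sequence length "
                f"{len(self.sequence)} for minimal promoter {self.name!r}"
            )

    @classmethod
    def named(cls, name: str, sequence: str | None = None) -> "MinimalPromoter":
        key = name.lower()
        if key not in MINIMAL_PROMOTER_LENGTHS:
            raise KeyError(
                f"unknown minimal promoter {name!r}; "
                f"known: {sorted(MINIMAL_PROMOTER_LENGTHS)}"
            )
        return cls(key, MINIMAL_PROMOTER_LENGTHS[key], sequence)


#: Sentinel for a promoter with no minimal-promoter part.
NO_MINIMAL = MinimalPromoter("none", 0, "")


@dataclass(frozen=True)
class PromoterDesign:
    """Tandem-repeat promoter layout: module x repeats + linker + minimal promoter."""

    module: EnhancerModule
    repeats: int = 4
    linker: str = ""
    minimal: MinimalPromoter = NO_MINIMAL

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def length(self) -> int:
        return 24 * self.repeats + len(self.linker) + self.minimal.length


def build_module(
    core: str,
    left: str = DEFAULT_LEFT_FLANK,
    right: str = DEFAULT_RIGHT_FLANK,
) -> EnhancerModule:
    """Assemble a 24 bp enhancer module from a 10 nt core and CME flanks.

    >>> build_module("TCGTGACTCA").sequence
    'CTAGAAGTTTGTTCGTGACTCAGA'
    """
    return EnhancerModule(
        _validate_dna(left, "left flank"),
        _validate_dna(core, "core"),
        _validate_dna(right, "right flank"),
    )


def printed_modules() -> dict[str, str]:
    """The six printed 24 nt module oligos, keyed by their published names."""
    out = {"P_NRE+AP-1": NRE_AP1_MODULE}
    for name, (left, core, right) in MODULE_CORES.items():
        out[name] = build_module(core, left, right).sequence
    return out


def assemble_promoter(design: PromoterDesign) -> str:
    """Concrete promoter sequence for a design.

    Raises if the design names a minimal promoter without a supplied
    sequence — minimal-promoter sequences are external inputs, never
    fabricated here.
    """
    if design.minimal.length and design.minimal.sequence is None:
        raise ValueError(
            f"minimal promoter {design.minimal.name!r} has a declared length "
            f"({design.minimal.length} bp) but no sequence; supply one to "
            "assemble a concrete promoter"
        )
    linker = _validate_dna(design.linker, "linker") if design.linker else ""
    seq = design.module.sequence * design.repeats + linker + (
        design.minimal.sequence or ""
    )
    assert len(seq) == design.length
    return seq


@dataclass(frozen=True)
class ModuleReport:
    """Outcome of validating a candidate module sequence."""

    length: int
    length_ok: bool
    cores_found: dict[str, bool] = field(default_factory=dict)

    @property
    def compliant(self) -> bool:
        return self.length_ok


def validate_module(seq: str, expected_cores: list[str]) -> ModuleReport:
    """Check 24 bp compliance and which core patterns occur (either strand)."""
    if not seq:
        raise ValueError("empty module sequence")
    seq = seq.upper()
    enc = encode_sequence(seq)
    found: dict[str, bool] = {}
    for core in expected_cores:
        core = _validate_pattern(core)
        hit = len(scan_encoded(enc, core)) > 0
        if not hit and not is_palindromic(core):
            hit = len(scan_encoded(enc, reverse_complement(core))) > 0
        found[core] = hit
    return ModuleReport(length=len(seq), length_ok=len(seq) == 24, cores_found=found)
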