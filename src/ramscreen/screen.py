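"""The positional enrichment screen over enhancer-centered windows.

Hits for each 10mer pattern, pooled over all enhancer windows, are counted
in 40 bp non-overlapping bins across the 2 kb window.  The enrichment factor

    E = 4 * C / F

compares the hit count C in the four central bins (the -80..+80 region) to
the count F in the eight outermost bins on each flank (-1000..-680 and
+680..+1000); the factor 4 adjusts for the flanks covering four times as
many bins.  Significance against a uniform center/flank hit distribution is
a binomial test,

    p = 1 - CDF(4*C, 4*C + F, 0.5),

Bonferroni-corrected over the tested patterns.  Patterns with no counted
hits get p = 0.5 and are excluded from further consideration; survivors are
ranked by E.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .motifs import (
    KmerSet,
    MatchHit,
    encode_sequence,
    is_palindromic,
    reverse_complement,
    scan_encoded,
)
from .sequence_io import EnhancerCenter, GenomeMap, SequenceWindow, extract_windows

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Geometry and testing policy of the screen.

    All regions are unions of whole bins: with the defaults the window has
    50 bins, the central region is bins 23-26 (relative -80..+80) and the
    flanks are bins 0-7 and 42-49.
    """

    half_width: int = 1000
    bin_width: int = 40
    center_half_width: int = 80
    flank_bins_per_side: int = 8
    alpha: float = 0.05
    mode: str = "wildcard-N"
    m_rule: str = "tested"  # Bonferroni denominator: "tested" or "all"

    def __post_init__(self) -> None:
        if (2 * self.half_width) % self.bin_width:
            raise ValueError("window width must be a multiple of bin_width")
        if self.center_half_width % self.bin_width:
            raise ValueError("central region must align to whole bins")
        if self.m_rule not in ("tested", "all"):
            raise ValueError(f"unknown m_rule {self.m_rule!r}")

    @property
    def n_bins(self) -> int:
        return 2 * self.half_width // self.bin_width

    @property
    def center_bins(self) -> range:
        lo = (self.half_width - self.center_half_width) // self.bin_width
        hi = (self.half_width + self.center_half_width) // self.bin_width
        return range(lo, hi)

    @property
    def flank_bins(self) -> tuple[range, range]:
        return (
            range(0, self.flank_bins_per_side),
            range(self.n_bins - self.flank_bins_per_side, self.n_bins),
        )


@dataclass
class BinProfile:
    """Pooled per-bin hit counts across all windows for one pattern."""

    counts: np.ndarray
    bin_width: int = 40
    origin: int = -1000  # relative coordinate of the left edge of bin 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("bin counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EnrichmentResult:
    """Per-pattern screen outcome (one row of the ranked table)."""

    pattern: str
    C: int
    F: int
    E: float
    p: float
    p_adj: float
    rank: int | None = None
    excluded: bool = False
    reason: str = ""


def bin_hits(hits: Iterable[MatchHit], cfg: ScreenConfig = ScreenConfig()) -> BinProfile:
    """Histogram hits into bins by forward-strand relative start position."""
    counts = np.zeros(cfg.n_bins, dtype=np.int64)
    for h in hits:
        idx = h.rel_start + cfg.half_width
        if not 0 <= idx < 2 * cfg.half_width:
            raise ValueError(f"hit at relative {h.rel_start} outside window")
        counts[idx // cfg.bin_width] += 1
    return BinProfile(counts, bin_width=cfg.bin_width, origin=-cfg.half_width)


def center_flank_counts(
    profile: BinProfile, cfg: ScreenConfig = ScreenConfig()
) -> tuple[int, int]:
    """(C, F): hits in the central bins and in the outermost flank bins.

    The buffer bins between center and flanks are intentionally not counted.
    """
    counts = profile.counts
    if len(counts) != cfg.n_bins:
        raise ValueError(f"expected {cfg.n_bins} bins, got {len(counts)}")
    C = int(counts[list(cfg.center_bins)].sum())
    left, right = cfg.flank_bins
    F = int(counts[list(left)].sum() + counts[list(right)].sum())
    return C, F


def enrichment_factor(C: int, F: int) -> float:
    """E = 4*C/F; 0.0 for an empty center, +inf when only the center has hits."""
    if C < 0 or F < 0:
        raise ValueError("counts must be non-negative")
    if F == 0:
        return math.inf if C > 0 else 0.0
    return 4.0 * C / F


def binomial_p(C: int, F: int) -> float:
    """Upper-tail binomial p-value, p = 1 - CDF(4C, 4C+F, 0.5).

    The null hypothesis is that hits fall uniformly, so the size-adjusted
    central count 4C and the flank count F are an even split of 4C+F fair
    trials.  With no hits anywhere that is counted (C = F = 0) the test is
    undefined and the conventional p = 0.5 is returned; run_screen excludes
    such patterns.
    """
    if C < 0 or F < 0:
        raise ValueError("counts must be non-negative")
    if C == 0 and F == 0:
        return 0.5
    # sf is the exact complement of cdf, without cancellation for small p
    return float(binom.sf(4 * C, 4 * C + F, 0.5))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment min(1, m*p) over m tests."""
    if m < 1:
        raise ValueError(f"number of tests m={m} must be >= 1")
    return min(1.0, m * p)


def pattern_profiles(
    windows: Sequence[SequenceWindow],
    kmers: KmerSet,
    cfg: ScreenConfig = ScreenConfig(),
) -> dict[str, BinProfile]:
    """Pooled bin profile per pattern over all windows (both strands).

    Windows are scanned as one encoded matrix; reverse-strand hits come from
    scanning the reverse complement of each pattern, and palindromic patterns
    are scanned once so each site counts a single hit.
    """
    if not windows:
        raise ValueError("no windows to screen")
    enc = np.vstack([encode_sequence(w.sequence) for w in windows])
    profiles: dict[str, BinProfile] = {}
    for pattern in kmers:
        starts = scan_encoded(enc, pattern)[:, 1]
        if not is_palindromic(pattern):
            starts = np.concatenate(
                [starts, scan_encoded(enc, reverse_complement(pattern))[:, 1]]
            )
        counts = np.bincount(starts // cfg.bin_width, minlength=cfg.n_bins)
        profiles[pattern] = BinProfile(
            counts, bin_width=cfg.bin_width, origin=-cfg.half_width
        )
    return profiles


def run_screen(
    genome: GenomeMap,
    centers: Sequence[EnhancerCenter],
    kmers: KmerSet,
    cfg: ScreenConfig = ScreenConfig(),
) -> list[EnrichmentResult]:
    """Run the full enrichment screen and return the ranked result table.

    Survivors (Bonferroni-adjusted p < alpha) come first, ranked by E
    descending with ties broken by p ascending then pattern; excluded rows
    follow with their reasons.
    """
    windows, n_dropped = extract_windows(genome, centers, cfg.half_width)
    if not windows:
        raise ValueError("no retainable windows (all dropped at contig ends)")
    profiles = pattern_profiles(windows, kmers, cfg)
    return screen_from_profiles(profiles, cfg, n_patterns=len(kmers))


def screen_from_profiles(
    profiles: dict[str, BinProfile],
    cfg: ScreenConfig = ScreenConfig(),
    n_patterns: int | None = None,
) -> list[EnrichmentResult]:
    """Turn pooled per-pattern profiles into the ranked EnrichmentResult table."""
    rows: list[EnrichmentResult] = []
    for pattern, profile in profiles.items():
        C, F = center_flank_counts(profile, cfg)
        E = enrichment_factor(C, F)
        p = binomial_p(C, F)
        rows.append(EnrichmentResult(pattern=pattern, C=C, F=F, E=E, p=p, p_adj=p))

    tested = [r for r in rows if not (r.C == 0 and r.F == 0)]
    for r in rows:
        if r.C == 0 and r.F == 0:
            r.excluded = True
            r.reason = "no hits in center or flank bins"
    if cfg.m_rule == "tested":
        m = max(1, len(tested))
    else:
        m = n_patterns if n_patterns is not None else len(rows)
    logger.info("Bonferroni over m=%d tests (%d patterns, %d with hits)",
                m, len(rows), len(tested))

    for r in tested:
        r.p_adj = bonferroni(r.p, m)
        if math.isinf(r.E):
            r.reason = "no flank hits; E unbounded, review"
        if r.p_adj >= cfg.alpha:
            r.excluded = True
            r.reason = (r.reason + "; " if r.reason else "") + \
                f"not significant (p_adj >= {cfg.alpha})"

    survivors = [r for r in rows if not r.excluded]
    survivors.sort(key=lambda r: (-r.E, r.p, r.pattern))
    for i, r in enumerate(survivors, start=1):
        r.rank = i
    excluded = sorted((r for r in rows if r.excluded), key=lambda r: r.pattern)
    return survivors + excluded


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pattern": [r.pattern for r in results],
            "C": [r.C for r in results],
            "F": [r.F for r in results],
            "E": [r.E for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "rank": [r.rank for r in results],
            "excluded": [r.excluded for r in results],
            "reason": [r.reason for r in results],
        }
    )


def write_screen_table(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write the ranked table as TSV (E to 4 significant digits, p scientific)."""
    with open(path, "w") as fh:
        fh.write("pattern\tC\tF\tE\tp\tp_adj\trank\texcluded\treason\n")
        for r in results:
            fh.write(
                f"{r.pattern}\t{r.C}\t{r.F}\t{r.E:.4g}\t{r.p:.4e}\t"
                f"{r.p_adj:.4e}\t{'' if r.rank is None else r.rank}\t"
                f"{int(r.excluded)}\t{r.reason}\n"
            )
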