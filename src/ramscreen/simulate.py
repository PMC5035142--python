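"""Seeded synthetic genomes with motifs planted around enhancer centers.

The generator emulates the positional structure the enrichment screen is
built to detect: windows of background sequence centered on "enhancers",
with a chosen pattern planted at a higher per-bp rate inside the central
+/-80 bp than in the rest of the window.  Plant counts per region are
Poisson with mean rate*length; each plant overwrites bases (never inserts,
so the coordinate frame is fixed) with a concrete instance of the pattern on
a uniformly chosen strand.  Every output is a pure function of the config
and its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .motifs import IUPAC_BASES, _validate_pattern, reverse_complement
from .sequence_io import EnhancerCenter, GenomeMap

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    Rates are expected plants per bp; the central region is the +/-80 bp
    around each enhancer center and the flank is the remaining 1,840 bp of
    the 2 kb window.  With the defaults (2,000 enhancers, flank rate 5e-4,
    center rate 2e-3) a run pools roughly 640 flank plants in the counted
    outer bins and 640 central plants, enough for the screen's pooled E to
    resolve the planted four-fold rate ratio.
    """

    n_enhancers: int = 2000
    contig_length: int | None = None  # default: exactly tiling windows
    base_composition: dict[str, float] = field(
        default_factory=lambda: {"A": 0.29, "C": 0.21, "G": 0.21, "T": 0.29}
    )
    planted_pattern: str = "TCGTGANTCA"
    rate_center: float = 2e-3
    rate_flank: float = 5e-4
    seed: int = 0
    half_width: int = 1000
    center_half_width: int = 80
    allow_overlap: bool = False
    contig_name: str = "chrS"
    # optional first-order Markov background: 4x4 row-stochastic matrix in
    # ACGT order; None (default) gives i.i.d. bases from base_composition
    markov_transition: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        comp = np.array([self.base_composition[b] for b in _BASES])
        if (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must be probabilities summing to 1")
        if self.rate_center < 0 or self.rate_flank < 0:
            raise ValueError("plant rates must be non-negative")
        if self.contig_length is not None and self.contig_length < 2 * self.half_width:
            raise ValueError("contig_length must be at least one window wide")
        _validate_pattern(self.planted_pattern)

    @property
    def window_width(self) -> int:
        return 2 * self.half_width

    @property
    def expected_E(self) -> float:
        """Rate ratio the screen's enrichment factor estimates."""
        if self.rate_flank == 0:
            return float("inf") if self.rate_center > 0 else float("nan")
        return self.rate_center / self.rate_flank


@dataclass(frozen=True)
class PlantedSite:
    enhancer_id: int
    rel_pos: int  # forward-strand start, center-relative
    strand: str
    instance: str  # concrete planted k-mer, forward-strand orientation


@dataclass
class TruthRecord:
    """Ground truth of a simulation: every plant, and the generative rate ratio."""

    plants: list[PlantedSite]
    expected_E: float

    def __len__(self) -> int:
        return len(self.plants)


def _derive_seed(seed: int, salt: int) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def simulate_genome(cfg: SimulationConfig) -> tuple[GenomeMap, list[EnhancerCenter]]:
    """One contig of background sequence plus evenly spaced enhancer centers.

    Centers sit at least half_width from the contig ends; windows are
    non-overlapping unless cfg.allow_overlap.
    """
    n, w, hw = cfg.n_enhancers, cfg.window_width, cfg.half_width
    length = cfg.contig_length if cfg.contig_length is not None else n * w
    # centers evenly spaced over [hw, length - hw]
    if n == 1:
        positions = [length // 2]
    else:
        span = length - w
        if span < 0:
            raise ValueError(f"contig of length {length} too short for a window")
        positions = [hw + (i * span) // (n - 1) for i in range(n)]
    if not cfg.allow_overlap and n > 1 and min(np.diff(positions)) < w:
        raise ValueError(
            f"contig of length {length} too short for {n} non-overlapping windows"
        )
    rng = np.random.default_rng(_derive_seed(cfg.seed, 0))
    comp = np.array([cfg.base_composition[b] for b in _BASES])
    if cfg.markov_transition is None:
        idx = rng.choice(4, size=length, p=comp)
    else:
        trans = np.asarray(cfg.markov_transition, dtype=float)
        if trans.shape != (4, 4) or not np.allclose(trans.sum(axis=1), 1.0):
            raise ValueError("markov_transition must be 4x4 row-stochastic")
        cum = trans.cumsum(axis=1)
        u = rng.random(length)
        idx = np.empty(length, dtype=np.int64)
        idx[0] = rng.choice(4, p=comp)
        for i in range(1, length):
            idx[i] = np.searchsorted(cum[idx[i - 1]], u[i], side="right")
    seq = np.frombuffer("ACGT".encode(), dtype=np.uint8)[idx].tobytes().decode()
    centers = [EnhancerCenter(cfg.contig_name, p) for p in positions]
    for c in centers:
        assert hw <= c.center <= length - hw
    return GenomeMap({cfg.contig_name: seq}), centers


def _resolve_instance(pattern: str, rng: np.random.Generator) -> str:
    """Concrete k-mer instance with wildcards resolved uniformly."""
    return "".join(
        sym if sym in _BASES else rng.choice(sorted(IUPAC_BASES[sym]))
        for sym in pattern
    )


def plant_pattern(
    genome: GenomeMap,
    centers: Sequence[EnhancerCenter],
    cfg: SimulationConfig,
) -> tuple[GenomeMap, TruthRecord]:
    """Overwrite pattern instances into each window at the configured rates.

    Per window the central +/-80 bp receives Poisson(rate_center * 160)
    plants (start positions uniform over the central starts) and the rest of
    the window Poisson(rate_flank * 1840) plants; positions colliding with
    an earlier plant are redrawn up to 100 times, then skipped with a log
    entry.  Plants never extend past the window edge.
    """
    k = len(cfg.planted_pattern)
    hw, chw = cfg.half_width, cfg.center_half_width
    if k > 2 * chw:
        raise ValueError("pattern longer than the central region")
    rng = np.random.default_rng(_derive_seed(cfg.seed, 1))
    contigs = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    # collision tracking is genome-wide so overlapping windows cannot
    # overwrite each other's plants
    occupied_map = {name: np.zeros(len(seq), dtype=bool) for name, seq in genome.items()}
    plants: list[PlantedSite] = []
    n_skipped = 0

    center_starts = np.arange(-chw, chw)  # start in the central region
    flank_starts = np.concatenate(
        [np.arange(-hw, -chw), np.arange(chw, hw - k + 1)]
    )
    for eid, c in enumerate(centers):
        buf = contigs[c.contig]
        occupied = occupied_map[c.contig]
        n_center = rng.poisson(cfg.rate_center * 2 * chw)
        n_flank = rng.poisson(cfg.rate_flank * (2 * hw - 2 * chw))
        for region, n_plants in ((center_starts, n_center), (flank_starts, n_flank)):
            for _ in range(n_plants):
                for _attempt in range(100):
                    rel = int(rng.choice(region))
                    abs0 = c.center + rel
                    if not occupied[abs0 : abs0 + k].any():
                        break
                else:
                    n_skipped += 1
                    continue
                occupied[abs0 : abs0 + k] = True
                instance = _resolve_instance(cfg.planted_pattern, rng)
                strand = "+" if rng.random() < 0.5 else "-"
                written = instance if strand == "+" else reverse_complement(instance)
                buf[abs0 : abs0 + k] = written.encode()
                plants.append(PlantedSite(eid, rel, strand, instance))
    if n_skipped:
        logger.info("skipped %d plant(s) after 100 collision resamples", n_skipped)
    planted = GenomeMap({name: buf.decode() for name, buf in contigs.items()})
    return planted, TruthRecord(plants=plants, expected_E=cfg.expected_E)


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[GenomeMap, list[EnhancerCenter], TruthRecord]:
    """simulate_genome followed by plant_pattern."""
    genome, centers = simulate_genome(cfg)
    genome, truth = plant_pattern(genome, centers, cfg)
    return genome, centers, truth


def write_dataset(
    genome: GenomeMap,
    centers: Sequence[EnhancerCenter],
    truth: TruthRecord,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + BED3 + truth TSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    bed = out / "enhancers.bed"
    with open(bed, "w") as fh:
        for c in centers:
            fh.write(f"{c.contig}\t{c.center}\t{c.center + 1}\n")
    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("enhancer_id\trelative_pos\tstrand\tinstance\n")
        for p in truth.plants:
            fh.write(f"{p.enhancer_id}\t{p.rel_pos}\t{p.strand}\t{p.instance}\n")
    return {"fasta": fasta, "bed": bed, "truth": truth_path}
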