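# Methods

## The enrichment screen

**Model.** Activity-regulated enhancers are summarized by a point (their
center); functional binding sites are assumed to concentrate near that
point. For a k-mer pattern, hits are pooled over all enhancer windows and
reduced to two counts: *C* in the four central 40 bp bins (relative
−80..+80) and *F* in the eight outermost bins of each flank (−1000..−680
and +680..+1000). Under the null that hit density is positionally uniform,
the size-adjusted central count 4*C* and flank count *F* are an even split
of 4*C* + *F* trials, giving the one-sided binomial tail
p = 1 − CDF(4*C*, 4*C* + *F*, 0.5). The enrichment factor E = 4*C*/*F*
estimates the center/flank density ratio. The fifteen bins on each side
between center and flank are deliberately left out of both counts: they act
as a buffer so that *F* measures a genuinely distal background, and they are
retained only for conservation checks (C + F + middle = total hits).

**Coordinate conventions.** All coordinates are 0-based half-open; BED
intervals are reduced to their midpoint by floor division. A window covers
[center − 1000, center + 1000) on the forward strand; windows that would
overrun a contig end are dropped (not clipped) so every window contributes
exactly 50 bins. A hit is located at the forward-strand start of the
matched bases for both strands; at 40 bp bin width the ≤9 bp asymmetry this
introduces for reverse-strand hits of a 10mer is immaterial.

**Matching.** Matching is exact and IUPAC-aware (pattern N matches any base;
a genome N matches nothing, so masked or unknown sequence never produces
hits). Overlapping occurrences all count. Both strands are scanned by
scanning the reverse complement of the pattern along the forward strand; a
self-reverse-complementary pattern is scanned once so each site yields one
hit. The kernel encodes bases as 4-bit masks and AND-reduces k shifted
comparisons, which screens 128 patterns over 2,000 windows (4 Mb) in a few
seconds; a naive position-by-position scanner is kept in the test suite as
the independent oracle.

**Enumeration.** The default pattern set places the AP-1 consensus TGANTCA
(N kept as a wildcard) at each of the four offsets of a 10mer, fills the
three free positions with every concrete base, and collapses reverse
complements: 256 raw patterns pair two-to-one (the consensus is its own
reverse complement) to exactly 128 canonical patterns. A `fixed-core` mode
resolves the N to C (TGACTCA, the resolution observed in every
characterized core); the resolved core is not self-reverse-complementary,
so nothing collapses and that mode yields 256 patterns. Canonicalization
uses plain ASCII string order for determinism.

**Testing policy.** Patterns with C = F = 0 are assigned the conventional
p = 0.5 and excluded from ranking ("zero counted hits" is read as no hits
in either counted region; hits confined to the buffer bins also trigger
it). The Bonferroni denominator *m* defaults to the number of patterns with
at least one counted hit; a config switch uses the full set size instead.
Patterns with C > 0 but F = 0 get E = ∞ and p = 0 — a degenerate outcome of
the 4C-successes construction that typically reflects tiny counts — and are
ranked but flagged for review rather than silently trusted. Survivors
(adjusted p < α = 0.05) are ranked by E descending, ties broken by p then
pattern, which makes the output order deterministic and independent of
input enhancer order.

**A caveat on ranking by E.** E is a ratio estimator: patterns with very few
counted hits have high-variance E and can out-rank a strongly supported
pattern. In planted simulations this happens systematically, because a
planted instance of one AP-1 10mer creates shifted windows that match other
AP-1 10mers (the consensus occupies a different offset), so several
"shadow" patterns inherit weak but genuine central enrichment whose E
fluctuates above the planted ratio. Rank 1 for the planted pattern is
therefore not a stable property of the full-set screen; what is stable, and
what the tests assert, is that the planted pattern survives Bonferroni,
carries by far the largest hit count, and that its pooled E recovers the
planted rate ratio. Users ranking real screens should read E jointly with
C + F and p, exactly as the fold-enrichment/p-value pair is read in any
count-based enrichment analysis.

## Promoter assembly

An enhancer module is left flank (12 nt) + core (10 nt) + right flank
(2 nt) = 24 bp; the default flanks are the CME backbone's
(CTAGAAGTTTGT / GA). The six published module oligos are reproduced
byte-for-byte from their parts, except the NRE+AP-1 module, whose printed
sequence keeps the two motifs separated by a spacer and does not follow the
12/10/2 anatomy; it is stored verbatim. A promoter design is
module × repeats + linker + minimal promoter, with length
24·repeats + |linker| + |minimal|. Minimal promoter sequences are not
bundled — only their published lengths (FOS 99, Arc 421, hBG 49, CMV
226 bp) — so a concrete assembly requires the user to supply the sequence;
the canonical four-repeat FOS design reaches its published 199 bp total
only with a 4 bp linker, whose identity is likewise a user input rather
than an invention of this package.

## Reporter metrics

Relative luciferase is firefly/renilla; fold induction f is the
stimulated/unstimulated ratio of relative values and is invariant to common
scaling. Labeling purity uses the background-contamination model: baseline
(home-cage) labeling is assumed unchanged by the experience, so it
constitutes fraction 1/f of the induced count and purity = 100·(1 − 1/f).
This formula is a modeling assumption adopted because it exactly reproduces
all four published percentages (80/97% at f = 5/37; 50/67% at f = 2/3,
nearest integer). Overlap is 100·(double-labeled)/(reporter-labeled) and
depends only on those two counts. Density/total estimates are plain
arithmetic on counting-cube volumes (the exclusion of cells touching three
cube faces is an upstream counting convention, documented as a contract).
`smooth3` is a centered 3-point moving average; at the series endpoints the
window truncates to the two available points (the endpoint policy is a
choice; a stated alternative would be to drop endpoints).

## Synthetic data generator

The generator emulates only the positional structure the screen detects:
i.i.d. background bases (default composition A/T 0.29, C/G 0.21 — a
mammalian-like 42% GC), enhancer centers ≥1 kb from contig ends with
non-overlapping windows, and a planted pattern whose per-window plant counts
are Poisson(rate·region-length) with uniform start positions, uniform
strand, and wildcards resolved uniformly per instance. Plants overwrite
bases, preserving coordinates; colliding positions are redrawn up to 100
times then skipped with a log entry. A first-order Markov background is
available but off by default — exact 10mer matching is insensitive to the
background autocorrelation that option adds. Defaults are 2,000 enhancers,
flank rate 5×10⁻⁴ plants/bp and center rate 2×10⁻³ (ratio 4). The rates
were chosen by a power argument made before any testing: they yield ≈640
counted plants in both center and flanks, so the relative standard error of
E is ≈5–6% and chance 10mer matches (~10 per pattern genome-wide) bias E by
≲1%, comfortably inside the ±15% recovery band at ratios 2–8. What passing
recovery tests shows is that the estimator is calibrated under its own
generative model; real enhancer sequence (repeats, composition structure,
correlated enhancers, uncertain centers) can only be addressed with real
data.

All generator output is a pure function of (config, seed); seeds for the
background and planting stages are derived from the config seed via a seed
sequence and stay below 2³¹.

## Numerical choices and degenerate inputs

- Binomial tails use the survival function directly (no 1 − CDF
  cancellation); agreement with an exact rational tail sum is ≤10⁻¹² over
  C ≤ 50, F ≤ 200.
- E is reported as 0 when C = 0 (F > 0) and as +∞ when F = 0 (C > 0);
  neither raises.
- FASTA/BED parsing is strict: duplicate contigs, non-IUPAC characters and
  end ≤ start are errors naming the line; IUPAC ambiguity codes in input
  sequence normalize to N (and hence never match).
- Duplicate or overlapping enhancer centers are retained as-is; no
  deduplication is applied.

## Problem sizes

The test suite runs the screen at 2,000 enhancers × 2 kb (4 Mb per
replicate) with 20 replicates per condition for recovery (single-pattern
screen) and the null control (full 128-pattern screen); the whole suite
completes in a few minutes on one CPU.
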