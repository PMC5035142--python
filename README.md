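# ramscreen

Positional k-mer enrichment screening of activity-regulated enhancers, and
assembly of compact synthetic activity-dependent promoters of the RAM
(Robust Activity Marking) family.

## The problem

Immediate early gene (IEG) transcription marks recently active neurons, but
natural IEG promoters are large and weakly selective. A compact synthetic
promoter can be designed instead by asking, across thousands of
activity-regulated enhancers, which short DNA elements pile up at enhancer
centers — where the functional transcription-factor binding sites sit —
rather than in the distal flanks. `ramscreen` implements that screen, the
promoter-module assembly rules built on its output, and the small
quantitative models used to interpret the resulting reporters.

## The screen

For each enhancer a 2 kb window centered on the enhancer is extracted and
divided into fifty 40 bp bins. Every 10mer pattern containing the AP-1
consensus TGANTCA (128 patterns after collapsing reverse complements) is
matched exactly on both strands and its hits are pooled over all windows.
With *C* the hit count in the four central bins (−80..+80) and *F* the
count in the eight outermost bins of each flank (−1000..−680, +680..+1000),
the enrichment factor is

```
E = 4·C / F
```

(the factor 4 corrects for the flanks spanning 4× as many bins), and the
significance of the central concentration is the binomial tail

```
p = 1 − CDF(4C, 4C + F, 0.5),
```

Bonferroni-corrected across the tested patterns. Patterns with no counted
hits receive p = 0.5 and are set aside; survivors are ranked by *E*.

Around the screen the package provides:

- **Promoter assembly** — the 24 bp enhancer module (12 nt CME backbone +
  10 nt core + 2 nt), tandem-repeat promoter layouts on named minimal
  promoters (FOS 99 bp, Arc 421 bp, hBG 49 bp, CMV 226 bp), and validation
  against the published module oligos.
- **Reporter metrics** — firefly/renilla normalization, fold induction
  *f*, the labeling-purity model `purity = 100·(1 − 1/f)`, ensemble-overlap
  percentages, cube-count density/total-cell estimates, and 3-point
  smoothing of longitudinal luminescence series.
- **Synthetic data** — seeded genomes with a chosen pattern planted at a
  higher per-bp rate in the central ±80 bp of each enhancer window than in
  the flanks, with full ground truth for parameter-recovery testing.

## Worked example

```python
from ramscreen import (SimulationConfig, simulate_dataset, KmerSet,
                       canonical_form, run_screen, labeling_purity)

# 2,000 synthetic enhancers; the NRE/AP-1 fusion 10mer TCGTGANTCA planted
# centrally at 4x the flank rate
cfg = SimulationConfig(seed=42)
genome, centers, truth = simulate_dataset(cfg)

pattern = canonical_form(cfg.planted_pattern)
(result,) = run_screen(genome, centers, KmerSet(k=10, patterns=(pattern,)))
print(pattern, result.C, result.F, round(result.E, 3), result.p)
print(round(labeling_purity(37), 1))
```

prints

```
TCGTGANTCA 663 604 4.391 6.419278897338202e-305
97.3
```

663 pooled central hits against 604 in the counted flank bins give
E = 4·663/604 ≈ 4.39, recovering the planted four-fold center/flank rate
ratio, at an astronomically small binomial p — the pattern survives any
correction. The second line is the labeling purity implied by a 37-fold
reporter induction: ~97% of labeled cells are attributable to the
designated experience rather than background.

The same pipeline is available from the shell:

```sh
ramscreen simulate --config sim.yaml --out data/
ramscreen screen --genome data/genome.fa --enhancers data/enhancers.bed --out screen.tsv
ramscreen design --core TCGTGACTCA --repeats 4 --minimal fos
ramscreen purity --fold 37
```

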