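# ystr-founder

Founder-effect analysis of Y-chromosomal STR haplotypes.

Island populations settled by a handful of males retain a paternal
signature for centuries: because the Y chromosome passes father to son
without recombination, every chromosome in the modern population traces
back to the founding haplotypes, modified only by stepwise microsatellite
mutation. This package detects and quantifies that signature in wide
haplotype tables (one row per man, one integer repeat-count column per
Y-STR locus, plus population and optional haplogroup labels).

## What it computes

**Mutational distance from the modal haplotype (MDM).** Within a
population × haplogroup stratum, the modal haplotype collects the
per-locus modes *Mo·ᵢ*; each individual's distance is

    MDM = Σᵢ |Moᵢ − xᵢ|,   i = 1 … l loci,

the number of stepwise mutations separating him from the mode. A recent
founder event compresses the MDM histogram against zero — most men are
"neighbor haplotypes" (MDM ≤ 1) — and skews it right (moment skewness
γ₁ = m₃/m₂^{3/2} > 0). Older, equilibrated populations show broader
histograms with the mode shifted away from zero. Multimodal histograms
flag founders carrying divergent haplotypes (or haplogroup
misclassification, which a strict classifier-score filter can probe).

**Diversity statistics.** Per stratum: the number of multilocus genotypes
MLG; its expectation eMLG in a rarefied subsample of size
g = max(10, smallest compared N) (Hurlbert's hypergeometric rarefaction);
the sample-size-corrected Simpson index λ = (N/(N−1))(1 − Σpᵢ²), also
reported as haplotype diversity Hd; and the percentages of unique
(100·k/N) and private (found in no other population) haplotypes.

**Minimum spanning networks.** Individuals collapse onto distinct
haplotypes (nodes sized by carrier count, annotated with population
composition); Kruskal's algorithm spans them under Hamming or stepwise
distance, retaining equal-length alternative edges. GraphML export.

**AMOVA.** One-level analysis of molecular variance on squared pairwise
distances: Φ_PT, the among-population fraction of molecular variance,
with a label-permutation test (99 permutations by default, so the
smallest attainable p is 0.01).

**Simulator.** A forward-time haploid Wright–Fisher model under the
single-step stepwise mutation model with locus-specific rates: mainland
sources equilibrated by burn-in, islands founded by few (optionally
paternally related) males and grown along a census trajectory, optional
admixture. It emits the same table format the analyses consume, with a
ground-truth sidecar.

## Worked example

`examples/03_mdm_histograms.py` simulates one equilibrated source
(male Nₑ 250, 1,500 burn-in generations) and an island founded 57
generations ago by three men of one patriline, then compares MDM
histograms:

```
 stratum  n  neighbor_proportion  gamma1  hist_mode  ...
source_1 60                 0.17    0.20          2  ...
island_1 60                 0.62    0.52          0  ...

source_1: 17% neighbors, gamma1 = 0.20, histogram {1: 10, 2: 12, 3: 8, 4: 3, 9: 4, 10: 9, 11: 7, 12: 7}
island_1: 62% neighbors, gamma1 = 0.52, histogram {0: 24, 1: 13, 2: 18, 3: 4, 4: 1}
```

The island's histogram peaks at zero with 62% of chromosomes within one
mutational step of the mode and a positive skew; the source's mode has
drifted to two steps with only 17% neighbors — the shape contrast the MDM
method reads as a founder signal. The other scripts in `examples/` walk
through table normalisation, diversity tables, networks, AMOVA, and a
time-since-founding sweep.

A thin CLI wraps the same functions for shell use:

```
ystr-founder simulate --seed 7 --out sim.csv
ystr-founder diversity sim.csv
ystr-founder all sim.csv --out bundle/ --seed 7
```

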