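# Methods

## Data model and locus conventions

Input is a wide table of integer repeat counts, one row per sampled male,
with `sample_id`, `population`, optional `haplogroup` plus classifier
scores (`hg_probability` in [0,1], `hg_fitness` ≥ 0), and one column per
locus. Three conventions standard for Y-STR panels are applied as
explicit, idempotent operations before analysis:

* **DYS389b** = DYS389II − DYS389I. The DYS389II amplicon contains the
  DYS389I repeat block, so the difference isolates the distal block; a
  negative difference is biologically impossible and is treated as a
  record-level error, a zero difference as a warning.
* **DYS385a/b ordering.** DYS385 is duplicated on the Y and the two
  alleles are not phase-resolved; the shorter allele is stored as
  DYS385a, the longer as DYS385b, making haplotypes comparable across
  sources regardless of reporting order.
* **Discreteness.** Intermediate alleles (e.g. 13.2) and missing values
  are excluded, never rounded or imputed — a fractional repeat is a
  different sequence structure, not a measurement near an integer. The
  exclusion report lists every affected cell.

The default analysis core is nine loci (DYS19, DYS385a, DYS385b, DYS389I,
DYS389b, DYS390, DYS391, DYS392, DYS393): the classic 12-locus panel
minus DYS388, DYS426 and DYS438, which mutate slowly, discriminate
haplogroups rather than haplotypes, and are missing from several widely
used published datasets. The core is fully configurable; DYS385a/b stay
in because they are typed in all datasets the package targets.

Haplogroup labels are inputs, not inferences. Records lacking a label are
excluded only from haplogroup-stratified operations.

## MDM histograms

For a stratum (population × haplogroup), the modal haplotype takes the
per-locus mode of repeat counts. Under the single-step stepwise mutation
model the L1 distance counts mutational steps, so each individual's
mutational distance from the modal haplotype is MDM = Σᵢ |Moᵢ − xᵢ|.

Summaries per stratum: the histogram of MDM values; the **neighbor
proportion**, the fraction of individuals with MDM ≤ 1 (the default
includes carriers of the mode itself; an `exactly_one` option counts
MDM = 1 only, since both readings appear in practice); and the moment
skewness γ₁ = m₃/m₂^{3/2} with 1/n central moments — the uncorrected
moment-ratio convention of the classic R `moments` library, with no
small-sample bias correction. γ₁ is reported as NaN for n < 3 or zero
variance. A histogram's modal distance (argmax, smallest on ties) and a
multimodality flag (two or more local maxima separated by a strictly
lower or empty bin; plateaus count once) support shape comparison across
strata.

Mode ties are broken to the smallest repeat count, deterministically; all
tied alternatives are recorded on the `ModalHaplotype` so sensitivity can
be audited. The modal haplotype is always computed per stratum, not
globally — pooling haplogroups mixes distinct genealogies and blurs the
founder signal the method is designed to expose.

The optional **strict filter** retains records with classifier
probability > 0.90 and fitness > 50 (strict inequalities). Comparing MDM
histograms before and after distinguishes genuine within-haplogroup
structure from haplogroup classification error: misassigned records
scatter far from the mode and vanish under the filter, whereas a truly
multimodal stratum keeps its shape.

### Interpretation caution

MDM histograms of *any* stratum are right-skew-prone — distances are
bounded below at zero with an open right tail — so a positive γ₁ alone is
not evidence of a founder event; equilibrated populations can show γ₁ near
or above the island range. The discriminating features are the joint
pattern: mode at or near zero, high neighbor proportion, and compressed
support. The package therefore reports the full histogram alongside the
scalar summaries rather than ranking strata by γ₁.

## Diversity statistics

Let the stratum contain N individuals in classes of identical haplotypes
with sizes n₁…n_k (MLG = k distinct multilocus genotypes; the count of
distinct haplotypes "k" in summary tables is the same quantity by
definition — published tables occasionally print the two columns from
different pipelines and they can disagree; this package computes one
number).

* **Rarefied richness.** eMLG at depth g is Hurlbert's expectation
  E = Σᵢ [1 − C(N−nᵢ, g)/C(N, g)], the mean number of classes hit by a
  uniform subsample of g individuals, computed with exact integer
  binomials. At g = N it equals MLG; for N < g the observed MLG is
  returned (no extrapolation). The table-level depth rule is
  g = max(10, smallest compared stratum N): richness is standardised to
  the smallest sample, floored at 10 so that a tiny stratum (which
  simply reports eMLG = MLG) does not drag every other stratum to an
  uninformative depth.
* **λ and Hd** are the same estimator, (N/(N−1))(1 − Σpᵢ²) with
  pᵢ = nᵢ/N: the unbiased probability that two individuals drawn without
  replacement differ. It is 1 iff all classes are singletons, 0 iff one
  class. Both columns are reported because readers expect both names.
* **%unique** = 100·k/N. **%private** counts, by default, *individuals*
  whose haplotype occurs in no other compared population (denominator N);
  a per-distinct-haplotype convention is available
  (`private_mode="haplotypes"`). The per-individual reading is the
  default because a "share of the sample" phrasing matches it. With a
  single population the comparison is vacuous and every haplotype counts
  as private.

Values are kept at full precision internally; rounding (two decimals,
one for percentages) is presentation-side.

## Networks

Individuals collapse onto distinct haplotypes; nodes carry carrier count
and per-population composition. Pairwise node distances use Hamming
(number of differing loci — robust to multi-step mutations and the
default) or stepwise (L1, consistent with the MDM logic). Kruskal's
algorithm runs over weight classes: within a class, any edge joining two
components *as they stood when the class opened* is retained, and those
that still join distinct components when reached are flagged as MST
edges. The flagged subset is a minimum spanning tree; the retained tied
edges make the result a network that preserves equally parsimonious
alternatives (a strict-tree flag drops them). Total MST weight is
invariant to tie-break order by the exchange property, which the tests
verify against exhaustive spanning-tree enumeration.

Mean within-population distance is computed over all unordered
*individual* pairs (not collapsed nodes), so shared haplotypes contribute
zero-distance pairs; the SD uses denominator (#pairs − 1). Collapsed
nodes would overstate the mean in exactly the populations where founder
effects concentrate carriers on few haplotypes.

## AMOVA

One-level decomposition on squared distances (squaring is applied to the
supplied metric distances by default):

    SS_total  = Σ_{i<j} d²ᵢⱼ / N
    SS_within = Σ_p Σ_{i<j∈p} d²ᵢⱼ / n_p
    MS_among  = (SS_total − SS_within)/(P−1),  MS_within = SS_within/(N−P)
    n₀ = (N − Σ n_p²/N)/(P−1)
    σ²_among = (MS_among − MS_within)/n₀,  σ²_within = MS_within
    Φ_PT = σ²_among / (σ²_among + σ²_within)

The reported Φ_PT is truncated at zero (negative variance-component
estimates are sampling noise), but the permutation test compares
*untruncated* statistics: truncating first piles permuted values onto an
atom at zero and makes the test conservative under the null — with
truncation the null mean p was ≈ 0.73 instead of 0.5 in the package's own
calibration. p = (1 + #{Φ_perm ≥ Φ_obs})/(1 + n_perm) with labels
permuted across individuals; 99 permutations by default (minimum p 0.01).
Populations of one individual are excluded with a warning since they
contribute no within-group pairs.

## Simulator

Haploid Wright–Fisher with single-step SMM: each of N sons draws a father
uniformly; each locus then mutates with its per-generation probability μ,
moving ±1 repeat with equal probability and reflecting at the locus's
allele bounds (a held-at-bound option exists; the boundary is rarely
touched at realistic rates). Per-locus μ defaults are published point
estimates for the 12-locus panel, from 0.0007 (DYS392, DYS426, DYS438)
to 0.0035 (DYS389b).

Scenario defaults describe a North-Atlantic-style settlement: sources of
effective male size 500 equilibrated for 1,000 generations; an island
founded 57 generations ago (≈1,700 years at 30 years/generation) by 5
males, growing geometrically to an effective male size of 1,600 (a
census of ≈3,200 halved, counting reproducing males); no migration;
samples of 50 per population. Founders can be restricted to fewer
patrilines (`n_patrilines`), duplicating founding haplotypes — the
"paternally related founders" scenario under which the MDM right-shift
prediction holds cleanly; unrelated founders carrying divergent
haplotypes instead generate multimodal island histograms, a pattern the
comparison table flags rather than hides. Sources keep evolving during
the island phase so optional migrants are drawn from contemporaneous
source generations. Everything derives from one seeded generator; a
truth sidecar records founder haplotypes, seed and configuration.

### What the simulations do and do not show

The generator reproduces the mechanisms the analyses target — bottleneck,
drift, stepwise mutation, growth — under idealised conditions: discrete
non-overlapping generations, uniform paternity, a single-step symmetric
SMM with no multi-step or length-dependent mutation, no population
structure within sources, and no genotyping error. Passing the
simulation-based tests therefore shows the statistics respond to founder
events as designed, not that real datasets are free of the confounders
the idealisation omits (classification error, admixture, structured
sources). Test problem sizes are scaled down from the scenario defaults:
equilibrium-dependent checks use source Nₑ 250 with burn-in 1,500
(six times Nₑ); relative-contrast checks use Nₑ 120 with burn-in 300,
which this package treats as adequate for orderings though not for
absolute equilibrium levels. Replicate counts are 50–200 per property
with one-sided tests at α = 0.01 on replicate means.

## Numerical and degenerate-input choices

* Rarefaction uses exact integer binomial coefficients (no log-gamma
  approximation); class sizes must be positive integers.
* λ/Hd require N ≥ 2; γ₁ requires n ≥ 3 and positive variance, else NaN.
* Mode ties: smallest repeat count, recorded; histogram argmax ties:
  smallest distance.
* Empty strata are omitted from tables; an all-excluded dataset raises
  rather than returning an empty frame.
* Single-node networks have empty edge sets; AMOVA refuses fewer than
  two usable populations.
* Seeds: every stochastic path (simulation, permutation) accepts an
  integer seed or a `numpy.random.Generator`; identical seeds give
  byte-identical outputs.

## Known limitations

* MDM locates founder signals but is not calibrated as a dating method;
  no mismatch-distribution model fitting is attempted.
* The AMOVA is strictly one-level (no region/population hierarchy).
* Median-joining networks and correspondence analysis are out of scope;
  the MSN with retained ties is the only network type.
* The simulator is forward-time and male-only; for very large populations
  a coalescent approach would be cheaper, but forward simulation keeps
  census trajectories and migration exact and transparent.
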