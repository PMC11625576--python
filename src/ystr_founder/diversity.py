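"""Genotypic richness and diversity statistics for haplotype strata.

The statistics mirror the standard population-genetic summary table for
multilocus Y-STR data:

* ``MLG`` — number of distinct multilocus genotypes (haplotypes) observed.
* ``eMLG`` — expected number of genotypes in a random subsample of fixed
  size ``g`` (Hurlbert's hypergeometric rarefaction), which makes richness
  comparable across unequal sample sizes.
* ``lambda`` — Simpson's index corrected for sample size,
  (N/(N−1))·(1 − Σ p_i²): the probability that two individuals drawn
  without replacement carry different haplotypes.
* ``Hd`` — haplotype diversity; the same unbiased estimator, reported
  under the name conventional for haploid data.
* ``%unique`` / ``%private`` — the fraction of a population's sample that
  is carried by distinct haplotypes, and the fraction carried by
  haplotypes observed in no other population.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import HaplotypeDataset

__all__ = [
    "genotype_class_sizes",
    "count_mlg",
    "rarefied_mlg",
    "simpson_corrected",
    "haplotype_diversity",
    "unique_private",
    "haplogroup_frequencies",
    "diversity_table",
]


def genotype_class_sizes(stratum: HaplotypeDataset) -> np.ndarray:
    """Multiset of haplotype class sizes (one entry per distinct haplotype)."""
    if stratum.n == 0:
        raise ValueError("empty stratum")
    counts = Counter(stratum.haplotypes())
    return np.asarray(sorted(counts.values(), reverse=True), dtype=np.int64)


def count_mlg(stratum: HaplotypeDataset) -> int:
    """Number of distinct multilocus genotypes in the stratum."""
    return int(len(genotype_class_sizes(stratum)))


def _as_counts(genotype_counts: Iterable[int]) -> np.ndarray:
    counts = np.asarray(list(genotype_counts), dtype=np.int64)
    if counts.size == 0:
        raise ValueError("empty class-size multiset")
    if (counts <= 0).any():
        raise ValueError("class sizes must be positive integers")
    return counts


def rarefied_mlg(genotype_counts: Iterable[int], g: int) -> float:
    """Hurlbert's expected number of genotype classes in a subsample of size g.

    E[MLG_g] = Σ_i [1 − C(N−n_i, g) / C(N, g)] over classes with sizes
    n_i and N = Σ n_i, i.e. one minus the hypergeometric probability that
    class i is entirely missed, summed over classes.  When N < g the full
    observed class count is returned (no extrapolation), and at g = N the
    expectation collapses to the exact MLG.
    """
    counts = _as_counts(genotype_counts)
    if g < 1:
        raise ValueError("rarefaction depth g must be >= 1")
    n_total = int(counts.sum())
    if n_total < g:
        return float(len(counts))
    denom = math.comb(n_total, g)
    return float(
        sum(1.0 - math.comb(n_total - int(n), g) / denom for n in counts)
    )


def simpson_corrected(genotype_counts: Iterable[int]) -> float:
    """Sample-size-corrected Simpson's index (N/(N−1))·(1 − Σ p_i²).

    Equals 1 when every individual carries a distinct haplotype and 0 when
    all are identical; undefined for N < 2.
    """
    counts = _as_counts(genotype_counts)
    n_total = int(counts.sum())
    if n_total < 2:
        raise ValueError("corrected Simpson's index requires N >= 2")
    p = counts / n_total
    return float(n_total / (n_total - 1) * (1.0 - np.sum(p**2)))


def haplotype_diversity(genotype_counts: Iterable[int]) -> float:
    """Haplotype diversity Hd — the unbiased (N/(N−1))·(1 − Σ p_i²).

    Numerically identical to :func:`simpson_corrected`; kept as a named
    alias because summary tables conventionally report both columns.
    """
    return simpson_corrected(genotype_counts)


def unique_private(
    dataset: HaplotypeDataset,
    focal_population: str,
    *,
    private_mode: str = "individuals",
) -> tuple[int, float, float]:
    """(k, %unique, %private) for one population against all others.

    k is the number of distinct haplotypes in the focal population and
    %unique = 100·k/N.  %private counts, by default, the *individuals*
    whose haplotype occurs in no other population (denominator N);
    ``private_mode="haplotypes"`` counts distinct private haplotypes
    instead (denominator k, scaled by 100·k/N·... kept simple: 100·
    private_k/N).
    """
    if focal_population not in dataset.populations:
        raise KeyError(
            f"unknown population {focal_population!r}; "
            f"available: {dataset.populations}"
        )
    if private_mode not in ("individuals", "haplotypes"):
        raise ValueError("private_mode must be 'individuals' or 'haplotypes'")
    focal = dataset.subset(population=focal_population)
    haps = focal.haplotypes()
    n = len(haps)
    k = len(set(haps))
    others = dataset.subset(
        population=[p for p in dataset.populations if p != focal_population]
    )
    other_set = set(others.haplotypes()) if others.n else set()
    if private_mode == "individuals":
        n_private = sum(1 for h in haps if h not in other_set)
    else:
        n_private = sum(1 for h in set(haps) if h not in other_set)
    return k, 100.0 * k / n, 100.0 * n_private / n


def haplogroup_frequencies(dataset: HaplotypeDataset) -> pd.DataFrame:
    """Population x haplogroup relative-frequency table.

    Frequencies are per population over the individuals that carry a
    haplogroup label; columns ordered by overall frequency.
    """
    df = dataset.df.dropna(subset=["haplogroup"])
    if df.empty:
        raise ValueError("no haplogroup labels in dataset")
    table = pd.crosstab(df["population"], df["haplogroup"], normalize="index")
    order = (
        pd.crosstab(df["population"], df["haplogroup"])
        .sum(axis=0)
        .sort_values(ascending=False)
        .index
    )
    return table.loc[:, order]


def rarefaction_depth(stratum_sizes: Sequence[int], *, floor: int = 10) -> int:
    """Shared rarefaction depth for a set of compared strata.

    g = max(floor, smallest stratum size): richness is rarefied to the
    smallest compared sample, but never below ``floor`` individuals so
    that tiny strata (which simply report eMLG = MLG) do not drag every
    other stratum down to an uninformative depth.
    """
    if not stratum_sizes:
        raise ValueError("no strata")
    return max(floor, min(int(s) for s in stratum_sizes))


def diversity_table(
    dataset: HaplotypeDataset,
    *,
    by_haplogroup: bool = False,
    g: int | None = None,
    private_mode: str = "individuals",
    include_total: bool = False,
) -> pd.DataFrame:
    """Per-stratum diversity summary (one row per population[, haplogroup]).

    Columns: population, haplogroup, N, MLG, eMLG, g, lambda, Hd, k,
    pct_unique, pct_private.  The rarefaction depth defaults to
    ``max(10, min stratum N)`` across the tabulated strata; strata smaller
    than g report eMLG = MLG.  %private compares populations within the
    same haplogroup stratum when stratified.  Values are reported at full
    precision; round at presentation time.
    """
    strata = [(key, ds) for key, ds in dataset.strata(by_haplogroup) if ds.n > 0]
    if not strata:
        raise ValueError("dataset has no non-empty strata")
    if g is None:
        g = rarefaction_depth([ds.n for _, ds in strata])

    rows = []
    for (pop, hg), ds in strata:
        counts = genotype_class_sizes(ds)
        n = int(counts.sum())
        mlg = len(counts)
        emlg = rarefied_mlg(counts, g)
        lam = simpson_corrected(counts) if n >= 2 else np.nan
        comparison = dataset.subset(haplogroup=hg) if by_haplogroup else dataset
        if len(comparison.populations) >= 2:
            k, pct_u, pct_p = unique_private(
                comparison, pop, private_mode=private_mode
            )
        else:
            k = mlg
            pct_u = 100.0 * k / n
            pct_p = np.nan
        rows.append((pop, hg, n, mlg, emlg, g, lam, lam, k, pct_u, pct_p))
    if include_total:
        if by_haplogroup:
            for hg in dataset.haplogroups:
                ds = dataset.subset(haplogroup=hg)
                counts = genotype_class_sizes(ds)
                n = int(counts.sum())
                lam = simpson_corrected(counts) if n >= 2 else np.nan
                rows.append(
                    ("Total", hg, n, len(counts), rarefied_mlg(counts, g), g,
                     lam, lam, len(counts), 100.0 * len(counts) / n, np.nan)
                )
        else:
            counts = genotype_class_sizes(dataset)
            n = int(counts.sum())
            lam = simpson_corrected(counts) if n >= 2 else np.nan
            rows.append(
                ("Total", None, n, len(counts), rarefied_mlg(counts, g), g,
                 lam, lam, len(counts), 100.0 * len(counts) / n, np.nan)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "population",
            "haplogroup",
            "N",
            "MLG",
            "eMLG",
            "g",
            "lambda",
            "Hd",
            "k",
            "pct_unique",
            "pct_private",
        ],
    )
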