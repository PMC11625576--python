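"""Diversity statistics: rarefaction, corrected Simpson, unique/private."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ystr_founder.diversity import (
    count_mlg,
    diversity_table,
    genotype_class_sizes,
    haplogroup_frequencies,
    haplotype_diversity,
    rarefied_mlg,
    simpson_corrected,
    unique_private,
)

from conftest import build_dataset, dataset_with_class_sizes


def enumerate_rarefied_mlg(class_sizes, g):
    """Brute-force oracle: average distinct classes over all C(N, g) subsamples."""
    individuals = []
    for cls, size in enumerate(class_sizes):
        individuals.extend([cls] * size)
    total = 0
    count = 0
    for combo in itertools.combinations(range(len(individuals)), g):
        total += len({individuals[i] for i in combo})
        count += 1
    return total / count


def test_count_mlg(make_class_dataset):
    assert count_mlg(make_class_dataset([3, 2, 1])) == 3
    assert count_mlg(make_class_dataset([6])) == 1
    assert count_mlg(make_class_dataset([1] * 5)) == 5


def test_genotype_class_sizes_multilocus(make_dataset):
    ds = make_dataset([[14, 23], [14, 23], [14, 24]])
    assert genotype_class_sizes(ds).tolist() == [2, 1]


@pytest.mark.parametrize(
    "counts,g,expected",
    [
        ([1] * 9 + [2], 10, 9.18),           # 11 samples, 10 genotypes
        ([2, 1, 1], 2, 11 / 6),              # enumeration-checked
        ([1] * 5, 10, 5.0),                  # N < g returns MLG
        ([5, 3, 2], 10, 3.0),                # g = N returns MLG exactly
    ],
)
def test_rarefied_mlg_examples(counts, g, expected):
    assert rarefied_mlg(counts, g) == pytest.approx(expected, abs=5e-3)


def test_rarefied_mlg_validation():
    with pytest.raises(ValueError):
        rarefied_mlg([2, 0], 2)
    with pytest.raises(ValueError):
        rarefied_mlg([2, 1], 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(min_value=1, max_value=5), min_size=1, max_size=6).filter(
        lambda c: sum(c) <= 8
    ),
    st.data(),
)
def test_rarefied_mlg_matches_enumeration(counts, data):
    g = data.draw(st.integers(min_value=1, max_value=sum(counts)))
    assert rarefied_mlg(counts, g) == pytest.approx(
        enumerate_rarefied_mlg(counts, g), abs=1e-12
    )


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=8))
def test_rarefied_mlg_monotone_in_g(counts):
    n = sum(counts)
    values = [rarefied_mlg(counts, g) for g in range(1, n + 1)]
    assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
    assert values[-1] == pytest.approx(len(counts))


@pytest.mark.parametrize(
    "counts,expected",
    [
        ([1] * 6, 1.0),                              # all distinct
        ([3, 2, 1], (6 / 5) * (1 - 14 / 36)),        # hand computation
        ([6], 0.0),                                  # monomorphic
        ([1, 1], 1.0),                               # two distinct, forced
    ],
)
def test_simpson_corrected(counts, expected):
    assert simpson_corrected(counts) == pytest.approx(expected)
    assert haplotype_diversity(counts) == pytest.approx(expected)


def test_simpson_needs_two():
    with pytest.raises(ValueError):
        simpson_corrected([1])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=8))
def test_simpson_boundary_characterisation(counts):
    if sum(counts) < 2:
        return
    lam = simpson_corrected(counts)
    assert 0.0 <= lam <= 1.0 + 1e-12
    assert (lam == pytest.approx(1.0)) == all(c == 1 for c in counts)
    assert (lam == pytest.approx(0.0)) == (len(counts) == 1)


def test_unique_private_two_identical_populations(make_dataset):
    ds = build_dataset(
        [[14], [15], [14], [15]],
        populations=["P1", "P1", "P2", "P2"],
        locus_names=["DYS19"],
    )
    for pop in ("P1", "P2"):
        k, pct_u, pct_p = unique_private(ds, pop)
        assert (k, pct_u, pct_p) == (2, 100.0, 0.0)


def test_unique_private_disjoint_and_modes(make_dataset):
    ds = build_dataset(
        [[14], [14], [15], [16], [17]],
        populations=["P1", "P1", "P1", "P2", "P2"],
        locus_names=["DYS19"],
    )
    k, pct_u, pct_p = unique_private(ds, "P1")
    assert k == 2
    assert pct_u == pytest.approx(100 * 2 / 3)
    assert pct_p == pytest.approx(100.0)  # nothing shared with P2
    k2, _, pct_hap = unique_private(ds, "P1", private_mode="haplotypes")
    assert k2 == 2 and pct_hap == pytest.approx(100 * 2 / 3)
    with pytest.raises(KeyError):
        unique_private(ds, "nope")


def test_single_population_private_vacuous(make_dataset):
    # with no other population every haplotype is private: the
    # per-haplotype convention collapses onto %unique, the per-individual
    # convention onto 100%
    ds = build_dataset([[14], [14], [15]], locus_names=["DYS19"])
    _, pct_u, pct_p_hap = unique_private(ds, "pop1", private_mode="haplotypes")
    assert pct_p_hap == pct_u
    _, _, pct_p_ind = unique_private(ds, "pop1")
    assert pct_p_ind == 100.0


def test_pooling_never_reduces_k(make_dataset):
    ds = build_dataset(
        [[14], [15], [15], [16]],
        populations=["P1", "P1", "P2", "P2"],
        locus_names=["DYS19"],
    )
    k1 = count_mlg(ds.subset(population="P1"))
    k2 = count_mlg(ds.subset(population="P2"))
    k_pool = count_mlg(ds)
    assert k_pool >= max(k1, k2)


def test_haplogroup_frequencies(make_dataset):
    ds = build_dataset(
        [[14]] * 6,
        populations=["P1"] * 4 + ["P2"] * 2,
        haplogroups=["R1a", "R1a", "R1b", "I1", "R1b", "R1b"],
        locus_names=["DYS19"],
    )
    freq = haplogroup_frequencies(ds)
    assert freq.loc["P1", "R1a"] == pytest.approx(0.5)
    assert freq.loc["P2", "R1b"] == pytest.approx(1.0)


def test_diversity_table_depth_rule_equal_sizes():
    # two populations, smallest N = 36 >= 10 -> g = 36; the 36-sample
    # population reports eMLG = MLG exactly
    p1 = dataset_with_class_sizes([2] * 6 + [1] * 24, population="P1")
    big = dataset_with_class_sizes([2] * 10 + [1] * 30, population="P2")
    ds = build_dataset(
        p1.df[["L1"]].values.tolist() + big.df[["L1"]].values.tolist(),
        populations=["P1"] * 36 + ["P2"] * 50,
        locus_names=["L1"],
    )
    table = diversity_table(ds)
    row = table.set_index("population").loc["P1"]
    assert row["g"] == 36
    assert row["eMLG"] == pytest.approx(row["MLG"])


def test_diversity_table_depth_floor(make_dataset):
    # smallest stratum N = 2 -> depth floored at 10
    ds = build_dataset(
        [[14]] * 2 + [[v] for v in range(12)],
        populations=["P1"] * 2 + ["P2"] * 12,
        locus_names=["DYS19"],
    )
    table = diversity_table(ds)
    assert set(table["g"]) == {10}
    small = table.set_index("population").loc["P1"]
    assert small["eMLG"] == pytest.approx(small["MLG"])  # N < g


def test_diversity_table_stratified_omits_empty(make_dataset):
    ds = build_dataset(
        [[14], [15], [16], [17]],
        populations=["P1", "P1", "P2", "P2"],
        haplogroups=["R1a", "R1a", "R1b", "R1b"],
        locus_names=["DYS19"],
    )
    table = diversity_table(ds, by_haplogroup=True)
    pairs = set(zip(table["population"], table["haplogroup"]))
    assert pairs == {("P1", "R1a"), ("P2", "R1b")}
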