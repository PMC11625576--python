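"""Modal haplotypes, MDM distributions, neighbor proportion, skewness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ystr_founder.mdm import (
    compare_mdm,
    count_histogram_peaks,
    mdm_distance,
    mdm_distribution,
    modal_haplotype,
    sample_skewness,
    strict_filter,
)

from conftest import build_dataset


def test_modal_haplotype_tally(make_dataset):
    ds = build_dataset(
        [[14, 12, 23]] * 3 + [[14, 13, 23]] * 2 + [[15, 12, 25]],
        locus_names=["A", "B", "C"],
    )
    modal = modal_haplotype(ds)
    assert modal.as_tuple() == (14, 12, 23)
    assert not modal.tie_loci


def test_modal_haplotype_single_individual(make_dataset):
    ds = build_dataset([[14, 12, 23]], locus_names=["A", "B", "C"])
    modal = modal_haplotype(ds)
    assert modal.as_tuple() == (14, 12, 23) and not modal.tie_loci


def test_modal_haplotype_tie_rule(make_dataset):
    ds = build_dataset([[14], [14], [15], [15]], locus_names=["A"])
    modal = modal_haplotype(ds)
    assert modal.modes["A"] == 14  # smallest tied value
    assert modal.tie_loci == frozenset({"A"})
    assert modal.tie_alternatives["A"] == (14, 15)
    assert modal_haplotype(ds, tie_break="largest").modes["A"] == 15


@pytest.mark.parametrize(
    "hap,expected",
    [((14, 12, 23), 0), ((14, 12, 24), 1), ((15, 12, 25), 3)],
)
def test_mdm_distance(hap, expected, make_dataset):
    ds = build_dataset([[14, 12, 23]] * 2, locus_names=["A", "B", "C"])
    modal = modal_haplotype(ds)
    assert mdm_distance(hap, modal) == expected
    assert mdm_distance(dict(zip("ABC", hap)), modal) == expected


def test_mdm_distance_locus_mismatch(make_dataset):
    ds = build_dataset([[14, 12]], locus_names=["A", "B"])
    modal = modal_haplotype(ds)
    with pytest.raises(ValueError):
        mdm_distance((14,), modal)
    with pytest.raises(KeyError):
        mdm_distance({"A": 14, "X": 9}, modal)


def test_mdm_distribution_summaries(make_dataset):
    # single locus with offsets [0,0,0,1,1,3] from the mode 10
    ds = build_dataset(
        [[10], [10], [10], [11], [9], [13]], locus_names=["A"]
    )
    dist = mdm_distribution(ds)
    assert sorted(dist.distances.tolist()) == [0, 0, 0, 1, 1, 3]
    assert dist.histogram == {0: 3, 1: 2, 3: 1}
    assert dist.neighbor_proportion == pytest.approx(5 / 6)
    assert dist.gamma1 == pytest.approx(1.158, abs=1e-3)


def test_mdm_distribution_monomorphic(make_dataset):
    ds = build_dataset([[10]] * 4, locus_names=["A"])
    dist = mdm_distribution(ds)
    assert dist.histogram == {0: 4}
    assert dist.neighbor_proportion == 1.0
    assert np.isnan(dist.gamma1)  # zero variance


def test_mdm_distribution_symmetric_skew_zero(make_dataset):
    # modal haplotype (10, 10); distances 0, 1, 1, 2 symmetric around 1
    ds = build_dataset(
        [[10, 10], [10, 11], [9, 10], [10, 12]], locus_names=["A", "B"]
    )
    dist = mdm_distribution(ds)
    assert sorted(dist.distances.tolist()) == [0, 1, 1, 2]
    assert dist.gamma1 == pytest.approx(0.0, abs=1e-12)


def test_mdm_distribution_small_n_gamma_undefined(make_dataset):
    ds = build_dataset([[10], [11]], locus_names=["A"])
    dist = mdm_distribution(ds)
    assert dist.distances.size == 2 and np.isnan(dist.gamma1)


def test_neighbor_rule_option(make_dataset):
    ds = build_dataset([[10], [10], [11], [13]], locus_names=["A"])
    within = mdm_distribution(ds, neighbor_rule="within_one")
    exact = mdm_distribution(ds, neighbor_rule="exactly_one")
    assert within.neighbor_proportion == pytest.approx(3 / 4)
    assert exact.neighbor_proportion == pytest.approx(1 / 4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(*[st.integers(min_value=8, max_value=20)] * 3),
        min_size=1,
        max_size=12,
    ),
    st.tuples(*[st.integers(min_value=8, max_value=20)] * 3),
)
def test_mdm_distance_l1_triangle_inequality(haps, third):
    ds = build_dataset([list(h) for h in haps], locus_names=["A", "B", "C"])
    modal = modal_haplotype(ds)
    for h in haps:
        d_direct = mdm_distance(h, modal)
        d_via = sum(abs(a - b) for a, b in zip(h, third)) + mdm_distance(
            third, modal
        )
        assert d_direct <= d_via
        assert (d_direct == 0) == (tuple(h) == modal.as_tuple())


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(*[st.integers(min_value=8, max_value=16)] * 2),
        min_size=2,
        max_size=10,
    )
)
def test_adding_modal_copy_is_conservative(haps):
    """A new carrier of the modal haplotype never increases any distance
    and never decreases the neighbor proportion."""
    ds = build_dataset([list(h) for h in haps], locus_names=["A", "B"])
    before = mdm_distribution(ds)
    augmented = build_dataset(
        [list(h) for h in haps] + [list(before.modal.as_tuple())],
        locus_names=["A", "B"],
    )
    after = mdm_distribution(augmented)
    # the mode cannot move: the old modal value gains one vote at each locus
    assert after.modal.as_tuple() == before.modal.as_tuple()
    assert sorted(after.distances.tolist()) == sorted(
        before.distances.tolist() + [0]
    )
    assert after.neighbor_proportion >= before.neighbor_proportion - 1e-12


def test_two_point_symmetric_skewness_zero():
    assert sample_skewness([0, 0, 4, 4]) == pytest.approx(0.0, abs=1e-12)
    assert sample_skewness([1, 3, 1, 3, 1, 3]) == pytest.approx(0.0, abs=1e-12)


def test_strict_filter_boundaries(make_dataset):
    ds = build_dataset(
        [[14]] * 4,
        locus_names=["A"],
        hg_probability=[0.95, 0.623, 0.95, np.nan],
        hg_fitness=[60.0, 60.0, 50.0, 60.0],
    )
    with pytest.warns(UserWarning, match="lack haplogroup scores"):
        out = strict_filter(ds)
    assert out.df["sample_id"].tolist() == ["s001"]  # strict > on both scores


def test_strict_filter_custom_thresholds(make_dataset):
    ds = build_dataset(
        [[14]] * 2,
        locus_names=["A"],
        hg_probability=[0.8, 0.7],
        hg_fitness=[55.0, 80.0],
    )
    out = strict_filter(ds, p_min=0.75, f_min=50.0)
    assert out.n == 1


@pytest.mark.parametrize(
    "hist,peaks",
    [
        ({0: 5, 1: 1, 3: 4}, 2),
        ({0: 5, 1: 5, 2: 1}, 1),
        ({2: 4}, 1),
        ({0: 1, 1: 3, 2: 1}, 1),
        ({0: 3, 1: 1, 2: 3, 4: 2}, 3),
    ],
)
def test_count_histogram_peaks(hist, peaks):
    assert count_histogram_peaks(hist) == peaks


def test_compare_mdm_identical_strata(make_dataset):
    ds1 = build_dataset([[10], [11], [13]], populations="P1", locus_names=["A"])
    ds2 = build_dataset([[10], [11], [13]], populations="P2", locus_names=["A"])
    table = compare_mdm([mdm_distribution(ds1), mdm_distribution(ds2)])
    a, b = table.drop(columns="stratum").iloc[0], table.drop(columns="stratum").iloc[1]
    assert a.tolist() == b.tolist()


def test_compare_mdm_multimodality_flag(make_dataset):
    # distances {0:5, 1:1, 3:4} -> two local maxima
    multi = build_dataset(
        [[10]] * 5 + [[11]] + [[13]] * 4, populations="P1", locus_names=["A"]
    )
    flat = build_dataset(
        [[10], [11], [11], [12]], populations="P2", locus_names=["A"]
    )
    table = compare_mdm([mdm_distribution(multi), mdm_distribution(flat)])
    row = table.set_index("stratum").loc["P1"]
    assert bool(row["multimodal"]) and row["n_peaks"] == 2
    assert row["hist_mode"] == 0
    assert not bool(table.set_index("stratum").loc["P2", "multimodal"])
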