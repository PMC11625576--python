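"""Shared fixtures: programmatic construction of small haplotype datasets."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import pytest

from ystr_founder.io import HaplotypeDataset
from ystr_founder.loci import LocusDef, locus_def


def build_dataset(
    haplotypes: Sequence[Sequence[float]],
    *,
    populations: Sequence[str] | str = "pop1",
    haplogroups: Sequence[str | None] | str | None = None,
    locus_names: Sequence[str] | None = None,
    hg_probability: Sequence[float] | None = None,
    hg_fitness: Sequence[float] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> HaplotypeDataset:
    """Assemble a HaplotypeDataset from a list of repeat vectors."""
    n = len(haplotypes)
    l = len(haplotypes[0])
    if locus_names is None:
        locus_names = [f"L{j + 1}" for j in range(l)]
    if isinstance(populations, str):
        populations = [populations] * n
    if haplogroups is None or isinstance(haplogroups, str):
        haplogroups = [haplogroups] * n
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids)
            if sample_ids is not None
            else [f"s{i + 1:03d}" for i in range(n)],
            "population": list(populations),
            "haplogroup": list(haplogroups),
            "hg_probability": list(hg_probability)
            if hg_probability is not None
            else np.nan,
            "hg_fitness": list(hg_fitness)
            if hg_fitness is not None
            else np.nan,
        }
    )
    for j, name in enumerate(locus_names):
        df[name] = [float(h[j]) for h in haplotypes]
    return HaplotypeDataset(df, tuple(locus_def(nm) for nm in locus_names))


def dataset_with_class_sizes(
    class_sizes: Sequence[int], *, population: str = "pop1"
) -> HaplotypeDataset:
    """A single-locus dataset realising a given haplotype class-size multiset."""
    haps = []
    for cls, size in enumerate(class_sizes):
        haps.extend([[10 + cls]] * size)
    return build_dataset(haps, populations=population)


@pytest.fixture
def make_dataset():
    return build_dataset


@pytest.fixture
def make_class_dataset():
    return dataset_with_class_sizes


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
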