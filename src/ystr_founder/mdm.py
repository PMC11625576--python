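"""Mutational distance from the modal haplotype (MDM) histograms.

Under the stepwise mutation model every mutation shifts a repeat count by
one, so the L1 distance between two haplotypes counts mutational steps.
For each population x haplogroup stratum a *modal haplotype* is assembled
from the per-locus modes Mo_i; each individual's MDM is

    MDM = sum_i |Mo_i - x_i|

over the l analysis loci.  In a recently founded population most
chromosomes descend from a handful of related founders, so the MDM
histogram is compressed against zero and right-skewed; older populations
at mutation-drift equilibrium show broader, flatter histograms whose mode
sits away from zero.  Two summary statistics capture this: the proportion
of "neighbor haplotypes" (MDM <= 1, i.e. at most one mutational step from
the mode) and the moment skewness gamma1 = m3 / m2^(3/2).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import HaplotypeDataset

__all__ = [
    "ModalHaplotype",
    "MDMDistribution",
    "modal_haplotype",
    "mdm_distance",
    "mdm_distribution",
    "strict_filter",
    "compare_mdm",
    "sample_skewness",
    "count_histogram_peaks",
]


@dataclass(frozen=True)
class ModalHaplotype:
    """Locus-wise modal repeat counts for one stratum.

    ``tie_loci`` records loci where the mode was ambiguous;
    ``tie_alternatives`` lists every repeat count sharing the maximal
    frequency there, so users can audit tie sensitivity.
    """

    population: str | None
    haplogroup: str | None
    modes: dict[str, int]
    tie_loci: frozenset[str] = frozenset()
    tie_alternatives: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def l(self) -> int:
        """Number of loci contributing to the distance."""
        return len(self.modes)

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(self.modes.values())


def modal_haplotype(
    stratum: HaplotypeDataset,
    *,
    tie_break: str = "smallest",
) -> ModalHaplotype:
    """Per-locus mode of repeat counts within a stratum.

    Ties are resolved deterministically (default: smallest tied repeat
    count; ``tie_break="largest"`` for the other extreme) and recorded.
    """
    if stratum.n == 0:
        raise ValueError("empty stratum")
    if tie_break not in ("smallest", "largest"):
        raise ValueError("tie_break must be 'smallest' or 'largest'")
    x = stratum.repeat_matrix()
    pops = stratum.populations
    hgs = stratum.haplogroups
    modes: dict[str, int] = {}
    ties: set[str] = set()
    alternatives: dict[str, tuple[int, ...]] = {}
    for j, name in enumerate(stratum.locus_names):
        values, counts = np.unique(x[:, j], return_counts=True)
        top = values[counts == counts.max()]
        if len(top) > 1:
            ties.add(name)
            alternatives[name] = tuple(int(v) for v in np.sort(top))
        modes[name] = int(top.min() if tie_break == "smallest" else top.max())
    return ModalHaplotype(
        population=pops[0] if len(pops) == 1 else None,
        haplogroup=hgs[0] if len(hgs) == 1 else None,
        modes=modes,
        tie_loci=frozenset(ties),
        tie_alternatives=alternatives,
    )


def mdm_distance(
    haplotype: Mapping[str, int] | Sequence[int], modal: ModalHaplotype
) -> int:
    """Sum over loci of absolute repeat differences from the modal haplotype."""
    if isinstance(haplotype, Mapping):
        missing = [n for n in modal.modes if n not in haplotype]
        if missing:
            raise KeyError(f"haplotype lacks modal loci {missing}")
        values = [int(haplotype[n]) for n in modal.modes]
    else:
        values = [int(v) for v in haplotype]
        if len(values) != modal.l:
            raise ValueError(
                f"haplotype has {len(values)} loci, modal has {modal.l}"
            )
    return int(sum(abs(m - v) for m, v in zip(modal.modes.values(), values)))


def sample_skewness(values: Sequence[float] | np.ndarray) -> float:
    """Moment skewness g1 = m3 / m2^(3/2) with 1/n central moments.

    NaN for n < 3 or zero variance (the uncorrected moment-ratio
    convention of the classic R ``moments`` library; no small-sample bias
    correction).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        return float("nan")
    d = v - v.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        return float("nan")
    return float(np.mean(d**3) / m2**1.5)


@dataclass(frozen=True)
class MDMDistribution:
    """Per-individual MDM values for one stratum, with summaries."""

    population: str | None
    haplogroup: str | None
    distances: np.ndarray
    modal: ModalHaplotype
    neighbor_rule: str = "within_one"

    @property
    def n(self) -> int:
        return int(self.distances.size)

    @property
    def histogram(self) -> dict[int, int]:
        return dict(sorted(Counter(int(d) for d in self.distances).items()))

    @property
    def neighbor_proportion(self) -> float:
        """Fraction of individuals at most one step from the mode.

        ``neighbor_rule="within_one"`` (default) counts MDM <= 1, i.e.
        including carriers of the modal haplotype itself;
        ``"exactly_one"`` counts MDM == 1 only.
        """
        if self.neighbor_rule == "within_one":
            return float(np.mean(self.distances <= 1))
        return float(np.mean(self.distances == 1))

    @property
    def gamma1(self) -> float:
        return sample_skewness(self.distances)


def mdm_distribution(
    stratum: HaplotypeDataset,
    *,
    modal: ModalHaplotype | None = None,
    neighbor_rule: str = "within_one",
    tie_break: str = "smallest",
) -> MDMDistribution:
    """MDM values of every individual against the stratum's modal haplotype.

    A pre-computed ``modal`` may be supplied (e.g. to score one population
    against another's mode); by default the stratum's own mode is used.
    """
    if neighbor_rule not in ("within_one", "exactly_one"):
        raise ValueError("neighbor_rule must be 'within_one' or 'exactly_one'")
    if modal is None:
        modal = modal_haplotype(stratum, tie_break=tie_break)
    x = stratum.repeat_matrix()
    order = [stratum.locus_names.index(n) for n in modal.modes]
    mo = np.asarray(list(modal.modes.values()), dtype=np.int64)
    distances = np.abs(x[:, order] - mo).sum(axis=1)
    pops = stratum.populations
    hgs = stratum.haplogroups
    return MDMDistribution(
        population=pops[0] if len(pops) == 1 else None,
        haplogroup=hgs[0] if len(hgs) == 1 else None,
        distances=distances,
        modal=modal,
        neighbor_rule=neighbor_rule,
    )


def strict_filter(
    dataset: HaplotypeDataset,
    *,
    p_min: float = 0.90,
    f_min: float = 50.0,
) -> HaplotypeDataset:
    """Retain records whose haplogroup call is confident.

    Keeps records with classifier probability strictly above ``p_min``
    AND fitness strictly above ``f_min``; records lacking either score are
    excluded with a warning.  Used to test whether multimodal MDM
    histograms are genuine within-haplogroup structure or classification
    error.
    """
    prob = dataset.df["hg_probability"]
    fit = dataset.df["hg_fitness"]
    missing = prob.isna() | fit.isna()
    if missing.any():
        warnings.warn(
            f"strict_filter: {int(missing.sum())} record(s) lack haplogroup "
            "scores and were excluded",
            stacklevel=2,
        )
    keep = (~missing) & (prob > p_min) & (fit > f_min)
    return HaplotypeDataset(
        dataset.df.loc[keep].reset_index(drop=True), dataset.loci
    )


def count_histogram_peaks(histogram: Mapping[int, int]) -> int:
    """Number of local maxima in a distance histogram.

    Bins are laid out contiguously from 0 to the largest observed
    distance (absent bins count zero).  A plateau of equal counts is one
    peak; two peaks must be separated by at least one strictly lower (or
    empty) bin.
    """
    if not histogram:
        return 0
    dmax = max(histogram)
    counts = np.zeros(dmax + 1, dtype=np.int64)
    for d, c in histogram.items():
        counts[d] = c
    peaks = 0
    rising = True  # before the first bin we are "rising"
    for i in range(len(counts)):
        nxt = counts[i + 1] if i + 1 < len(counts) else -1
        if counts[i] == nxt:
            continue  # plateau: defer to its right edge
        if rising and nxt < counts[i] and counts[i] > 0:
            peaks += 1
        rising = nxt > counts[i]
    return peaks


def compare_mdm(distributions: Sequence[MDMDistribution]) -> pd.DataFrame:
    """Aligned comparison table across strata.

    One row per distribution: n, neighbor_proportion, gamma1, the
    histogram's modal distance (location of its maximum, smallest on
    ties), a multimodality flag, and aligned histogram columns d0..dmax.
    """
    if len(distributions) < 2:
        raise ValueError("compare_mdm needs at least two distributions")
    dmax = max(max(d.histogram) for d in distributions)
    rows = []
    for dist in distributions:
        hist = dist.histogram
        counts = [hist.get(d, 0) for d in range(dmax + 1)]
        hist_mode = int(np.argmax(counts))  # argmax takes smallest on ties
        n_peaks = count_histogram_peaks(hist)
        label = "/".join(
            s for s in (dist.population, dist.haplogroup) if s is not None
        ) or "stratum"
        rows.append(
            [label, dist.n, dist.neighbor_proportion, dist.gamma1,
             hist_mode, n_peaks, n_peaks >= 2, *counts]
        )
    return pd.DataFrame(
        rows,
        columns=[
            "stratum", "n", "neighbor_proportion", "gamma1",
            "hist_mode", "n_peaks", "multimodal",
            *[f"d{d}" for d in range(dmax + 1)],
        ],
    )


def plot_mdm_histogram(distribution: MDMDistribution, ax=None):
    """Bar plot of an MDM histogram (matplotlib Axes returned)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    hist = distribution.histogram
    dmax = max(hist) if hist else 0
    xs = list(range(dmax + 1))
    ax.bar(xs, [hist.get(d, 0) for d in xs], color="#4878a8")
    label = "/".join(
        s
        for s in (distribution.population, distribution.haplogroup)
        if s is not None
    )
    ax.set_xlabel("mutational distance from modal haplotype")
    ax.set_ylabel("individuals")
    ax.set_title(
        f"{label}  (neighbors {100 * distribution.neighbor_proportion:.0f}%, "
        f"$\\gamma_1$={distribution.gamma1:.2f})"
    )
    ax.set_xticks(xs)
    return ax
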