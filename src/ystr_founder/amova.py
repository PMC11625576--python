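"""One-level AMOVA on haplotype distance matrices (Phi_PT).

The analysis of molecular variance partitions squared pairwise distances
into among-population and within-population components.  With squared
distances d2 and N individuals in P populations of sizes n_p:

    SS_total  = sum_{i<j} d2_ij / N
    SS_within = sum_p sum_{i<j in p} d2_ij / n_p
    SS_among  = SS_total - SS_within

    MS_among = SS_among / (P - 1),  MS_within = SS_within / (N - P)
    n0 = (N - sum_p n_p^2 / N) / (P - 1)
    sigma2_among = (MS_among - MS_within) / n0,  sigma2_within = MS_within

    Phi_PT = sigma2_among / (sigma2_among + sigma2_within)

Phi_PT is the fraction of molecular variance attributable to population
membership; negative estimates are truncated to zero.  Significance is
assessed by permuting population labels across individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import DistanceMatrix

__all__ = ["AMOVAResult", "amova_phi_pt", "permutation_test"]


@dataclass(frozen=True)
class AMOVAResult:
    """Phi_PT point estimate with variance components and optional p-value."""

    phi_pt: float
    sigma_among: float
    sigma_within: float
    p_value: float | None = None
    n_permutations: int = 0
    n_populations: int = 0
    n_individuals: int = 0

    @property
    def within_fraction(self) -> float:
        """1 − Phi_PT: the within-population share of molecular variance."""
        return 1.0 - self.phi_pt


def _prepare(
    d: DistanceMatrix | np.ndarray, populations: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    dm = d.d if isinstance(d, DistanceMatrix) else np.asarray(d)
    labels = np.asarray(list(populations))
    if len(labels) != dm.shape[0]:
        raise ValueError("label vector length does not match distance matrix")
    # populations of one individual contribute no within-group pairs and
    # break the df bookkeeping; drop them with a warning
    values, counts = np.unique(labels, return_counts=True)
    singletons = values[counts < 2]
    if singletons.size:
        warnings.warn(
            f"AMOVA: excluding single-individual population(s) "
            f"{singletons.tolist()}",
            stacklevel=3,
        )
        keep = ~np.isin(labels, singletons)
        dm = dm[np.ix_(keep, keep)]
        labels = labels[keep]
    if np.unique(labels).size < 2:
        raise ValueError("AMOVA requires at least 2 populations with >= 2 members")
    return dm.astype(float), labels


def _phi_components(
    d2: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """(phi_raw, sigma_among, sigma_within) from a squared-distance matrix.

    phi_raw is *untruncated* (can be negative); reporting truncates at
    zero, but permutation comparisons must use the raw statistic — an
    atom at zero would make the test conservative under the null.
    """
    n_total = d2.shape[0]
    values, counts = np.unique(labels, return_counts=True)
    n_pops = values.size
    ss_total = d2.sum() / (2.0 * n_total)
    ss_within = 0.0
    for pop, n_p in zip(values, counts):
        idx = np.flatnonzero(labels == pop)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * n_p)
    ss_among = ss_total - ss_within
    ms_among = ss_among / (n_pops - 1)
    ms_within = ss_within / (n_total - n_pops)
    n0 = (n_total - (counts**2).sum() / n_total) / (n_pops - 1)
    sigma_among = (ms_among - ms_within) / n0
    sigma_within = ms_within
    denom = sigma_among + sigma_within
    phi = 0.0 if denom == 0 else sigma_among / denom
    return float(phi), float(sigma_among), float(sigma_within)


def amova_phi_pt(
    d: DistanceMatrix | np.ndarray,
    populations: Sequence[str],
    *,
    squared: bool = True,
) -> AMOVAResult:
    """Point estimate of Phi_PT from a distance matrix and labels.

    ``squared=True`` (default) squares the supplied distances before the
    sums-of-squares decomposition, the standard treatment when the input
    is a metric distance (e.g. Hamming) rather than already-squared.
    """
    dm, labels = _prepare(d, populations)
    d2 = dm**2 if squared else dm
    phi, s_a, s_w = _phi_components(d2, labels)
    return AMOVAResult(
        phi_pt=max(0.0, phi),
        sigma_among=s_a,
        sigma_within=s_w,
        n_populations=int(np.unique(labels).size),
        n_individuals=int(labels.size),
    )


def permutation_test(
    d: DistanceMatrix | np.ndarray,
    populations: Sequence[str],
    *,
    n_perm: int = 99,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    squared: bool = True,
) -> AMOVAResult:
    """Phi_PT with a label-permutation p-value.

    Population labels are permuted across individuals ``n_perm`` times;
    p = (1 + #{permuted Phi >= observed}) / (1 + n_perm), so 99
    permutations give a minimum attainable p of 0.01.  The comparison is
    on the untruncated statistic (truncating at zero first would pile
    permuted values onto the observed one and bias p upward under the
    null).  The permutation stream is fixed by ``seed`` (or a supplied
    Generator).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    dm, labels = _prepare(d, populations)
    d2 = dm**2 if squared else dm
    obs_phi, s_a, s_w = _phi_components(d2, labels)
    if rng is None:
        rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        phi_perm, _, _ = _phi_components(d2, perm)
        if phi_perm >= obs_phi:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return AMOVAResult(
        phi_pt=max(0.0, obs_phi),
        sigma_among=s_a,
        sigma_within=s_w,
        p_value=float(p),
        n_permutations=n_perm,
        n_populations=int(np.unique(labels).size),
        n_individuals=int(labels.size),
    )
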