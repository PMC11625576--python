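"""Forward-time haploid simulator of Y-STR haplotypes under the SMM.

The model: Y chromosomes are transmitted father-to-son without
recombination, so the male population is a haploid Wright–Fisher system.
Each locus mutates independently each generation with its own probability
mu; a mutation moves the repeat count by +-1 with equal probability
(single-step stepwise mutation model), reflecting at the locus's allele
bounds.

A *source* population of constant effective male size is equilibrated by
a long burn-in; an *island* population is then founded by a small number
of males sampled from a source (optionally from even fewer patrilines,
i.e. duplicated founder haplotypes) and grown along a census trajectory
for a chosen number of generations, with optional per-generation
admixture from its source.  The output is a standard haplotype table, so
every analysis in this package (diversity, MDM, networks, AMOVA) can be
exercised against scenarios with known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import HaplotypeDataset, write_table
from .loci import DEFAULT_PANEL, LocusDef

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "mutate_haplotypes",
    "simulate_source",
    "found_island",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario parameters for source-vs-island simulations.

    Defaults describe a North-Atlantic-style settlement scenario: an
    island founded by a handful of males ~57 generations ago (about
    1,700 years at 30 years per generation) growing to an effective male
    size of 1,600 (a census of ~3,200 halved, counting only reproducing
    males), drawing founders from mainland source pools of effective male
    size 500 equilibrated for 1,000 generations.
    """

    loci: tuple[LocusDef, ...] = DEFAULT_PANEL
    source_ne: int = 500
    burn_in: int = 1000
    n_source_pops: int = 2
    n_islands: int = 1
    n_founders: int = 5
    n_patrilines: int | None = None
    generations_since_founding: int = 57
    island_ne: int = 1600
    growth: str | tuple[int, ...] = "exponential"
    migration: float = 0.0
    sample_size: int = 50
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.source_ne < 2 or self.island_ne < 1:
            raise ValueError("population sizes must be positive (source >= 2)")
        if self.burn_in < 0 or self.generations_since_founding < 0:
            raise ValueError("generation counts must be non-negative")
        if not (0.0 <= self.migration <= 1.0):
            raise ValueError("migration must be a fraction in [0, 1]")
        if self.n_founders < 1 or self.n_founders > self.source_ne:
            raise ValueError("n_founders must be in [1, source_ne]")
        if self.n_patrilines is not None and not (
            1 <= self.n_patrilines <= self.n_founders
        ):
            raise ValueError("n_patrilines must be in [1, n_founders]")

    def trajectory(self) -> np.ndarray:
        """Island census sizes for generations 1..G after founding.

        ``growth="exponential"`` interpolates geometrically from the
        founder count to ``island_ne``; an explicit tuple of sizes is
        used verbatim (must cover every generation).
        """
        g = self.generations_since_founding
        if isinstance(self.growth, str):
            if self.growth != "exponential":
                raise ValueError(f"unknown growth spec {self.growth!r}")
            if g == 0:
                return np.empty(0, dtype=np.int64)
            t = np.arange(1, g + 1)
            sizes = self.n_founders * (self.island_ne / self.n_founders) ** (t / g)
            return np.maximum(1, np.rint(sizes)).astype(np.int64)
        sizes = np.asarray(self.growth, dtype=np.int64)
        if sizes.size < g:
            raise ValueError(
                f"growth trajectory has {sizes.size} entries but "
                f"{g} generations are simulated"
            )
        if (sizes < 1).any():
            raise ValueError("trajectory sizes must be >= 1")
        return sizes[:g]


def _locus_arrays(
    loci: Sequence[LocusDef],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mus = np.asarray([ld.mu for ld in loci])
    mins = np.asarray([ld.min_repeat for ld in loci], dtype=np.int64)
    maxs = np.asarray([ld.max_repeat for ld in loci], dtype=np.int64)
    return mus, mins, maxs


def mutate_haplotypes(
    x: np.ndarray,
    loci: Sequence[LocusDef],
    rng: np.random.Generator,
    *,
    boundary: str = "reflect",
) -> np.ndarray:
    """One generation of stepwise mutation applied to an (n, l) repeat matrix.

    Each cell mutates independently with its locus's probability mu; a
    mutation is a +-1 step with equal sign probability.  Steps that would
    leave the locus's allele bounds are reflected back inside
    (``boundary="reflect"``) or suppressed (``boundary="hold"``).
    """
    if boundary not in ("reflect", "hold"):
        raise ValueError("boundary must be 'reflect' or 'hold'")
    mus, mins, maxs = _locus_arrays(loci)
    x = np.asarray(x, dtype=np.int64)
    hit = rng.random(x.shape) < mus
    steps = np.where(rng.random(x.shape) < 0.5, -1, 1) * hit
    out = x + steps
    if boundary == "reflect":
        below = out < mins
        out = np.where(below, 2 * mins - out, out)
        above = out > maxs
        out = np.where(above, 2 * maxs - out, out)
    else:
        out = np.clip(out, mins, maxs)
    return out


def _start_haplotype(loci: Sequence[LocusDef]) -> np.ndarray:
    """Ancestral haplotype: each locus at the middle of its allele range."""
    return np.asarray(
        [(ld.min_repeat + ld.max_repeat) // 2 for ld in loci], dtype=np.int64
    )


def _wf_generation(
    x: np.ndarray,
    next_size: int,
    loci: Sequence[LocusDef],
    rng: np.random.Generator,
) -> np.ndarray:
    parents = rng.integers(0, x.shape[0], size=next_size)
    return mutate_haplotypes(x[parents], loci, rng)


def simulate_source(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Equilibrate one source population; returns its (Ne, l) repeat matrix.

    Starts from a uniform ancestral haplotype and runs ``burn_in``
    Wright–Fisher generations with mutation.  With ``burn_in=0`` the
    population is monomorphic.
    """
    x = np.tile(_start_haplotype(config.loci), (config.source_ne, 1))
    for _ in range(config.burn_in):
        x = _wf_generation(x, config.source_ne, config.loci, rng)
    return x


def found_island(
    source: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    source_trajectory: Sequence[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Found and grow an island from a source population.

    ``n_founders`` haplotypes are drawn without replacement from the
    source (restricted to ``n_patrilines`` distinct paternal lineages if
    configured), then the island follows the growth trajectory with
    mutation for ``generations_since_founding`` generations.  When
    ``migration > 0`` and concurrent source states are supplied, a
    binomial number of island slots is replaced by source migrants each
    generation.

    Returns ``(island, founders)`` repeat matrices.
    """
    idx = rng.choice(source.shape[0], size=config.n_founders, replace=False)
    founders = source[idx].copy()
    if config.n_patrilines is not None and config.n_patrilines < config.n_founders:
        lineages = founders[: config.n_patrilines]
        founders = lineages[
            rng.integers(0, config.n_patrilines, size=config.n_founders)
        ]
    x = founders.copy()
    sizes = config.trajectory()
    for t, size in enumerate(sizes):
        x = _wf_generation(x, int(size), config.loci, rng)
        if config.migration > 0 and source_trajectory is not None:
            n_mig = rng.binomial(x.shape[0], config.migration)
            if n_mig:
                pool = source_trajectory[t]
                slots = rng.choice(x.shape[0], size=n_mig, replace=False)
                x[slots] = pool[rng.integers(0, pool.shape[0], size=n_mig)]
    return x, founders


@dataclass
class SimulatedDataset:
    """A simulated haplotype table plus its ground truth."""

    dataset: HaplotypeDataset
    truth: dict

    def write(self, table_path: str | Path, truth_path: str | Path | None = None):
        write_table(self.dataset, table_path)
        if truth_path is not None:
            Path(truth_path).write_text(json.dumps(self.truth, indent=2) + "\n")


def generate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> SimulatedDataset:
    """Simulate sources and islands and sample a haplotype table.

    Island ``i`` is founded from source ``i mod n_source_pops``; sources
    keep evolving during the island phase (so migrants, when enabled,
    come from contemporaneous source generations).  ``sample_size``
    individuals per population are drawn without replacement (or the
    whole population when smaller).  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    loci = config.loci

    sources = [simulate_source(config, rng) for _ in range(config.n_source_pops)]

    # Continue source evolution through the island phase, recording states.
    g = config.generations_since_founding
    source_states: list[list[np.ndarray]] = [[] for _ in sources]
    founders_at = [s.copy() for s in sources]
    current = [s.copy() for s in sources]
    for _ in range(g):
        for k in range(len(current)):
            current[k] = _wf_generation(
                current[k], config.source_ne, loci, rng
            )
            source_states[k].append(current[k])

    islands = []
    founders_list = []
    for m in range(config.n_islands):
        k = m % config.n_source_pops
        island, founders = found_island(
            founders_at[k],
            config,
            rng,
            source_trajectory=source_states[k] if config.migration > 0 else None,
        )
        islands.append(island)
        founders_list.append(founders)

    frames = []
    truth_founders = {}
    for name, pop in [
        *[(f"source_{k + 1}", current[k]) for k in range(len(current))],
        *[(f"island_{m + 1}", islands[m]) for m in range(len(islands))],
    ]:
        n_take = min(config.sample_size, pop.shape[0])
        take = rng.choice(pop.shape[0], size=n_take, replace=False)
        block = pop[np.sort(take)]
        df = pd.DataFrame(block, columns=[ld.name for ld in loci], dtype=float)
        df.insert(0, "sample_id", [f"{name}_{i + 1:04d}" for i in range(n_take)])
        df.insert(1, "population", name)
        df.insert(2, "haplogroup", None)
        df.insert(3, "hg_probability", np.nan)
        df.insert(4, "hg_fitness", np.nan)
        frames.append(df)
    for m, founders in enumerate(founders_list):
        truth_founders[f"island_{m + 1}"] = founders.tolist()

    table = pd.concat(frames, ignore_index=True)
    dataset = HaplotypeDataset(table, loci)
    truth = {
        "seed": config.seed if seed is None else seed,
        "n_founders": config.n_founders,
        "n_patrilines": config.n_patrilines,
        "generations_since_founding": config.generations_since_founding,
        "founder_haplotypes": truth_founders,
        "config": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("loci",)
        },
        "loci": [ld.name for ld in loci],
    }
    return SimulatedDataset(dataset=dataset, truth=truth)
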