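"""End-to-end workflow: filter -> stratify -> diversity -> MDM -> network -> AMOVA.

`run_pipeline` wires the library modules into the standard analysis of a
multi-population Y-STR table and writes a reproducible output bundle:
diversity tables (overall and within-haplogroup), per-stratum MDM
histograms and summaries, GraphML networks, AMOVA results, and a JSON log
recording versions, seed, configuration and exclusion counts.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amova import permutation_test
from .diversity import diversity_table
from .io import (
    HaplotypeDataset,
    derive_dys389b,
    filter_discrete,
    normalize_dys385,
    read_table,
    select_loci,
)
from .loci import CORE_LOCI
from .mdm import compare_mdm, mdm_distribution, strict_filter
from .network import build_msn, pairwise_distances, write_graphml

__all__ = ["RunConfig", "run_pipeline"]

#: Haplogroups analysed by default when stratifying (the three major
#: European Y lineages); strata need >= MIN_STRATUM individuals per
#: population to enter stratified analyses.
DEFAULT_HAPLOGROUPS = ("R1a", "R1b", "I1")
MIN_STRATUM = 2


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    input_path: str
    out_dir: str
    delimiter: str | None = None
    column_map: dict | None = None
    loci: tuple[str, ...] | None = None  # None -> intersect with CORE_LOCI
    by_haplogroup: bool = True
    haplogroups: tuple[str, ...] | None = None  # None -> DEFAULT_HAPLOGROUPS
    metric: str = "hamming"
    strict: bool = False
    p_min: float = 0.90
    f_min: float = 50.0
    n_permutations: int = 99
    seed: int = 0
    overwrite: bool = False


def _prepare(config: RunConfig) -> tuple[HaplotypeDataset, dict]:
    ds = read_table(
        config.input_path,
        delimiter=config.delimiter,
        column_map=config.column_map,
    )
    n_raw = ds.n
    names = set(ds.locus_names)
    if {"DYS389I", "DYS389II"} <= names:
        ds = derive_dys389b(ds)
    if {"DYS385a", "DYS385b"} <= set(ds.locus_names):
        ds = normalize_dys385(ds)
    if config.loci is not None:
        ds = select_loci(ds, list(config.loci))
    else:
        core = [n for n in CORE_LOCI if n in ds.locus_names]
        if core:
            ds = select_loci(ds, core)
    ds, report = filter_discrete(ds)
    info = {
        "n_input": n_raw,
        "n_retained": ds.n,
        "n_excluded_non_discrete": n_raw - ds.n,
        "loci": list(ds.locus_names),
    }
    if config.strict:
        before = ds.n
        ds = strict_filter(ds, p_min=config.p_min, f_min=config.f_min)
        info["n_excluded_strict"] = before - ds.n
    return ds, info


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns a manifest of written artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    existing = [p.name for p in out.iterdir()] if out.exists() else []
    if existing and not config.overwrite:
        raise FileExistsError(
            f"{out} is not empty; pass overwrite=True (--force) to proceed"
        )

    manifest: dict = {"outputs": []}
    try:
        ds, info = _prepare(config)
    except Exception as exc:  # stage-named failure
        raise RuntimeError(f"pipeline stage 'prepare' failed: {exc}") from exc

    def _save_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"].append(str(path))

    # --- diversity ------------------------------------------------------
    try:
        _save_df(diversity_table(ds, include_total=True), "diversity_overall.tsv")
        if config.by_haplogroup and ds.haplogroups:
            hgs = [
                h
                for h in (config.haplogroups or DEFAULT_HAPLOGROUPS)
                if h in ds.haplogroups
            ]
            if hgs:
                sub = ds.subset(haplogroup=hgs)
                _save_df(
                    diversity_table(sub, by_haplogroup=True),
                    "diversity_by_haplogroup.tsv",
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'diversity' failed: {exc}") from exc

    # --- stratified MDM / network / AMOVA -------------------------------
    if config.by_haplogroup and ds.haplogroups:
        strata_groups = [
            h
            for h in (config.haplogroups or DEFAULT_HAPLOGROUPS)
            if h in ds.haplogroups
        ]
    else:
        strata_groups = [None]

    mdm_summaries = []
    for hg in strata_groups:
        tag = hg if hg is not None else "all"
        sub = ds.subset(haplogroup=hg) if hg is not None else ds
        dists = []
        for pop in sub.populations:
            stratum = sub.subset(population=pop)
            if stratum.n < MIN_STRATUM:
                continue
            dists.append(mdm_distribution(stratum))
        if len(dists) >= 2:
            try:
                table = compare_mdm(dists)
                table.insert(0, "haplogroup", tag)
                _save_df(table, f"mdm_{tag}.tsv")
                mdm_summaries.append(table)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage 'mdm' failed for {tag}: {exc}"
                ) from exc
        if sub.n >= 2 and len(set(sub.haplotypes())) >= 1:
            try:
                msn = build_msn(sub, metric=config.metric)
                gpath = out / f"network_{tag}.graphml"
                write_graphml(msn, gpath)
                manifest["outputs"].append(str(gpath))
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage 'network' failed for {tag}: {exc}"
                ) from exc
        pops_ok = [
            p for p in sub.populations if sub.subset(population=p).n >= 2
        ]
        if len(pops_ok) >= 2:
            try:
                d = pairwise_distances(sub, metric=config.metric)
                res = permutation_test(
                    d,
                    sub.df["population"].tolist(),
                    n_perm=config.n_permutations,
                    seed=config.seed,
                )
                apath = out / f"amova_{tag}.json"
                apath.write_text(
                    json.dumps(
                        {
                            "haplogroup": tag,
                            "phi_pt": res.phi_pt,
                            "within_fraction": res.within_fraction,
                            "p_value": res.p_value,
                            "n_permutations": res.n_permutations,
                            "n_individuals": res.n_individuals,
                            "n_populations": res.n_populations,
                        },
                        indent=2,
                    )
                    + "\n"
                )
                manifest["outputs"].append(str(apath))
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage 'amova' failed for {tag}: {exc}"
                ) from exc

    log = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "exclusions": info,
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2) + "\n")
    manifest["outputs"].append(str(log_path))
    manifest["log"] = log
    return manifest
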