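"""Reading, validating, normalising and writing Y-STR haplotype tables.

Input is a wide table (CSV/TSV), one row per sampled male: a sample
identifier, a population label, an optional haplogroup label with its
classifier probability/fitness scores, and one integer repeat-count column
per locus.  Three conventions common to published Y-STR datasets are
implemented as explicit, idempotent normalisation steps:

* ``derive_dys389b`` — DYS389II is read as a composite; the DYS389b repeat
  block is obtained by subtracting DYS389I from DYS389II.
* ``normalize_dys385`` — DYS385 is duplicated on the Y; within each
  individual the shorter allele is assigned to DYS385a, the longer to
  DYS385b.
* ``filter_discrete`` — intermediate (non-integer, e.g. "13.2") or missing
  alleles are excluded, never rounded, and reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .loci import LocusDef, locus_def

#: Canonical non-locus columns, in output order.
META_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "population",
    "haplogroup",
    "hg_probability",
    "hg_fitness",
)


class HaplotypeFormatError(ValueError):
    """The file as a whole cannot be interpreted as a haplotype table."""


class HaplotypeParseError(ValueError):
    """Individual cells could not be parsed; carries a per-cell report."""

    def __init__(self, message: str, cells: list[tuple[str, str, object]]):
        super().__init__(message)
        self.cells = cells


class EmptyDatasetError(ValueError):
    """An operation removed every record."""


@dataclass
class HaplotypeDataset:
    """Individuals x loci repeat-count table with population annotations.

    ``df`` holds one row per individual with the ``META_COLUMNS`` followed
    by one float column per locus (floats so that missing and intermediate
    alleles survive loading; ``filter_discrete`` narrows to integers).
    ``loci`` is the shared, ordered locus panel.
    """

    df: pd.DataFrame
    loci: tuple[LocusDef, ...]

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        missing = [ld.name for ld in self.loci if ld.name not in self.df.columns]
        if missing:
            raise HaplotypeFormatError(f"locus columns absent from table: {missing}")

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(ld.name for ld in self.loci)

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.df["population"]))

    @property
    def haplogroups(self) -> list[str]:
        hg = self.df["haplogroup"].dropna()
        return list(pd.unique(hg))

    def repeat_matrix(self) -> np.ndarray:
        """The (n, l) integer repeat-count matrix.

        Raises if any value is missing or non-discrete; run
        ``filter_discrete`` first on raw data.
        """
        block = self.df.loc[:, list(self.locus_names)].to_numpy(dtype=float)
        if np.isnan(block).any() or not np.all(block == np.floor(block)):
            raise ValueError(
                "dataset contains missing or non-discrete alleles; "
                "apply filter_discrete() first"
            )
        return block.astype(np.int64)

    def haplotypes(self) -> list[tuple[int, ...]]:
        """Per-individual repeat vectors as hashable tuples."""
        return [tuple(row) for row in self.repeat_matrix()]

    # -- subsetting --------------------------------------------------------

    def subset(
        self,
        population: str | Sequence[str] | None = None,
        haplogroup: str | Sequence[str] | None = None,
    ) -> "HaplotypeDataset":
        mask = pd.Series(True, index=self.df.index)
        if population is not None:
            pops = [population] if isinstance(population, str) else list(population)
            mask &= self.df["population"].isin(pops)
        if haplogroup is not None:
            hgs = [haplogroup] if isinstance(haplogroup, str) else list(haplogroup)
            mask &= self.df["haplogroup"].isin(hgs)
        return HaplotypeDataset(self.df.loc[mask].reset_index(drop=True), self.loci)

    def strata(
        self, by_haplogroup: bool = False
    ) -> Iterator[tuple[tuple[str, str | None], "HaplotypeDataset"]]:
        """Yield ((population, haplogroup), subset) in first-seen order.

        Without haplogroup stratification the second key element is None.
        Records lacking a haplogroup label are omitted from stratified
        iteration only.
        """
        for pop in self.populations:
            pop_ds = self.subset(population=pop)
            if not by_haplogroup:
                yield (pop, None), pop_ds
                continue
            for hg in pop_ds.haplogroups:
                yield (pop, hg), pop_ds.subset(haplogroup=hg)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def read_table(
    path: str | Path,
    *,
    delimiter: str | None = None,
    column_map: Mapping[str, str] | None = None,
    locus_columns: Sequence[str] | None = None,
) -> HaplotypeDataset:
    """Read a wide haplotype table from CSV/TSV.

    Rows are retained verbatim — no filtering or normalisation is applied;
    missing and intermediate alleles survive as NaN / fractional values.

    Parameters
    ----------
    delimiter:
        Field separator; sniffed when omitted.
    column_map:
        Mapping from file column names to canonical names (the
        ``META_COLUMNS`` and locus names), for sources with differing
        headers.
    locus_columns:
        Explicit list of locus columns; by default every non-meta column
        is treated as a locus.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import csv

    try:
        if delimiter is None:
            raw = pd.read_csv(path, sep=None, engine="python", dtype=object)
        else:
            raw = pd.read_csv(path, sep=delimiter, dtype=object)
    except (pd.errors.EmptyDataError, csv.Error):
        # sep sniffing fails on empty/headerless input
        raise HaplotypeFormatError(f"{path}: empty or unrecognisable file") from None
    if column_map:
        raw = raw.rename(columns=dict(column_map))

    if locus_columns is None:
        locus_names = [c for c in raw.columns if c not in META_COLUMNS]
    else:
        locus_names = list(locus_columns)
        absent = [c for c in locus_names if c not in raw.columns]
        if absent:
            raise HaplotypeFormatError(f"{path}: missing locus columns {absent}")
    for mandatory in ("sample_id", "population"):
        if mandatory not in raw.columns:
            raise HaplotypeFormatError(
                f"{path}: missing mandatory column '{mandatory}' "
                "(use column_map to rename)"
            )
    if not locus_names:
        raise HaplotypeFormatError(f"{path}: no locus columns found")

    df = pd.DataFrame()
    df["sample_id"] = raw["sample_id"].astype(str)
    df["population"] = raw["population"].astype(str)
    df["haplogroup"] = (
        raw["haplogroup"].where(raw["haplogroup"].notna(), None)
        if "haplogroup" in raw.columns
        else None
    )
    for score in ("hg_probability", "hg_fitness"):
        df[score] = (
            pd.to_numeric(raw[score], errors="coerce")
            if score in raw.columns
            else np.nan
        )

    bad_cells: list[tuple[str, str, object]] = []
    for name in locus_names:
        col = pd.to_numeric(raw[name], errors="coerce")
        newly_bad = col.isna() & raw[name].notna()
        for i in np.flatnonzero(newly_bad.to_numpy()):
            bad_cells.append((str(raw["sample_id"].iloc[i]), name, raw[name].iloc[i]))
        df[name] = col.astype(float)
    if bad_cells:
        shown = ", ".join(f"{s}:{l}={v!r}" for s, l, v in bad_cells[:10])
        raise HaplotypeParseError(
            f"{path}: unparseable allele values ({shown}"
            + (", ..." if len(bad_cells) > 10 else "")
            + ")",
            bad_cells,
        )
    if (df["population"].str.len() == 0).any():
        raise HaplotypeFormatError(f"{path}: empty population labels")

    loci = tuple(locus_def(name) for name in locus_names)
    return HaplotypeDataset(df.reset_index(drop=True), loci)


def write_table(
    dataset: HaplotypeDataset, path: str | Path, *, delimiter: str = ","
) -> None:
    """Write a dataset back to CSV/TSV (round-trips with ``read_table``)."""
    out = dataset.df.copy()
    for name in dataset.locus_names:
        col = out[name]
        out[name] = [
            ""
            if pd.isna(v)
            else (str(int(v)) if float(v) == int(v) else repr(float(v)))
            for v in col
        ]
    cols = [c for c in META_COLUMNS if c in out.columns] + list(dataset.locus_names)
    out.loc[:, cols].to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Normalisation / filtering
# ---------------------------------------------------------------------------


def derive_dys389b(
    dataset: HaplotypeDataset, *, keep_dys389ii: bool = False
) -> HaplotypeDataset:
    """Add DYS389b = DYS389II − DYS389I.

    DYS389II is a composite amplicon that contains the DYS389I repeat
    block, so the difference isolates the distal block.  A negative
    difference is biologically impossible and raises; a zero difference is
    retained with a warning.  Idempotent: if DYS389b is already present
    and DYS389II absent, the dataset is returned unchanged.
    """
    names = dataset.locus_names
    if "DYS389b" in names and "DYS389II" not in names:
        return dataset
    if "DYS389I" not in names or "DYS389II" not in names:
        raise HaplotypeFormatError(
            "derive_dys389b requires DYS389I and DYS389II columns"
        )
    df = dataset.df.copy()
    diff = df["DYS389II"] - df["DYS389I"]
    bad = diff < 0
    if bad.any():
        offenders = df.loc[bad, "sample_id"].tolist()
        raise ValueError(
            f"DYS389II < DYS389I (impossible composite) for samples {offenders}"
        )
    zero = diff == 0
    if zero.any():
        warnings.warn(
            "DYS389b is zero for samples "
            f"{df.loc[zero, 'sample_id'].tolist()} (empty distal repeat block)",
            stacklevel=2,
        )
    df["DYS389b"] = diff

    new_loci: list[LocusDef] = []
    for ld in dataset.loci:
        if ld.name == "DYS389II" and not keep_dys389ii:
            continue
        new_loci.append(ld)
    if "DYS389b" not in {ld.name for ld in new_loci}:
        # place DYS389b right after DYS389I
        idx = [ld.name for ld in new_loci].index("DYS389I") + 1
        new_loci.insert(idx, locus_def("DYS389b"))
    if not keep_dys389ii:
        df = df.drop(columns=["DYS389II"])
    return HaplotypeDataset(df, tuple(new_loci))


def normalize_dys385(dataset: HaplotypeDataset) -> HaplotypeDataset:
    """Order the duplicated DYS385 locus: shorter allele to DYS385a.

    Idempotent; equal alleles are left untouched.
    """
    names = dataset.locus_names
    if "DYS385a" not in names or "DYS385b" not in names:
        raise HaplotypeFormatError(
            "normalize_dys385 requires DYS385a and DYS385b columns"
        )
    df = dataset.df.copy()
    a = df["DYS385a"].to_numpy(dtype=float)
    b = df["DYS385b"].to_numpy(dtype=float)
    both = ~(np.isnan(a) | np.isnan(b))
    lo = np.where(both, np.minimum(a, b), a)
    hi = np.where(both, np.maximum(a, b), b)
    df["DYS385a"] = lo
    df["DYS385b"] = hi
    return HaplotypeDataset(df, dataset.loci)


def non_discrete_report(
    dataset: HaplotypeDataset, loci: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-cell report of missing and intermediate (fractional) alleles.

    Columns: sample_id, locus, value, reason ('missing' | 'non-discrete').
    """
    names = list(loci) if loci is not None else list(dataset.locus_names)
    rows = []
    for name in names:
        col = dataset.df[name].to_numpy(dtype=float)
        for i in np.flatnonzero(np.isnan(col)):
            rows.append(
                (dataset.df["sample_id"].iloc[i], name, np.nan, "missing")
            )
        fractional = ~np.isnan(col) & (col != np.floor(col))
        for i in np.flatnonzero(fractional):
            rows.append(
                (dataset.df["sample_id"].iloc[i], name, col[i], "non-discrete")
            )
    return pd.DataFrame(rows, columns=["sample_id", "locus", "value", "reason"])


def filter_discrete(
    dataset: HaplotypeDataset, loci: Sequence[str] | None = None
) -> tuple[HaplotypeDataset, pd.DataFrame]:
    """Drop records with missing or intermediate alleles at the given loci.

    Returns the filtered dataset (locus columns narrowed to int64) and the
    exclusion report.  Retained records are never altered.  Raises
    ``EmptyDatasetError`` if nothing survives.
    """
    names = list(loci) if loci is not None else list(dataset.locus_names)
    report = non_discrete_report(dataset, names)
    block = dataset.df.loc[:, names].to_numpy(dtype=float)
    bad_rows = np.isnan(block).any(axis=1) | (block != np.floor(block)).any(axis=1)
    keep = pd.Series(~bad_rows, index=dataset.df.index)
    if not keep.any():
        raise EmptyDatasetError("filter_discrete excluded every record")
    df = dataset.df.loc[keep].reset_index(drop=True).copy()
    for name in dataset.locus_names:
        col = df[name].to_numpy(dtype=float)
        if not np.isnan(col).any() and np.all(col == np.floor(col)):
            df[name] = col.astype(np.int64)
    return HaplotypeDataset(df, dataset.loci), report


def select_loci(
    dataset: HaplotypeDataset, locus_names: Sequence[str]
) -> HaplotypeDataset:
    """Project the dataset onto the requested loci, preserving record order."""
    have = {ld.name: ld for ld in dataset.loci}
    unknown = [n for n in locus_names if n not in have]
    if unknown:
        raise KeyError(
            f"unknown loci {unknown}; available: {sorted(have)}"
        )
    keep_meta = [c for c in META_COLUMNS if c in dataset.df.columns]
    df = dataset.df.loc[:, keep_meta + list(locus_names)].copy()
    return HaplotypeDataset(df, tuple(have[n] for n in locus_names))
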