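"""Y-STR locus definitions: names, mutation rates, and plausible allele bounds.

The default panel covers the 12 loci of the classic "extended minimal"
Y-chromosomal haplotype.  Per-generation mutation probabilities are
locus-specific point estimates from published forensic compilations (NIST
and related father–son pair studies), expressed as fractions.  Allele
bounds bracket the repeat-count ranges reported for European populations
and are used both for input validation and as reflecting boundaries in the
stepwise-mutation simulator.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class LocusDef:
    """A single Y-STR locus.

    Parameters
    ----------
    name:
        Locus identifier, e.g. ``"DYS390"``.
    mu:
        Per-generation probability that a mutation occurs at this locus
        (a fraction; Y-STR point estimates are all well below 1%).
    min_repeat, max_repeat:
        Plausible integer repeat-count bounds, used for validation and as
        simulator boundaries.
    """

    name: str
    mu: float = 0.002
    min_repeat: int = 5
    max_repeat: int = 40

    def __post_init__(self) -> None:
        if not (0.0 < self.mu <= 0.01):
            raise ValueError(
                f"{self.name}: mu must be in (0, 0.01], got {self.mu!r}"
            )
        if self.min_repeat < 1:
            raise ValueError(f"{self.name}: min_repeat must be >= 1")
        if self.max_repeat < self.min_repeat:
            raise ValueError(f"{self.name}: max_repeat < min_repeat")


#: The 12-locus default panel with per-locus mutation probabilities.
DEFAULT_PANEL: tuple[LocusDef, ...] = (
    LocusDef("DYS19", mu=0.0025, min_repeat=10, max_repeat=19),
    LocusDef("DYS385a", mu=0.0021, min_repeat=7, max_repeat=17),
    LocusDef("DYS385b", mu=0.0021, min_repeat=8, max_repeat=22),
    LocusDef("DYS388", mu=0.0010, min_repeat=10, max_repeat=18),
    LocusDef("DYS389I", mu=0.0024, min_repeat=9, max_repeat=17),
    LocusDef("DYS389b", mu=0.0035, min_repeat=12, max_repeat=20),
    LocusDef("DYS390", mu=0.0025, min_repeat=17, max_repeat=29),
    LocusDef("DYS391", mu=0.0028, min_repeat=6, max_repeat=14),
    LocusDef("DYS392", mu=0.0007, min_repeat=6, max_repeat=18),
    LocusDef("DYS393", mu=0.0008, min_repeat=8, max_repeat=18),
    LocusDef("DYS426", mu=0.0007, min_repeat=7, max_repeat=15),
    LocusDef("DYS438", mu=0.0007, min_repeat=6, max_repeat=14),
)

DEFAULT_MU: dict[str, float] = {ld.name: ld.mu for ld in DEFAULT_PANEL}

_PANEL_BY_NAME: dict[str, LocusDef] = {ld.name: ld for ld in DEFAULT_PANEL}

#: Nine-locus cross-population analysis core: the full panel minus the three
#: loci typically reserved for haplogroup assignment (DYS388, DYS426, DYS438),
#: with the DYS389II reading replaced by the derived DYS389b block.
CORE_LOCI: tuple[str, ...] = (
    "DYS19",
    "DYS385a",
    "DYS385b",
    "DYS389I",
    "DYS389b",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
)


def locus_def(name: str) -> LocusDef:
    """Return the panel definition for ``name``, or a generic fallback.

    Loci outside the default panel get a conservative mu of 0.002 (the
    order of magnitude typical for Y-STRs) and wide allele bounds.
    """
    try:
        return _PANEL_BY_NAME[name]
    except KeyError:
        return LocusDef(name)
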