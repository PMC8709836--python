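"""Packaged study fixtures: the banding-sequence pool and printed tables.

The package ships, as plain text, everything needed to rerun the whole
analysis: the 16-sequence banding pool (arms A-F mapped, arm G
catalogued but unmapped), the collection-sites table, the per-population
banding-sequence frequency tables of the ten quantitative-panel
populations, their printed polymorphism indices, and the printed
pairwise distance matrix.

Known internal inconsistencies of the printed tables are preserved, not
reconciled, and surfaced as notes by `load_fixtures`:

* The frequency tables for NSK-LI and NSK-OR each reproduce the printed
  distance-matrix row of the *other* population, which points to swapped
  column labels.  ``load_frequency_tables(curated=True)`` opts into the
  swap; the default keeps the tables as printed.
* The larva count of YAR-RY is 4 in the collection-sites table but 100
  (a previously published figure) in the frequency-table header; the
  panel table carries the header figure.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from skbio.stats.distance import DistanceMatrix

from . import bandmap
from .bandmap import SequenceMap, ValidationReport, group_by_arm, read_pool
from .neiphylo import read_phylip_matrix
from .popstats import AlleleFrequencyTable

__all__ = [
    "FixtureSet",
    "load_pool",
    "load_e1_kv",
    "load_frequency_tables",
    "load_sites",
    "load_panel",
    "load_printed_distances",
    "load_fixtures",
    "dms_to_decimal",
    "PANEL_POPULATIONS",
]

PANEL_POPULATIONS = (
    "YAR-RY",
    "NSK-BE",
    "NSK-KA",
    "NSK-SH",
    "NSK-2R",
    "NSK-LI",
    "NSK-OR",
    "NSK-YU",
    "NSK-ST",
    "KHA-EV",
)

# frequency columns suspected of carrying each other's labels (their printed
# distance-matrix rows are interchanged)
SWAPPED_LABELS = ("NSK-LI", "NSK-OR")


def _read_text(name: str) -> str:
    return (resources.files("karyopool") / "data" / name).read_text(encoding="utf-8")


_DMS_RE = re.compile(r"^(\d+)°(\d+)'([\d.]+)\"([NSEW])$")


def dms_to_decimal(dms: str) -> float:
    """Convert a degrees-minutes-seconds coordinate to decimal degrees."""
    m = _DMS_RE.match(dms.strip())
    if not m:
        raise ValueError(f"bad DMS coordinate {dms!r}")
    deg, minute, sec, hemi = m.groups()
    value = int(deg) + int(minute) / 60 + float(sec) / 3600
    return -value if hemi in "SW" else value


def load_pool() -> list[SequenceMap]:
    """The packaged banding-sequence pool (16 sequences)."""
    return read_pool(_read_text("agilis.pool"))


def load_e1_kv() -> SequenceMap:
    """Alternate KV rendering of the arm-E main sequence (never mix with GV)."""
    (m,) = read_pool(_read_text("arm_e_kv.pool"))
    return m


def load_frequency_tables(curated: bool = False) -> list[AlleleFrequencyTable]:
    """Per-population frequency tables, in panel order.

    ``curated=True`` swaps the NSK-LI and NSK-OR column labels (the
    suspected misprint); the default keeps the tables as printed.
    """
    df = pd.read_csv(_read_text_buffer("frequencies.tsv"), sep="\t", comment="#")
    tables = []
    for pop in PANEL_POPULATIONS:
        sub = df[df["population"] == pop]
        freqs: dict[str, dict[str, float]] = {}
        for row in sub.itertuples():
            freqs.setdefault(row.arm, {})[row.sequence] = float(row.frequency)
        code = pop
        if curated and pop in SWAPPED_LABELS:
            code = SWAPPED_LABELS[1 - SWAPPED_LABELS.index(pop)]
        tables.append(AlleleFrequencyTable(code, freqs))
    if curated:
        tables.sort(key=lambda t: PANEL_POPULATIONS.index(t.population))
    return tables


def _read_text_buffer(name: str):
    import io

    return io.StringIO(_read_text(name))


def load_sites() -> pd.DataFrame:
    """Collection sites with coordinates converted to decimal degrees."""
    df = pd.read_csv(_read_text_buffer("sites.tsv"), sep="\t", comment="#")
    df["lat_deg"] = df["lat"].map(dms_to_decimal)
    df["lon_deg"] = df["lon"].map(dms_to_decimal)
    return df


def load_panel() -> pd.DataFrame:
    """Printed polymorphism indices of the ten panel populations."""
    return pd.read_csv(_read_text_buffer("panel.tsv"), sep="\t", comment="#")


def load_printed_distances() -> DistanceMatrix:
    """The printed pairwise Nei-distance matrix (lower triangle)."""
    return read_phylip_matrix(_read_text("distances.tsv"))


@dataclass
class FixtureSet:
    """All packaged fixtures, validated, plus provenance notes."""

    pool: list[SequenceMap]
    validation: dict[str, ValidationReport]
    tables: list[AlleleFrequencyTable]
    sites: pd.DataFrame
    panel: pd.DataFrame
    printed_distances: DistanceMatrix
    e1_kv: SequenceMap
    notes: list[str] = field(default_factory=list)

    @property
    def pool_size(self) -> int:
        """Distinct banding sequences in the pool, mapped or not."""
        return len({(m.species, m.arm, m.serial) for m in self.pool})

    def table(self, population: str) -> AlleleFrequencyTable:
        for t in self.tables:
            if t.population == population:
                return t
        raise KeyError(population)

    def sequence(self, name_or_short: str) -> SequenceMap:
        """Look up a pool sequence by full id or arm+serial shorthand (B2)."""
        for m in self.pool:
            if m.name == name_or_short or f"{m.arm}{m.serial}" == name_or_short:
                return m
        raise KeyError(name_or_short)


def load_fixtures(curated: bool = False, warn: bool = True) -> FixtureSet:
    """Load and validate every packaged fixture.

    Validation failures are errors; the known printed inconsistencies
    are surfaced as notes (and warnings when ``warn`` is true), never
    silently reconciled.
    """
    pool = load_pool()
    validation: dict[str, ValidationReport] = {}
    for arm, maps in sorted(group_by_arm(pool).items()):
        mapped = [m for m in maps if m.mapped]
        if len(mapped) < 1:
            continue
        report = bandmap.validate_arm_pool(mapped)
        if not report.ok:
            raise ValueError(f"packaged pool corrupt: {report.message()}")
        validation[arm] = report
    tables = load_frequency_tables(curated=curated)
    for t in tables:
        for arm, vec in t.freqs.items():
            total = sum(vec.values())
            if abs(total - 1.0) > 2e-3:
                raise ValueError(
                    f"fixture table {t.population} arm {arm} sums to {total}"
                )
    notes = [
        "frequency tables: the NSK-LI and NSK-OR columns are suspected of "
        "carrying each other's labels (each reproduces the other's printed "
        "distance-matrix row); pass curated=True to swap them",
        "YAR-RY larva count: 4 in the collection-sites table vs 100 (prior "
        "published data) in the frequency-table header; frequency-based "
        "work uses the header figure",
        "the printed genotype-frequency table has more data columns than "
        "population headers; only its panel index rows are packaged, "
        "aligned to the panel populations in printed order",
    ]
    if warn:
        for note in notes:
            warnings.warn(note, stacklevel=2)
    return FixtureSet(
        pool=pool,
        validation=validation,
        tables=tables,
        sites=load_sites(),
        panel=load_panel(),
        printed_distances=load_printed_distances(),
        e1_kv=load_e1_kv(),
        notes=notes,
    )
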