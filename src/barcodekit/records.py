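"""Stranding-record tabulation.

A regional stranding network records, for every marine mammal found on the
coastline, a taxon (to species level when the carcass allows, otherwise a
higher rank such as "Delphinidae (undetermined)"), a broad group (cetacean or
pinniped) and the year.  This module loads such tables from CSV and computes
the monitoring statistics used to judge how much a barcoding programme could
improve them: total strandings, the number and fraction of animals never
identified to species, and yearly species richness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

VALID_RANKS = {"species", "genus_or_higher", "unknown"}
VALID_GROUPS = {"cetacean", "pinniped", "unknown"}


class StrandingTableError(ValueError):
    """Raised when a stranding CSV violates the table invariants."""


@dataclass(frozen=True)
class StrandingRow:
    taxon: str
    rank: str  # species | genus_or_higher | unknown
    group: str  # cetacean | pinniped | unknown
    year: int
    count: int


@dataclass
class StrandingTable:
    """Validated long-format stranding table: one row per (taxon, year)."""

    rows: list[StrandingRow] = field(default_factory=list)

    @property
    def years(self) -> list[int]:
        return sorted({r.year for r in self.rows})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


@dataclass
class StrandingSummary:
    grand_total: int
    per_year_totals: dict[int, int]
    undetermined_total: int
    undetermined_fraction: float
    species_per_year: dict[int, int]
    n_cetacean_species: int
    n_pinniped_species: int

    @property
    def undetermined_percent(self) -> float:
        """Undetermined fraction as a percentage, truncated to 1 decimal
        (the convention of the source monitoring tables)."""
        return math.floor(1000.0 * self.undetermined_fraction) / 10.0

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["undetermined_percent"] = self.undetermined_percent
        d["per_year_totals"] = {str(k): v for k, v in self.per_year_totals.items()}
        d["species_per_year"] = {str(k): v for k, v in self.species_per_year.items()}
        return json.dumps(d, indent=2)

    def to_text(self) -> str:
        lines = [
            f"Total strandings: {self.grand_total}",
            f"Undetermined to species: {self.undetermined_total} "
            f"({self.undetermined_percent}%)",
            f"Cetacean species: {self.n_cetacean_species}",
            f"Pinniped species: {self.n_pinniped_species}",
            "Year  Strandings  Species",
        ]
        for y in sorted(self.per_year_totals):
            lines.append(
                f"{y}  {self.per_year_totals[y]:>10d}  {self.species_per_year.get(y, 0):>7d}"
            )
        return "\n".join(lines)


def bundled_table_path() -> Path:
    """Path of the packaged Brittany 2003-2012 stranding table."""
    return Path(
        resources.files("barcodekit").joinpath(
            "data/brittany_strandings_2003_2012.csv"
        )
    )


def _infer_rank(taxon: str, rank: str) -> str:
    if rank:
        return rank
    return "genus_or_higher" if "(undetermined)" in taxon else "species"


def load_stranding_table(path: str | Path) -> StrandingTable:
    """Load and validate a stranding CSV (header ``taxon,rank,group,year,count``).

    Rank may be left blank, in which case it is inferred: labels containing
    "(undetermined)" are genus-or-higher, anything else species.  Errors name
    the offending row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["taxon", "year", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise StrandingTableError(f"missing required columns: {missing}")
    rows: list[StrandingRow] = []
    seen: set[tuple[str, int]] = set()
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        taxon = rec.taxon.strip()
        try:
            year = int(rec.year)
        except ValueError:
            raise StrandingTableError(f"row {i}: malformed year {rec.year!r}") from None
        try:
            count = int(rec.count)
        except ValueError:
            raise StrandingTableError(
                f"row {i}: malformed count {rec.count!r}"
            ) from None
        if count < 0:
            raise StrandingTableError(f"row {i}: negative count {count}")
        rank = _infer_rank(taxon, getattr(rec, "rank", "").strip())
        if rank not in VALID_RANKS:
            raise StrandingTableError(f"row {i}: invalid rank {rank!r}")
        group = getattr(rec, "group", "").strip() or "unknown"
        if group not in VALID_GROUPS:
            raise StrandingTableError(f"row {i}: invalid group {group!r}")
        if (taxon, year) in seen:
            raise StrandingTableError(f"row {i}: duplicate (taxon, year) ({taxon}, {year})")
        seen.add((taxon, year))
        rows.append(StrandingRow(taxon, rank, group, year, count))
    return StrandingTable(rows)


def summarize_strandings(table: StrandingTable) -> StrandingSummary:
    """Monitoring summary of a stranding table.

    "Undetermined" counts every row whose rank is not ``species`` (including
    rank ``unknown``); species richness counts a species in a year iff its
    count that year is positive.
    """
    if not table.rows:
        raise StrandingTableError("cannot summarize an empty table")
    grand_total = sum(r.count for r in table.rows)
    per_year: dict[int, int] = {}
    species_per_year: dict[int, int] = {}
    undetermined = 0
    cet_species: set[str] = set()
    pin_species: set[str] = set()
    for r in table.rows:
        per_year[r.year] = per_year.get(r.year, 0) + r.count
        species_per_year.setdefault(r.year, 0)
        if r.rank != "species":
            undetermined += r.count
        elif r.count > 0:
            species_per_year[r.year] += 1
            if r.group == "cetacean":
                cet_species.add(r.taxon)
            elif r.group == "pinniped":
                pin_species.add(r.taxon)
    return StrandingSummary(
        grand_total=grand_total,
        per_year_totals=dict(sorted(per_year.items())),
        undetermined_total=undetermined,
        undetermined_fraction=undetermined / grand_total if grand_total else 0.0,
        species_per_year=dict(sorted(species_per_year.items())),
        n_cetacean_species=len(cet_species),
        n_pinniped_species=len(pin_species),
    )
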