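"""Phage metadata and host-range tables, with summary statistics.

The metadata schema mirrors the characteristics table of a phage collection:
one row per phage with its susceptible host strain(s), packaging group,
isolation year/country, fermentation product, genome size, CDS count, GC
percentage and accession.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field

GROUPS = ("cos", "pac", "5093", "987", "unknown")
PRODUCTS = ("cheese", "yoghurt", "other")

METADATA_COLUMNS = [
    "phage_id",
    "host_strains",
    "group",
    "year",
    "country",
    "product",
    "genome_size",
    "n_orfs",
    "gc",
    "accession",
]


@dataclass(frozen=True)
class PhageMetadataRow:
    phage_id: str
    host_strains: frozenset[str]
    group: str
    year: int | None
    country: str | None
    product: str
    genome_size: int
    n_orfs: int
    gc: float
    accession: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"{self.phage_id}: unknown group {self.group!r}")
        if self.product not in PRODUCTS:
            raise ValueError(f"{self.phage_id}: unknown product {self.product!r}")
        if self.genome_size <= 0:
            raise ValueError(f"{self.phage_id}: genome_size must be positive")
        if self.n_orfs <= 0:
            raise ValueError(f"{self.phage_id}: n_orfs must be positive")
        if not 0.0 < self.gc < 100.0:
            raise ValueError(f"{self.phage_id}: GC% must lie in (0, 100)")
        if not self.host_strains:
            raise ValueError(f"{self.phage_id}: host_strains must be non-empty")


def _missing(cell: str) -> bool:
    return cell.strip() in ("", "N/A", "NA", "n/a")


def read_metadata(tsv_path) -> list[PhageMetadataRow]:
    """Parse a metadata TSV with the fixed column header.

    Multi-host cells are split on whitespace; "N/A" year/country/accession
    map to missing.  Malformed numeric cells raise a ValueError naming the
    row and column.
    """
    rows: list[PhageMetadataRow] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != METADATA_COLUMNS:
            raise ValueError(
                f"{tsv_path}: expected columns {METADATA_COLUMNS}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(METADATA_COLUMNS):
                raise ValueError(f"{tsv_path}:{lineno}: wrong number of columns")
            rec = dict(zip(METADATA_COLUMNS, cells))

            def intcell(col: str) -> int:
                try:
                    return int(rec[col].replace(",", ""))
                except ValueError:
                    raise ValueError(
                        f"{tsv_path}:{lineno}: malformed integer in column {col!r}: {rec[col]!r}"
                    ) from None

            def floatcell(col: str) -> float:
                try:
                    return float(rec[col])
                except ValueError:
                    raise ValueError(
                        f"{tsv_path}:{lineno}: malformed number in column {col!r}: {rec[col]!r}"
                    ) from None

            rows.append(
                PhageMetadataRow(
                    phage_id=rec["phage_id"],
                    host_strains=frozenset(rec["host_strains"].split()),
                    group=rec["group"],
                    year=None if _missing(rec["year"]) else intcell("year"),
                    country=None if _missing(rec["country"]) else rec["country"],
                    product=rec["product"],
                    genome_size=intcell("genome_size"),
                    n_orfs=intcell("n_orfs"),
                    gc=floatcell("gc"),
                    accession=None if _missing(rec["accession"]) else rec["accession"],
                )
            )
    return rows


@dataclass
class MetadataSummary:
    n_records: int
    group_counts: dict[str, int]
    orf_mean: float
    orf_mean_rounded: int
    orf_min: int
    orf_max: int
    size_mean_kb: float
    phages_per_strain: dict[str, int]


def summarize_metadata(rows: list[PhageMetadataRow]) -> MetadataSummary:
    """Group counts, ORF-count statistics and per-strain phage counts."""
    if not rows:
        raise ValueError("no metadata rows")
    orfs = [r.n_orfs for r in rows]
    per_strain: Counter[str] = Counter()
    for r in rows:
        per_strain.update(r.host_strains)
    return MetadataSummary(
        n_records=len(rows),
        group_counts=dict(Counter(r.group for r in rows)),
        orf_mean=statistics.fmean(orfs),
        orf_mean_rounded=round(statistics.fmean(orfs)),
        orf_min=min(orfs),
        orf_max=max(orfs),
        size_mean_kb=statistics.fmean(r.genome_size for r in rows) / 1000.0,
        phages_per_strain=dict(per_strain),
    )


@dataclass
class HostRangeTable:
    """phage id -> set of susceptible strain ids (each phage >= 1 strain)."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for phage, strains in self.entries.items():
            if not strains:
                raise ValueError(f"phage {phage!r} maps to no strains")
            if any(not s for s in strains):
                raise ValueError(f"phage {phage!r} has an empty strain id")

    def strains(self) -> set[str]:
        return set().union(*self.entries.values()) if self.entries else set()

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("phage_id\thost_strains\n")
            for phage in sorted(self.entries):
                fh.write(f"{phage}\t{' '.join(sorted(self.entries[phage]))}\n")

    @classmethod
    def from_tsv(cls, path) -> "HostRangeTable":
        entries: dict[str, set[str]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["phage_id", "host_strains"]:
                raise ValueError(f"{path}: bad host-range header {header}")
            for line in fh:
                if not line.strip():
                    continue
                phage, strains = line.rstrip("\n").split("\t")
                if phage in entries:
                    raise ValueError(f"{path}: duplicate phage {phage!r}")
                entries[phage] = set(strains.split())
        return cls(entries)
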