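"""Ingestion of the MAG-labeled ORF catalog.

Builds a merged gene table — one row per predicted ORF, labeled with its
source MAG, nucleotide length, Prodigal ``partial`` completeness flag and
any KO annotations — from either a ready-made gene TSV or per-MAG Prodigal
GFF files plus a GhostKOALA-style two-column KO table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import pandas as pd

__all__ = [
    "GeneIngestError",
    "GeneRecord",
    "GeneTable",
    "KoAttachResult",
    "attach_ko_annotations",
    "full_length_fraction",
    "merge_tables",
    "read_gene_table",
    "read_prodigal_gff",
    "read_sample_sheet",
]

logger = logging.getLogger(__name__)

_VALID_PARTIAL = {"00", "01", "10", "11"}


class GeneIngestError(ValueError):
    """Raised for malformed gene tables, GFF records or KO tables."""


@dataclass(frozen=True)
class GeneRecord:
    """A single MAG-labeled ORF."""

    gene_id: str
    mag_id: str
    length_nt: int
    partial_flag: str
    kos: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.length_nt < 3:
            raise GeneIngestError(
                f"gene {self.gene_id!r}: length_nt {self.length_nt} < 3"
            )
        if self.partial_flag not in _VALID_PARTIAL:
            raise GeneIngestError(
                f"gene {self.gene_id!r}: bad partial flag {self.partial_flag!r}"
            )
        if not self.mag_id:
            raise GeneIngestError(f"gene {self.gene_id!r}: empty mag_id")


class GeneTable:
    """Immutable collection of :class:`GeneRecord` with unique gene ids.

    Internally pandas-backed; ``df`` exposes columns ``gene_id``,
    ``mag_id``, ``length_nt``, ``partial``, ``kos`` (tuple-valued).
    """

    def __init__(self, records: Iterable[GeneRecord]):
        recs = list(records)
        ids = [r.gene_id for r in recs]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise GeneIngestError(f"duplicate gene_id {dup!r}")
        self._records = tuple(recs)
        self.df = pd.DataFrame(
            {
                "gene_id": ids,
                "mag_id": [r.mag_id for r in recs],
                "length_nt": pd.array([r.length_nt for r in recs], dtype="int64"),
                "partial": [r.partial_flag for r in recs],
                "kos": [r.kos for r in recs],
            }
        )
        self._by_id = {r.gene_id: r for r in recs}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    @property
    def records(self) -> tuple[GeneRecord, ...]:
        return self._records

    @property
    def gene_ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def mag_ids(self) -> list[str]:
        """Distinct MAG ids in first-appearance order."""
        return list(dict.fromkeys(r.mag_id for r in self._records))

    def lengths(self) -> pd.Series:
        """Per-gene nucleotide lengths indexed by gene_id."""
        return self.df.set_index("gene_id")["length_nt"]

    def mag_kos(self, mag_id: str) -> set[str]:
        """Union of KO annotations over all genes of one MAG."""
        return {ko for r in self._records if r.mag_id == mag_id for ko in r.kos}

    def genes_with_ko(self, mag_id: str, ko: str) -> list[str]:
        return [
            r.gene_id for r in self._records if r.mag_id == mag_id and ko in r.kos
        ]

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["ko"] = out.pop("kos").map(";".join)
        out = out.rename(columns={"partial": "partial"})
        out.to_csv(path, sep="\t", index=False, columns=["gene_id", "mag_id", "length_nt", "partial", "ko"])


def merge_tables(*tables: GeneTable) -> GeneTable:
    """Concatenate per-MAG fragments; gene ids must be globally unique."""
    return GeneTable(r for t in tables for r in t)


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a gene TSV with header ``gene_id, mag_id, length_nt, partial, ko``.

    The ``ko`` column may be blank (no annotation) or semicolon-separated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "mag_id", "length_nt", "partial"}
    missing = required - set(df.columns)
    if missing:
        raise GeneIngestError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            length = int(row.length_nt)
        except ValueError:
            raise GeneIngestError(
                f"{path}:{lineno}: non-integer length {row.length_nt!r}"
            ) from None
        if length <= 0:
            raise GeneIngestError(f"{path}:{lineno}: non-positive length {length}")
        raw_ko = getattr(row, "ko", "")
        kos = tuple(k.strip().upper() for k in raw_ko.split(";") if k.strip())
        try:
            records.append(
                GeneRecord(row.gene_id, row.mag_id, length, row.partial, kos)
            )
        except GeneIngestError as exc:
            raise GeneIngestError(f"{path}:{lineno}: {exc}") from None
    try:
        return GeneTable(records)
    except GeneIngestError as exc:
        raise GeneIngestError(f"{path}: {exc}") from None


def read_prodigal_gff(path: str | Path, mag_id: str) -> GeneTable:
    """Read CDS features from a Prodigal GFF3 file as one MAG's fragment.

    Lengths are ``end - start + 1`` (1-based inclusive coordinates); the
    ``partial=XY`` attribute is taken verbatim. A missing attribute
    defaults to "00" with a logged warning.
    """
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GeneIngestError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, _src, ftype, start, end = fields[0], fields[1], fields[2], fields[3], fields[4]
            if ftype != "CDS":
                continue
            attrs = {}
            for item in fields[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            gene_id = attrs.get("ID") or f"{seqid}_{len(records) + 1}"
            partial = attrs.get("partial")
            if partial is None:
                logger.warning(
                    "%s:%d: CDS %s lacks a partial attribute; assuming 00",
                    path, lineno, gene_id,
                )
                partial = "00"
            try:
                length = int(end) - int(start) + 1
            except ValueError:
                raise GeneIngestError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            records.append(GeneRecord(gene_id, mag_id, length, partial))
    return GeneTable(records)


class KoAttachResult(NamedTuple):
    table: GeneTable
    orphans: list[str]


def attach_ko_annotations(table: GeneTable, path: str | Path) -> KoAttachResult:
    """Merge a GhostKOALA-style two-column TSV (gene_id<TAB>KO) onto a table.

    Rows with a blank KO leave the gene unannotated; rows naming unknown
    genes are collected into the orphan report rather than raising.
    Re-applying the same file is idempotent.
    """
    assignments: dict[str, list[str]] = {}
    orphans: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            gene_id = parts[0].strip()
            ko = parts[1].strip().upper() if len(parts) > 1 else ""
            if gene_id not in table:
                orphans.append(gene_id)
                continue
            if ko:
                kos = assignments.setdefault(gene_id, [])
                if ko not in kos:
                    kos.append(ko)
    records = []
    for r in table:
        new = [ko for ko in assignments.get(r.gene_id, []) if ko not in r.kos]
        records.append(
            GeneRecord(r.gene_id, r.mag_id, r.length_nt, r.partial_flag, r.kos + tuple(new))
            if new
            else r
        )
    return KoAttachResult(GeneTable(records), orphans)


def full_length_fraction(table: GeneTable) -> float:
    """QC metric: fraction of ORFs complete at both ends (partial == "00")."""
    if len(table) == 0:
        raise GeneIngestError("full_length_fraction of an empty gene table")
    return sum(r.partial_flag == "00" for r in table) / len(table)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns ``sample_id, condition, replicate``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"sample_id", "condition", "replicate"} - set(df.columns)
    if missing:
        raise GeneIngestError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise GeneIngestError(f"{path}: duplicate sample_id {dup!r}")
    return df
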