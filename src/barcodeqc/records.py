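"""Core domain types: a barcode record and an ordered reference library.

A :class:`BarcodeRecord` is one sequence together with its species label
and provenance metadata; a :class:`ReferenceLibrary` is an ordered
collection of records plus an audit trail of every filter applied to it.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_SOURCES = ("genbank", "bold", "novel")

#: Characters counted as informative (unambiguous) in an aligned sequence.
CANONICAL_BASES = frozenset("ACGT")


@dataclass
class BarcodeRecord:
    """One barcode sequence with its species label and metadata.

    Parameters
    ----------
    record_id
        Unique identifier within a library.
    species_label
        Binomial, optionally with a subspecies epithet (trinomial).
    sequence
        IUPAC nucleotide string; may contain gaps after trimming.
    accession
        Database accession, or ``None`` for unreleased records.
    source
        One of ``genbank``, ``bold`` or ``novel``.
    updated_date
        Date the record (and its name) was last updated, if known.
    metadata
        Free key/value map (locality, voucher, collector, ...).
    """

    record_id: str
    species_label: str
    sequence: str
    accession: str | None = None
    source: str = "novel"
    updated_date: _dt.date | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        if self.source not in VALID_SOURCES:
            raise ValueError(
                f"record {self.record_id!r}: source {self.source!r} not in {VALID_SOURCES}"
            )
        self.sequence = self.sequence.upper().replace("U", "T")

    @property
    def n_informative(self) -> int:
        """Number of unambiguous (A/C/G/T) positions in the sequence."""
        return sum(1 for c in self.sequence if c in CANONICAL_BASES)


class ReferenceLibrary:
    """Ordered collection of :class:`BarcodeRecord` with a filter log.

    The filter log records, for each filtering step applied in order,
    the step name and the number of records it removed, so that the
    count of input records always equals retained + removed.
    """

    def __init__(
        self,
        records: Iterable[BarcodeRecord],
        alignment_length: int = 0,
        filter_log: list[tuple[str, int]] | None = None,
    ) -> None:
        self.records: list[BarcodeRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id {rec.record_id!r}")
            seen.add(rec.record_id)
        self.alignment_length = alignment_length
        if alignment_length:
            bad = [r.record_id for r in self.records if len(r.sequence) != alignment_length]
            if bad:
                raise ValueError(
                    f"alignment_length={alignment_length} but records {bad[:5]} differ"
                )
        self.filter_log: list[tuple[str, int]] = list(filter_log or [])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BarcodeRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> BarcodeRecord:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    @property
    def ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    @property
    def labels(self) -> dict[str, str]:
        """Mapping record_id -> stored species label."""
        return {r.record_id: r.species_label for r in self.records}

    def species_counts(self) -> pd.Series:
        return pd.Series([r.species_label for r in self.records]).value_counts()

    def with_records(
        self, records: Iterable[BarcodeRecord], step: str | None = None, removed: int = 0
    ) -> "ReferenceLibrary":
        """Copy of this library with a new record list and an extended log."""
        log = list(self.filter_log)
        if step is not None:
            log.append((step, removed))
        new_records = list(records)
        lengths = {len(r.sequence) for r in new_records}
        aln = lengths.pop() if len(lengths) == 1 else 0
        return ReferenceLibrary(new_records, alignment_length=aln, filter_log=log)

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    def to_fasta(self, path: str | Path) -> None:
        seqs = [
            SeqRecord(Seq(r.sequence), id=r.record_id, description=r.species_label)
            for r in self.records
        ]
        SeqIO.write(seqs, str(path), "fasta")

    def to_metadata_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "record_id": r.record_id,
                    "accession": r.accession or "",
                    "species_label": r.species_label,
                    "source": r.source,
                    "updated_date": r.updated_date.isoformat() if r.updated_date else "",
                    **r.metadata,
                }
            )
        return pd.DataFrame(rows)

    def to_metadata_tsv(self, path: str | Path) -> None:
        self.to_metadata_frame().to_csv(path, sep="\t", index=False)

    def filter_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.filter_log, columns=["filter", "removed"])

    @classmethod
    def from_fasta(
        cls,
        fasta: str | Path,
        metadata: str | Path | pd.DataFrame | None = None,
        source: str = "genbank",
    ) -> "ReferenceLibrary":
        """Read a library from FASTA, optionally joined with a metadata table.

        FASTA headers of the form ``>id Genus species ...`` supply the
        species label when no metadata table is given.  A metadata table
        (TSV with at least ``record_id`` and ``species_label`` columns)
        overrides header-derived fields and may add ``accession``,
        ``source`` and ``updated_date``.
        """
        meta: dict[str, dict] = {}
        if metadata is not None:
            df = (
                metadata
                if isinstance(metadata, pd.DataFrame)
                else pd.read_csv(metadata, sep="\t", dtype=str).fillna("")
            )
            meta = {row["record_id"]: dict(row) for _, row in df.iterrows()}
        records = []
        for seq in SeqIO.parse(str(fasta), "fasta"):
            m = meta.get(seq.id, {})
            label = m.get("species_label") or " ".join(seq.description.split()[1:]) or seq.id
            date_s = m.get("updated_date") or ""
            date = _dt.date.fromisoformat(date_s) if date_s else None
            extra = {
                k: v
                for k, v in m.items()
                if k not in {"record_id", "accession", "species_label", "source", "updated_date"}
            }
            records.append(
                BarcodeRecord(
                    record_id=seq.id,
                    species_label=label,
                    sequence=str(seq.seq),
                    accession=m.get("accession") or None,
                    source=m.get("source") or source,
                    updated_date=date,
                    metadata=extra,
                )
            )
        lengths = {len(r.sequence) for r in records}
        aln = lengths.pop() if len(lengths) == 1 else 0
        return cls(records, alignment_length=aln)


def copy_record(rec: BarcodeRecord, **changes) -> BarcodeRecord:
    """Shallow copy of a record with field overrides."""
    return replace(rec, metadata=dict(rec.metadata), **changes)
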