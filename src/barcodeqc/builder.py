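"""Reference-library assembly: merge, dereplicate, filter, trim.

Reproduces the dataset-building rules used for curated barcode
libraries: records from multiple repositories are pooled, duplicated
accessions collapse to one record (conflicting species names resolved in
favour of the more recently updated one), records not identified to
species level are dropped, every sequence is trimmed to the span of a
reference barcode by pairwise alignment, and records with too few
informative positions are removed.  Every removal is logged with a
reason so the path from raw pool to final library is auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import Align

from barcodeqc.records import BarcodeRecord, ReferenceLibrary, copy_record

#: Open-nomenclature tokens marking a label not identified to species level.
_OPEN_NOMENCLATURE = re.compile(r"(?:^|\s)(sp\.?|cf\.?|aff\.?|nr\.?)(?:\s|$)", re.IGNORECASE)


def merge_sources(libraries: list[ReferenceLibrary]) -> ReferenceLibrary:
    """Concatenate libraries, preserving order and source tags.

    No filtering is performed.  Raises ``ValueError`` naming the first
    clashing ``record_id`` if two sources share one.
    """
    if not libraries:
        raise ValueError("need at least one library to merge")
    seen: dict[str, int] = {}
    records: list[BarcodeRecord] = []
    for k, lib in enumerate(libraries):
        for rec in lib:
            if rec.record_id in seen:
                raise ValueError(
                    f"record_id {rec.record_id!r} present in sources "
                    f"{seen[rec.record_id]} and {k}"
                )
            seen[rec.record_id] = k
            records.append(rec)
    lengths = {len(r.sequence) for r in records}
    aln = lengths.pop() if len(lengths) == 1 else 0
    return ReferenceLibrary(records, alignment_length=aln)


def dereplicate_by_accession(
    lib: ReferenceLibrary,
) -> tuple[ReferenceLibrary, list[dict]]:
    """Keep one record per accession; prefer the most recently updated name.

    When duplicates of an accession disagree on the species label, the
    retained record carries the label of the duplicate with the latest
    ``updated_date``.  Conflicts where no duplicate has a date are kept
    with the first-seen label and reported in the returned conflicts
    list.  Records without an accession are always retained.
    """
    by_acc: dict[str, list[BarcodeRecord]] = {}
    order: list[str | None] = []
    no_acc: list[BarcodeRecord] = []
    for rec in lib:
        if rec.accession is None:
            no_acc.append(rec)
            order.append(None)
        else:
            by_acc.setdefault(rec.accession, []).append(rec)
            order.append(rec.accession)

    conflicts: list[dict] = []
    kept: dict[str, BarcodeRecord] = {}
    for acc, dups in by_acc.items():
        winner = dups[0]
        labels = {d.species_label for d in dups}
        if len(labels) > 1:
            dated = [d for d in dups if d.updated_date is not None]
            if dated:
                latest = max(dated, key=lambda d: d.updated_date)
                if latest.species_label != winner.species_label:
                    winner = copy_record(winner, species_label=latest.species_label)
            else:
                conflicts.append(
                    {
                        "accession": acc,
                        "labels": sorted(labels),
                        "retained": winner.species_label,
                        "reason": "conflicting labels, no updated_date",
                    }
                )
        kept[acc] = winner

    emitted: set[str] = set()
    out: list[BarcodeRecord] = []
    no_acc_iter = iter(no_acc)
    for acc in order:
        if acc is None:
            out.append(next(no_acc_iter))
        elif acc not in emitted:
            emitted.add(acc)
            out.append(kept[acc])
    removed = len(lib) - len(out)
    return lib.with_records(out, "dereplicate_by_accession", removed), conflicts


def is_species_level(label: str) -> bool:
    """True when a label names a species (or subspecies), not an open ID.

    Rejects open-nomenclature qualifiers (``sp.``, ``cf.``, ``aff.``,
    ``nr.``) and bare genus names; trinomials (subspecies) pass.
    """
    label = label.strip()
    if not label or _OPEN_NOMENCLATURE.search(label):
        return False
    return len(label.split()) >= 2


def filter_species_level(lib: ReferenceLibrary) -> ReferenceLibrary:
    """Drop records whose label is not identified to species level."""
    kept = [r for r in lib if is_species_level(r.species_label)]
    return lib.with_records(kept, "filter_species_level", len(lib) - len(kept))


def _make_aligner(match: float, mismatch: float, gap_open: float,
                  gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps: records may cover only part of the reference and
    # may carry flanking sequence beyond it
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


@dataclass
class TrimResult:
    """Outcome of trimming: the library plus per-record audit entries."""

    library: ReferenceLibrary
    unmappable: list[str] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)


def trim_to_reference(
    lib: ReferenceLibrary,
    reference: BarcodeRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
    min_score: float | None = None,
) -> TrimResult:
    """Trim every record to the reference barcode span by pairwise alignment.

    Each record is globally aligned to the ungapped reference with free
    end gaps.  Columns outside the reference span, and record columns
    inserted relative to the reference, are removed; positions of the
    reference not covered by the record are padded with ``-``.  All
    output sequences therefore have length ``len(reference.sequence)``.

    Records scoring below ``min_score`` (default: a quarter of the
    reference length, far above what unrelated sequence achieves under
    the +1/-1 scheme) are flagged unmappable, removed and logged.
    """
    ref_seq = reference.sequence.replace("-", "")
    if ref_seq != reference.sequence:
        raise ValueError("reference sequence must be ungapped")
    ref_len = len(ref_seq)
    if min_score is None:
        min_score = 0.25 * ref_len

    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    out: list[BarcodeRecord] = []
    result = TrimResult(library=lib)
    for rec in lib:
        query = rec.sequence.replace("-", "")
        alignment = aligner.align(ref_seq, query)[0]
        result.scores[rec.record_id] = alignment.score
        if alignment.score < min_score:
            result.unmappable.append(rec.record_id)
            continue
        trimmed = ["-"] * ref_len
        # aligned blocks: paired (target, query) coordinate runs
        for (t0, t1), (q0, q1) in zip(*alignment.aligned):
            trimmed[t0:t1] = query[q0:q1]
        out.append(copy_record(rec, sequence="".join(trimmed)))

    new_lib = lib.with_records(out, "trim_to_reference_unmappable", len(result.unmappable))
    new_lib.alignment_length = ref_len
    result.library = new_lib
    return result


def filter_min_length(lib: ReferenceLibrary, min_informative: int = 300) -> ReferenceLibrary:
    """Drop records with fewer than ``min_informative`` unambiguous columns.

    The bound is strict: a record with exactly ``min_informative``
    informative positions is retained.
    """
    kept = [r for r in lib if r.n_informative >= min_informative]
    return lib.with_records(kept, f"filter_min_length<{min_informative}", len(lib) - len(kept))
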