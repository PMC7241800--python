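"""Curation edits and cross-version accuracy comparison.

Expert taxonomic judgements enter the pipeline as a batch of
:class:`RevisionEdit` actions — relabel a record or remove it — applied
all-or-nothing with a full audit trail.  Identification accuracy across
library versions (e.g. original, optimised-threshold, post-revision) is
compared on the per-species correct-identification ratio, normalised by
quotient transformation (each version's vector divided by its own mean,
removing pure scale differences) and tested with a one-way fixed-effects
ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from barcodeqc.records import ReferenceLibrary, copy_record

EVIDENCE_KINDS = ("voucher_reexamination", "reference_sequence_match", "metadata")


@dataclass
class RevisionEdit:
    """One expert curation action: relabel or remove a record."""

    action: str  # "relabel" | "remove"
    target: str
    new_label: str | None = None
    rationale: str = ""
    evidence: str = "metadata"

    def __post_init__(self) -> None:
        if self.action not in ("relabel", "remove"):
            raise ValueError(f"unknown action {self.action!r}")
        if self.action == "relabel" and not self.new_label:
            raise ValueError(f"relabel of {self.target!r} needs new_label")
        if self.evidence not in EVIDENCE_KINDS:
            raise ValueError(f"unknown evidence kind {self.evidence!r}")


def read_edits(path: str | Path) -> list[RevisionEdit]:
    """Read a batch of edits from TSV (action, target, new_label, rationale, evidence)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        RevisionEdit(
            action=row["action"],
            target=row["target"],
            new_label=row.get("new_label") or None,
            rationale=row.get("rationale", ""),
            evidence=row.get("evidence") or "metadata",
        )
        for _, row in df.iterrows()
    ]


def apply_edits(
    lib: ReferenceLibrary, edits: list[RevisionEdit]
) -> tuple[ReferenceLibrary, pd.DataFrame]:
    """Apply a batch of edits all-or-nothing.

    Any edit targeting a missing record raises before anything is
    applied.  A relabel to the record's current label is rejected.
    Returns the edited library and an audit frame mapping every action
    to the record's pre-edit state.
    """
    ids = set(lib.ids)
    for e in edits:
        if e.target not in ids:
            raise KeyError(f"edit targets unknown record {e.target!r}")

    current = {r.record_id: r for r in lib}
    audit_rows = []
    removed: set[str] = set()
    for e in edits:
        rec = current[e.target]
        if e.action == "relabel":
            if e.target in removed:
                raise ValueError(f"relabel after remove for {e.target!r}")
            if e.new_label == rec.species_label:
                raise ValueError(
                    f"relabel of {e.target!r} to its current label {e.new_label!r}"
                )
            audit_rows.append(
                {
                    "record_id": e.target,
                    "action": "relabel",
                    "old_label": rec.species_label,
                    "new_label": e.new_label,
                    "rationale": e.rationale,
                    "evidence": e.evidence,
                }
            )
            current[e.target] = copy_record(rec, species_label=e.new_label)
        else:
            audit_rows.append(
                {
                    "record_id": e.target,
                    "action": "remove",
                    "old_label": rec.species_label,
                    "new_label": "",
                    "rationale": e.rationale,
                    "evidence": e.evidence,
                }
            )
            removed.add(e.target)

    out = [current[r.record_id] for r in lib if r.record_id not in removed]
    new_lib = lib.with_records(out, "revision_removals", len(removed))
    return new_lib, pd.DataFrame(
        audit_rows,
        columns=["record_id", "action", "old_label", "new_label", "rationale", "evidence"],
    )


def invert_relabels(audit: pd.DataFrame) -> list[RevisionEdit]:
    """Edits that undo the relabels in an audit frame (removals are not undoable)."""
    inv = []
    for _, row in audit[audit["action"] == "relabel"].iterrows():
        inv.append(
            RevisionEdit("relabel", row["record_id"], new_label=row["old_label"],
                         rationale="revert", evidence="metadata")
        )
    return inv


def species_correct_ratios(per_species: pd.DataFrame) -> pd.Series:
    """Per-species correct/(total classified) ratio from a BCM summary table."""
    classified = per_species[["correct", "ambiguous", "incorrect", "no_id"]].sum(axis=1)
    ratios = per_species["correct"] / classified
    ratios.index = per_species["species"]
    return ratios.dropna()


@dataclass
class VersionComparison:
    """One-way ANOVA on quotient-normalised per-species correct ratios."""

    f_value: float
    p_value: float
    group_means: pd.Series
    normalized: pd.DataFrame  # long format: version, species, ratio, normalized


def compare_versions(
    version_ratios: dict[str, pd.Series],
    normalization: str = "per_version",
) -> VersionComparison:
    """Compare per-species correct-identification ratios across versions.

    Each version supplies a Series of per-species ratios in [0, 1].
    The ratios are quotient-transformed (divided by a mean) and the
    normalised species-level values are compared with a one-way
    fixed-effects ANOVA.  The design may be unbalanced: species absent
    from a version simply contribute nothing there.

    ``normalization="per_version"`` (default) divides each version's
    vector by its own mean.  Note that this forces every group mean to
    exactly 1, absorbing the very effect the ANOVA would test — it is
    useful for demonstrating that pure scale differences vanish, but
    F is ~0 by construction.  ``normalization="global"`` divides all
    ratios by the pooled mean, which leaves the F statistic identical
    to that of the raw ratios and is the variant to use for actual
    cross-version inference.
    """
    if len(version_ratios) < 2:
        raise ValueError("need at least two versions to compare")
    cleaned: dict[str, pd.Series] = {}
    for name, ratios in version_ratios.items():
        r = ratios.dropna()
        if ((r < 0) | (r > 1)).any():
            raise ValueError(f"version {name!r}: ratios must lie in [0, 1]")
        if len(r) == 0:
            continue  # version with nothing classifiable is excluded
        cleaned[name] = r
    common = set.intersection(*(set(r.index) for r in cleaned.values()))
    if len(common) < 3:
        raise ValueError("versions share fewer than 3 species")

    pooled_mean = np.concatenate([r.to_numpy() for r in cleaned.values()]).mean()
    long_rows = []
    groups = []
    for name, r in cleaned.items():
        mean = r.mean() if normalization == "per_version" else pooled_mean
        norm = r / mean if mean > 0 else r * np.nan
        groups.append(norm.to_numpy())
        for sp in r.index:
            long_rows.append(
                {"version": name, "species": sp, "ratio": r[sp], "normalized": norm[sp]}
            )
    allv = np.concatenate(groups)
    if np.allclose(allv, allv[0]):
        # degenerate 0/0 case: every normalised value identical -> no effect
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*groups)
        if np.isnan(f):
            f, p = 0.0, 1.0
    means = pd.Series({name: float(np.mean(g)) for name, g in zip(cleaned, groups)})
    return VersionComparison(
        f_value=float(f),
        p_value=float(p),
        group_means=means,
        normalized=pd.DataFrame(long_rows),
    )
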