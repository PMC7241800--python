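"""Best-close-match specimen identification.

Each sequence in the reference library is treated as a query against
all other sequences.  If the smallest distance to any neighbour exceeds
the identification threshold (or no distance is defined), the query
gets *no id*.  Otherwise the species labels of the neighbours at that
smallest distance decide the outcome: *correct* when they are exactly
the query's own label, *incorrect* when the query's label is absent
from the set, and *ambiguous* when the query's label is present
alongside others.  The tie set defaults to neighbours at exactly the
minimum distance; a wider variant treats every neighbour within the
threshold as a match candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from barcodeqc.distance import DistanceMatrix

CATEGORIES = ("correct", "ambiguous", "incorrect", "no_id")


@dataclass
class MatchClassification:
    """Best-close-match outcome for one sequence."""

    record_id: str
    species_label: str
    best_distance: float  # NaN when no neighbour has a defined distance
    best_match_species: frozenset[str]
    category: str


def _neighbour_sets(
    i: int,
    values: np.ndarray,
    labels_arr: np.ndarray,
    threshold: float,
    ties: str,
) -> tuple[float, frozenset[str]]:
    d = values[i].copy()
    d[i] = np.nan
    if np.all(np.isnan(d)):
        return np.nan, frozenset()
    best = np.nanmin(d)
    if best > threshold:
        return float(best), frozenset()
    if ties == "within_threshold":
        members = np.flatnonzero(d <= threshold)
    else:
        members = np.flatnonzero(d == best)
    return float(best), frozenset(labels_arr[members])


def classify_sequence(
    record_id: str,
    dm: DistanceMatrix,
    labels: Mapping[str, str],
    threshold: float,
    ties: Literal["strict", "within_threshold"] = "strict",
) -> MatchClassification:
    """Classify one sequence as correct / ambiguous / incorrect / no_id."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if record_id not in dm.ids:
        raise KeyError(f"record {record_id!r} absent from distance matrix")
    i = dm.index_of(record_id)
    labels_arr = np.array([labels[r] for r in dm.ids])
    best, species = _neighbour_sets(i, dm.values, labels_arr, threshold, ties)
    own = labels[record_id]
    if not species:
        category = "no_id"
    elif species == {own}:
        category = "correct"
    elif own not in species:
        category = "incorrect"
    else:
        category = "ambiguous"
    return MatchClassification(record_id, own, best, species, category)


def classify_library(
    dm: DistanceMatrix,
    labels: Mapping[str, str],
    threshold: float,
    ties: Literal["strict", "within_threshold"] = "strict",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every sequence and summarise per species.

    Returns
    -------
    per_sequence
        Columns: record_id, species_label, best_distance,
        best_match_species (semicolon-joined), category.
    per_species
        Columns: species, min_inter_dist, max_intra_dist, correct,
        ambiguous, incorrect, no_id — plus an ``overall`` attribute-free
        summary obtainable via :func:`overall_accuracy`.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    ids = dm.ids
    labels_arr = np.array([labels[r] for r in ids])
    rows = []
    for i, rid in enumerate(ids):
        best, species = _neighbour_sets(i, dm.values, labels_arr, threshold, ties)
        own = labels_arr[i]
        if not species:
            cat = "no_id"
        elif species == {own}:
            cat = "correct"
        elif own not in species:
            cat = "incorrect"
        else:
            cat = "ambiguous"
        rows.append(
            {
                "record_id": rid,
                "species_label": own,
                "best_distance": best,
                "best_match_species": ";".join(sorted(species)),
                "category": cat,
            }
        )
    per_seq = pd.DataFrame(rows)

    # per-species min interspecific / max intraspecific distances
    same = labels_arr[:, None] == labels_arr[None, :]
    np.fill_diagonal(same, False)
    stats_rows = []
    for sp in sorted(set(labels_arr)):
        mask = labels_arr == sp
        intra_block = dm.values[np.ix_(mask, mask)][same[np.ix_(mask, mask)]]
        inter_block = dm.values[np.ix_(mask, ~mask)]
        intra_ok = intra_block[~np.isnan(intra_block)]
        inter_ok = inter_block[~np.isnan(inter_block)]
        sub = per_seq[per_seq["species_label"] == sp]["category"]
        stats_rows.append(
            {
                "species": sp,
                "min_inter_dist": float(inter_ok.min()) if inter_ok.size else np.nan,
                "max_intra_dist": float(intra_ok.max()) if intra_ok.size else 0.0,
                **{cat: int((sub == cat).sum()) for cat in CATEGORIES},
            }
        )
    per_species = pd.DataFrame(stats_rows)
    return per_seq, per_species


def overall_accuracy(per_sequence: pd.DataFrame) -> dict:
    """Overall category counts and the correct-identification percentage."""
    counts = {cat: int((per_sequence["category"] == cat).sum()) for cat in CATEGORIES}
    total = len(per_sequence)
    counts["total"] = total
    counts["pct_correct"] = 100.0 * counts["correct"] / total if total else np.nan
    return counts
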