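"""Per-sequence barcoding-gap statistics and sampling-effect summaries.

For each sequence the maximum distance to a conspecific (``max_intra``)
and the minimum distance to an allospecific (``min_inter``) are
computed; the barcoding gap is *present* for the sequence iff
``min_inter - max_intra > 0`` — a tie counts as absence, since a query
equidistant from its own and another species cannot be identified.
Per-species absence counts and their relationship to sampling depth
(OLS regression of counts on the number of sequences per species, plus
a gaussian KDE of the sampling distribution) summarise how much of the
gap structure could be an artefact of uneven sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from barcodeqc.distance import DistanceMatrix


@dataclass
class GapReport:
    """Per-sequence and per-species barcoding-gap tables.

    ``per_sequence`` columns: record_id, species_label, max_intra,
    min_inter, singleton, gap_present.  ``per_species`` columns:
    species, n_sequences, n_gap_absent, n_gap_present.
    """

    per_sequence: pd.DataFrame
    per_species: pd.DataFrame
    singleton_policy: str = "zero"

    @property
    def n_gap_absent(self) -> int:
        return int((~self.per_sequence["gap_present"].astype(bool)).sum())


def collapse_to_binomial(label: str) -> str:
    """Collapse a trinomial (subspecies) label to its binomial."""
    parts = label.split()
    return " ".join(parts[:2]) if len(parts) > 2 else label


def gap_statistics(
    dm: DistanceMatrix,
    labels: Mapping[str, str],
    singleton_policy: Literal["zero", "exclude"] = "zero",
    collapse_subspecies: bool = False,
) -> GapReport:
    """Compute per-sequence barcoding-gap statistics.

    ``singleton_policy`` controls ``max_intra`` for species sampled
    once: ``"zero"`` (default, the convention of distance-based gap
    analyses — a singleton trivially has no intraspecific variation)
    or ``"exclude"`` (singleton rows get no gap call).  Missing
    distances are skipped.  Raises ``ValueError`` when the matrix holds
    a single species (no interspecific comparison exists).
    """
    ids = dm.ids
    lab = np.array(
        [collapse_to_binomial(labels[r]) if collapse_subspecies else labels[r] for r in ids]
    )
    if len(set(lab)) < 2:
        raise ValueError("gap analysis needs at least two species in the matrix")

    values = dm.values
    n = len(ids)
    same = lab[:, None] == lab[None, :]
    np.fill_diagonal(same, False)
    allo = ~same
    np.fill_diagonal(allo, False)

    rows = []
    for i in range(n):
        di = values[i]
        intra = di[same[i]]
        intra = intra[~np.isnan(intra)]
        inter = di[allo[i]]
        inter = inter[~np.isnan(inter)]
        singleton = not same[i].any()
        if singleton:
            max_intra = 0.0 if singleton_policy == "zero" else np.nan
        else:
            max_intra = float(intra.max()) if intra.size else np.nan
        min_inter = float(inter.min()) if inter.size else np.nan
        if np.isnan(max_intra) or np.isnan(min_inter):
            gap = np.nan
        else:
            gap = min_inter - max_intra > 0.0
        rows.append(
            {
                "record_id": ids[i],
                "species_label": lab[i],
                "max_intra": max_intra,
                "min_inter": min_inter,
                "singleton": singleton,
                "gap_present": gap,
            }
        )
    per_seq = pd.DataFrame(rows)

    grouped = per_seq.groupby("species_label", sort=True)
    per_species = pd.DataFrame(
        {
            "n_sequences": grouped.size(),
            "n_gap_absent": grouped["gap_present"].apply(
                lambda s: int((s == False).sum())  # noqa: E712 — NaN must not count
            ),
            "n_gap_present": grouped["gap_present"].apply(lambda s: int((s == True).sum())),  # noqa: E712
        }
    ).reset_index(names="species")
    return GapReport(per_seq, per_species, singleton_policy)


@dataclass
class SamplingEffectSummary:
    """OLS fits of gap absence/presence counts vs species sample size."""

    absence_fit: pd.Series
    presence_fit: pd.Series
    absence_kde: stats.gaussian_kde | None
    presence_kde: stats.gaussian_kde | None
    degenerate: bool = False


def _ols_counts(n: np.ndarray, y: np.ndarray) -> pd.Series:
    if np.all(y == 0):
        return pd.Series(
            {"slope": 0.0, "intercept": 0.0, "adj_r2": np.nan, "p_value": np.nan}
        )
    model = sm.OLS(y, sm.add_constant(n.astype(float))).fit()
    return pd.Series(
        {
            "slope": float(model.params[1]),
            "intercept": float(model.params[0]),
            "adj_r2": float(model.rsquared_adj),
            "p_value": float(model.f_pvalue),
        }
    )


def sampling_effect_summary(report: GapReport) -> SamplingEffectSummary:
    """Regress per-species gap absence/presence counts on sample size.

    Also returns gaussian KDEs (Silverman-type bandwidth, scipy's
    default) of the sample-size distribution weighted by absence and
    presence counts — the density of gap failures over sampling depth.
    Degenerate designs (all species equally sampled) are reported as
    such rather than fitted.
    """
    sp = report.per_species
    if len(sp) < 3:
        raise ValueError("sampling-effect summary needs >= 3 species")
    n = sp["n_sequences"].to_numpy()
    absent = sp["n_gap_absent"].to_numpy()
    present = sp["n_gap_present"].to_numpy()

    if np.unique(n).size == 1:
        empty = pd.Series({"slope": np.nan, "intercept": np.nan, "adj_r2": np.nan,
                           "p_value": np.nan})
        return SamplingEffectSummary(empty, empty, None, None, degenerate=True)

    def _kde(weights: np.ndarray) -> stats.gaussian_kde | None:
        if weights.sum() == 0:
            return None
        pts = np.repeat(n.astype(float), weights)
        if np.unique(pts).size < 2:
            return None
        return stats.gaussian_kde(pts)

    return SamplingEffectSummary(
        absence_fit=_ols_counts(n, absent),
        presence_fit=_ols_counts(n, present),
        absence_kde=_kde(absent),
        presence_kde=_kde(present),
    )
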