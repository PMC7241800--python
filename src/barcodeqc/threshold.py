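"""Identification-threshold optimisation from the distance density.

The pooled pairwise-distance distribution of a barcode library is
typically bimodal: an intraspecific mode near zero and an interspecific
mode an order of magnitude higher.  A gaussian kernel density estimate
over all defined pairwise distances is scanned for local minima; the
dip between the two modes marks the transition from intra- to
inter-specific divergence and is taken as the identification threshold.
No knowledge of species identity is needed.  Species represented by a
single sequence contribute no intraspecific distances and are removed
beforehand to avoid biasing the density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from barcodeqc.distance import DistanceMatrix
from barcodeqc.records import ReferenceLibrary

#: BOLD-style fixed threshold used when optimisation is disabled.
DEFAULT_FIXED_THRESHOLD = 0.01


class NoLocalMinimumError(RuntimeError):
    """The distance density is unimodal; fall back to a fixed threshold."""


@dataclass
class ThresholdResult:
    """Outcome of density-based threshold optimisation."""

    candidate_minima: list[float]
    selected: float
    bandwidth: float
    grid: np.ndarray = field(repr=False)
    density: np.ndarray = field(repr=False)
    removed_singletons: list[str] = field(default_factory=list)


def remove_singletons(lib: ReferenceLibrary) -> tuple[ReferenceLibrary, list[str]]:
    """Drop species represented by a single sequence.

    Returns the filtered library and the list of removed species names.
    """
    counts = lib.species_counts()
    singleton_species = sorted(counts.index[counts == 1])
    kept = [r for r in lib if r.species_label not in singleton_species]
    new = lib.with_records(kept, "remove_singletons", len(lib) - len(kept))
    return new, singleton_species


def nrd0_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, 0.9 min(sd, IQR/1.34) m^(-1/5).

    The convention used by R's ``density()`` (``bw.nrd0``), which the
    local-minima threshold method inherits; when the IQR is zero the sd
    is used alone, and a floor avoids a zero bandwidth on constant data.
    """
    x = np.asarray(x, dtype=float)
    m = x.size
    sd = x.std(ddof=1) if m > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread_candidates = [v for v in (sd, iqr / 1.34) if v > 0]
    spread = min(spread_candidates) if spread_candidates else abs(x).max() or 1.0
    return 0.9 * spread * m ** (-0.2)


def _gaussian_kde_on_grid(x: np.ndarray, bw: float, grid: np.ndarray) -> np.ndarray:
    # explicit evaluation so the bandwidth convention is exactly nrd0
    z = (grid[:, None] - x[None, :]) / bw
    return np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))


def optimise_threshold(
    dm: DistanceMatrix,
    n_grid: int = 512,
    bandwidth: float | None = None,
    rule: str = "smallest",
) -> ThresholdResult:
    """Find identification-threshold candidates as dips in the distance density.

    A gaussian KDE of all defined pairwise distances is evaluated on an
    ``n_grid``-point grid spanning ``[min - 3*bw, max + 3*bw]``;
    candidate thresholds are grid points strictly lower than both
    neighbours.  ``rule`` picks among them: ``"smallest"`` (default —
    the first dip after the intraspecific mode) or ``"deepest"``
    (lowest density).

    Raises
    ------
    NoLocalMinimumError
        When the density has no interior local minimum (unimodal data);
        callers should fall back to a fixed threshold.
    ValueError
        When fewer than two distinct defined distances exist.
    """
    x = dm.defined_distances()
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct defined distances")
    bw = bandwidth if bandwidth is not None else nrd0_bandwidth(x)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, n_grid)
    dens = _gaussian_kde_on_grid(x, bw, grid)

    lower_than_left = dens[1:-1] < dens[:-2]
    lower_than_right = dens[1:-1] < dens[2:]
    minima_idx = np.flatnonzero(lower_than_left & lower_than_right) + 1
    if minima_idx.size == 0:
        raise NoLocalMinimumError(
            "distance density is unimodal; use a fixed threshold instead"
        )
    candidates = [float(grid[i]) for i in minima_idx]
    if rule == "deepest":
        selected = float(grid[minima_idx[np.argmin(dens[minima_idx])]])
    elif rule == "smallest":
        selected = candidates[0]
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return ThresholdResult(
        candidate_minima=candidates,
        selected=selected,
        bandwidth=bw,
        grid=grid,
        density=dens,
    )
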