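"""Kimura-2-parameter distances with pairwise deletion.

For each sequence pair, alignment columns where either member carries a
gap, an ``N`` or any other non-A/C/G/T symbol are excluded (pairwise
deletion).  Over the n remaining columns, with P the transition
proportion and Q the transversion proportion,

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

The distance is undefined (recorded as NaN) when no columns remain or
when either logarithm's argument is non-positive (saturation); undefined
entries propagate as missing and are excluded from all downstream
density estimation, gap statistics and neighbor searches.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from barcodeqc.records import ReferenceLibrary

# encoding: A=0, C=1, G=2, T=3, everything else (gap/N/IUPAC ambiguity) = 4
_CODE = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i
    _CODE[ord(b.lower())] = i
_CODE[ord("U")] = 3
_CODE[ord("u")] = 3

_PURINE = np.array([True, False, True, False, False])


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (4 = missing)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _k2p_from_counts(n_valid: int, n_ts: int, n_tv: int) -> float:
    if n_valid == 0:
        return math.nan
    p = n_ts / n_valid
    q = n_tv / n_valid
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(a: str, b: str) -> tuple[float, int]:
    """K2P distance between two aligned sequences.

    Returns ``(distance, n_valid_sites)``; the distance is NaN when
    undefined (no shared unambiguous sites, or saturated).

    Raises
    ------
    ValueError
        If the sequences differ in length.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal sequence lengths: {len(a)} vs {len(b)}")
    ca, cb = encode(a), encode(b)
    valid = (ca < 4) & (cb < 4)
    n = int(valid.sum())
    da, db = ca[valid], cb[valid]
    diff = da != db
    same_class = _PURINE[da] == _PURINE[db]
    n_ts = int((diff & same_class).sum())
    n_tv = int((diff & ~same_class).sum())
    return _k2p_from_counts(n, n_ts, n_tv), n


class DistanceMatrix:
    """Symmetric pairwise distance matrix with missing-value support.

    ``values`` holds distances (NaN for undefined pairs) and
    ``valid_sites`` the per-pair count of compared columns.  The
    diagonal is zero by construction.
    """

    def __init__(self, ids: list[str], values: np.ndarray, valid_sites: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValueError("values shape does not match ids")
        if not np.allclose(np.nan_to_num(np.diag(values)), 0.0):
            raise ValueError("diagonal must be zero")
        self.ids = list(ids)
        self.values = values
        self.valid_sites = np.asarray(valid_sites)
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self._index[pair[0]], self._index[pair[1]]
        return float(self.values[i, j])

    def index_of(self, record_id: str) -> int:
        return self._index[record_id]

    @property
    def n_missing_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances (NaN included) in row-major order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def defined_distances(self) -> np.ndarray:
        d = self.condensed()
        return d[~np.isnan(d)]

    def subset(self, keep_ids: list[str]) -> "DistanceMatrix":
        idx = [self._index[r] for r in keep_ids]
        return DistanceMatrix(
            list(keep_ids), self.values[np.ix_(idx, idx)], self.valid_sites[np.ix_(idx, idx)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="record_id")

    def to_long_tsv(self, path: str | Path) -> None:
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append(
                    (self.ids[i], self.ids[j], self.values[i, j], int(self.valid_sites[i, j]))
                )
        pd.DataFrame(rows, columns=["id_a", "id_b", "distance", "valid_sites"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        values = df.to_numpy(dtype=float)
        return cls(ids, values, np.zeros_like(values, dtype=int))


def pairwise_matrix(lib: ReferenceLibrary) -> DistanceMatrix:
    """All-pairs K2P distance matrix for an aligned library.

    Vectorised: each record row is compared against all later rows at
    once, so the cost is O(N^2 L / lanes) rather than a per-site Python
    loop.
    """
    n = len(lib)
    if n == 0:
        return DistanceMatrix([], np.zeros((0, 0)), np.zeros((0, 0), dtype=int))
    lengths = {len(r.sequence) for r in lib}
    if len(lengths) != 1:
        raise ValueError("library is not aligned: sequences differ in length")

    codes = np.stack([encode(r.sequence) for r in lib])  # (n, L)
    is_valid = codes < 4
    purine = _PURINE[codes]

    values = np.zeros((n, n), dtype=float)
    sites = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        rest = slice(i + 1, n)
        both = is_valid[i] & is_valid[rest]          # (m, L)
        diff = (codes[i] != codes[rest]) & both
        same_class = purine[i] == purine[rest]
        n_valid = both.sum(axis=1)
        n_ts = (diff & same_class).sum(axis=1)
        n_tv = (diff & ~same_class).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_valid > 0, n_ts / np.maximum(n_valid, 1), np.nan)
            q = np.where(n_valid > 0, n_tv / np.maximum(n_valid, 1), np.nan)
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            d = np.where(
                (w1 > 0) & (w2 > 0), -0.5 * np.log(np.abs(w1)) - 0.25 * np.log(np.abs(w2)),
                np.nan,
            )
        values[i, rest] = d
        values[rest, i] = d
        sites[i, rest] = n_valid
        sites[rest, i] = n_valid
    return DistanceMatrix(lib.ids, values, sites)


def intra_inter_split(
    dm: DistanceMatrix, labels: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Defined pairwise distances split into within- and between-species sets."""
    lab = np.array([labels[r] for r in dm.ids])
    iu = np.triu_indices(len(dm.ids), k=1)
    d = dm.values[iu]
    same = lab[iu[0]] == lab[iu[1]]
    ok = ~np.isnan(d)
    return d[same & ok], d[~same & ok]
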