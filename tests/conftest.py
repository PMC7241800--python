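import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from barcodeqc.distance import DistanceMatrix
from barcodeqc.records import BarcodeRecord, ReferenceLibrary
from barcodeqc.simulate import SimulationConfig, simulate_library


@pytest.fixture(scope="session")
def clean_library():
    """Well-separated 10-species library without mislabels."""
    cfg = SimulationConfig(
        n_species=10,
        seqs_per_species=5,
        seq_length=400,
        intra_divergence_scale=0.01,
        inter_divergence_scale=0.15,
        seed=42,
    )
    return simulate_library(cfg)


@pytest.fixture(scope="session")
def clean_matrix(clean_library):
    from barcodeqc.distance import pairwise_matrix

    lib, _ = clean_library
    return pairwise_matrix(lib)


def matrix_from_dict(ids, dist, default=np.nan):
    """Build a DistanceMatrix from an unordered-pair dict (tests only)."""
    n = len(ids)
    values = np.full((n, n), default, dtype=float)
    np.fill_diagonal(values, 0.0)
    index = {r: i for i, r in enumerate(ids)}
    for (a, b), v in dist.items():
        values[index[a], index[b]] = v
        values[index[b], index[a]] = v
    return DistanceMatrix(list(ids), values, np.zeros((n, n), dtype=int))


def tiny_record(rid, label, seq="ACGT" * 100, **kw):
    return BarcodeRecord(record_id=rid, species_label=label, sequence=seq, **kw)


def tiny_library(records):
    return ReferenceLibrary(records)
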