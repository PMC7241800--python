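"""Synthetic barcode libraries with known ground truth.

Sequences are evolved along a star-of-stars genealogy: a single random
root sequence, one ancestor per species at depth ``inter_divergence_scale/2``
from the root, and tips at depth ``intra_divergence_scale/2`` from their
species ancestor.  Substitutions follow the Kimura two-rate model
(transition rate alpha, transversion rate beta per target, kappa =
alpha/beta), so the K2P distance estimator is unbiased for the simulated
branch lengths: two conspecific tips are separated by an expected
``intra_divergence_scale`` substitutions per site, two allospecific tips
by ``inter_divergence_scale + intra_divergence_scale`` (the inter scale
dominates by construction).

Ground truth — each record's true species and whether its stored label
was swapped — is returned alongside the library, which is what makes
mislabel-detection rates measurable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from barcodeqc.records import BarcodeRecord, ReferenceLibrary

_BASES = np.array(list("ACGT"))
# index encoding: A=0, C=1, G=2, T=3; transitions are A<->G and C<->T.
_TRANSITION_PARTNER = np.array([2, 3, 0, 1])


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of a simulated reference library.

    ``seqs_per_species`` is either a single int (same count for every
    species, singletons allowed via 1) or an explicit per-species list.
    ``intra_divergence_scale`` / ``inter_divergence_scale`` are expected
    K2P distances (substitutions per site) within and between species;
    the inter scale must exceed the intra scale for a distance valley to
    exist.  ``mislabel_fraction`` of records get their stored label
    swapped uniformly to another species; the sequence itself is never
    altered (label errors model misidentification, not sequencing
    artifacts).  ``ambiguous_base_fraction`` replaces bases with ``N``
    independently per site to exercise pairwise deletion.
    """

    n_species: int = 20
    seqs_per_species: int | Sequence[int] = 10
    seq_length: int = 658
    intra_divergence_scale: float = 0.01
    inter_divergence_scale: float = 0.15
    kappa: float = 2.0
    mislabel_fraction: float = 0.0
    ambiguous_base_fraction: float = 0.0
    seed: int = 0

    def counts(self) -> list[int]:
        if isinstance(self.seqs_per_species, int):
            return [self.seqs_per_species] * self.n_species
        return list(self.seqs_per_species)

    def validate(self) -> None:
        if self.n_species < 2:
            raise ConfigurationError("n_species must be >= 2")
        if self.seq_length < 100:
            raise ConfigurationError("seq_length must be >= 100")
        if not 0 <= self.mislabel_fraction < 0.5:
            raise ConfigurationError("mislabel_fraction must be in [0, 0.5)")
        if not self.intra_divergence_scale < self.inter_divergence_scale:
            raise ConfigurationError(
                "intra_divergence_scale must be < inter_divergence_scale"
            )
        counts = self.counts()
        if len(counts) != self.n_species:
            raise ConfigurationError(
                f"seqs_per_species has {len(counts)} entries for {self.n_species} species"
            )
        if any(c < 1 for c in counts):
            raise ConfigurationError("every species needs >= 1 sequence")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be > 0")


def _k80_transition_probs(branch_length: float, kappa: float) -> tuple[float, float]:
    """Per-site probabilities of (transition, each single transversion).

    For the two-rate model with transition rate alpha and rate beta to
    each of the two transversion targets, the branch length (expected
    substitutions/site) is d = (alpha + 2 beta) t.  With kappa =
    alpha/beta this gives beta*t = d/(kappa+2):

        P(transition)        = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2(alpha+beta) t}
        P(one transversion)  = 1/4 - 1/4 e^{-4 beta t}
    """
    bt = branch_length / (kappa + 2.0)
    at = kappa * bt
    e1 = np.exp(-4.0 * bt)
    e2 = np.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 - 0.25 * e1
    return p_ts, p_tv_each


def _evolve(seq: np.ndarray, branch_length: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence along one branch of the two-rate model."""
    p_ts, p_tv = _k80_transition_probs(branch_length, kappa)
    u = rng.random(seq.shape[0])
    out = seq.copy()
    ts_mask = u < p_ts
    out[ts_mask] = _TRANSITION_PARTNER[seq[ts_mask]]
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
    # transversion targets: the two bases of the other purine/pyrimidine class
    out[tv1] = (seq[tv1] + 1) % 4
    out[tv2] = (seq[tv2] + 3) % 4
    return out


def simulate_library(config: SimulationConfig) -> tuple[ReferenceLibrary, pd.DataFrame]:
    """Generate a library and its truth table.

    Returns
    -------
    library
        :class:`ReferenceLibrary` whose records carry the *stored*
        (possibly swapped) species labels.
    truth
        DataFrame with columns ``record_id``, ``true_species``,
        ``species_label`` and boolean ``mislabeled``; exactly
        ``round(mislabel_fraction * N)`` rows are mislabeled.

    The output is deterministic given the config (including the seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = config.counts()
    n_total = sum(counts)

    root = rng.integers(0, 4, size=config.seq_length)
    species_names = [f"Species_{i + 1:03d}" for i in range(config.n_species)]

    records: list[BarcodeRecord] = []
    true_species: list[str] = []
    for sp_idx, (name, n_seqs) in enumerate(zip(species_names, counts)):
        ancestor = _evolve(root, config.inter_divergence_scale / 2.0, config.kappa, rng)
        for k in range(n_seqs):
            tip = _evolve(ancestor, config.intra_divergence_scale / 2.0, config.kappa, rng)
            chars = _BASES[tip].copy()
            if config.ambiguous_base_fraction > 0:
                mask = rng.random(config.seq_length) < config.ambiguous_base_fraction
                chars[mask] = "N"
            rid = f"SIM{sp_idx + 1:03d}_{k + 1:03d}"
            records.append(
                BarcodeRecord(
                    record_id=rid,
                    species_label=name,
                    sequence="".join(chars),
                    accession=rid,
                    source="novel",
                )
            )
            true_species.append(name)

    # swap stored labels on exactly round(f * N) records
    n_mislabel = int(round(config.mislabel_fraction * n_total))
    mislabeled = np.zeros(n_total, dtype=bool)
    if n_mislabel:
        chosen = rng.choice(n_total, size=n_mislabel, replace=False)
        for idx in chosen:
            others = [s for s in species_names if s != true_species[idx]]
            records[idx] = BarcodeRecord(
                record_id=records[idx].record_id,
                species_label=others[rng.integers(len(others))],
                sequence=records[idx].sequence,
                accession=records[idx].accession,
                source=records[idx].source,
            )
            mislabeled[idx] = True

    truth = pd.DataFrame(
        {
            "record_id": [r.record_id for r in records],
            "true_species": true_species,
            "species_label": [r.species_label for r in records],
            "mislabeled": mislabeled,
        }
    )
    library = ReferenceLibrary(records, alignment_length=config.seq_length)
    return library, truth


def heavy_tailed_counts(
    n_species: int,
    mean: float = 10.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> list[int]:
    """Per-species sample sizes with a heavy right tail and singletons.

    Draws from a geometric-like distribution (shifted so singletons are
    common) mimicking the skew of real repositories, where one or two
    species dominate and many are represented once.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    p = 1.0 / max(mean, 1.0 + 1e-9)
    return [int(c) for c in rng.geometric(p, size=n_species)]


def write_simulation(
    library: ReferenceLibrary, truth: pd.DataFrame, out_dir: str | Path
) -> None:
    """Write FASTA, metadata TSV and truth-table TSV for a simulated library."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library.to_fasta(out / "library.fasta")
    meta = library.to_metadata_frame().merge(
        truth[["record_id", "true_species", "mislabeled"]], on="record_id"
    )
    meta.to_csv(out / "metadata.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
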