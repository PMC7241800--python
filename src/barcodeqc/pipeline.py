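"""End-to-end orchestration: build -> distances -> gap -> threshold -> BCM
-> tree consistency -> revision -> version comparison.

A :class:`PipelineConfig` fixes every analysis choice (threshold mode,
singleton policy, tie semantics, cluster linkage, subspecies handling)
so that a run is fully reproducible from its config; every stage's
table is written to the output directory and the combined summary is
assembled only from those persisted intermediates.

Three conventional presets mirror the common QC protocol: ``original``
(fixed 1% threshold, singletons retained), ``optimal-threshold``
(density-minimum threshold after singleton removal) and ``final``
(optimised threshold re-run after curation edits).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from barcodeqc import bcm, gap, revision, threshold, treecheck
from barcodeqc.distance import DistanceMatrix, pairwise_matrix
from barcodeqc.records import ReferenceLibrary

log = logging.getLogger("barcodeqc")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    fasta: str | Path | None = None
    metadata: str | Path | None = None
    out_dir: str | Path = "barcodeqc_out"
    threshold_mode: str = "fixed"  # "fixed" | "optimise"
    fixed_threshold: float = threshold.DEFAULT_FIXED_THRESHOLD
    remove_singletons: bool = False
    singleton_policy: str = "zero"
    collapse_subspecies: bool = False
    bcm_ties: str = "strict"
    cluster_linkage: str = "single"
    edits: str | Path | None = None
    min_informative_length: int = 300
    seed: int = 0
    name: str = "run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    @classmethod
    def preset(cls, which: str, **overrides) -> "PipelineConfig":
        base = {
            "original": dict(name="original", threshold_mode="fixed",
                             fixed_threshold=0.01, remove_singletons=False),
            "optimal-threshold": dict(name="optimal-threshold",
                                      threshold_mode="optimise",
                                      remove_singletons=True),
            "final": dict(name="final", threshold_mode="optimise",
                          remove_singletons=True),
        }[which]
        base.update(overrides)
        return cls(**base)


@dataclass
class PipelineResult:
    """Everything a run produced, with the machine-readable summary."""

    library: ReferenceLibrary
    distance_matrix: DistanceMatrix
    gap_report: gap.GapReport
    threshold_used: float
    threshold_result: threshold.ThresholdResult | None
    bcm_per_sequence: object
    bcm_per_species: object
    consistency: treecheck.ConsistencyReport
    summary: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig, library: ReferenceLibrary | None = None
) -> PipelineResult:
    """Run every analysis stage on a library and persist all artifacts.

    The library is read from ``config.fasta``/``config.metadata`` unless
    passed directly.  Raises :class:`StageError` naming the failing
    stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 — rewrap with stage name
            raise StageError(name, exc) from exc

    if library is None:
        if config.fasta is None:
            raise StageError("load", ValueError("no library and no fasta path given"))
        library = stage(
            "load", lambda: ReferenceLibrary.from_fasta(config.fasta, config.metadata)
        )

    if config.edits:
        edits = stage("read_edits", lambda: revision.read_edits(config.edits))
        library, audit = stage("apply_edits", lambda: revision.apply_edits(library, edits))
        audit.to_csv(out / "edits_audit.tsv", sep="\t", index=False)

    removed_singletons: list[str] = []
    if config.remove_singletons:
        library, removed_singletons = stage(
            "remove_singletons", lambda: threshold.remove_singletons(library)
        )

    library.to_fasta(out / "library.fasta")
    library.to_metadata_tsv(out / "metadata.tsv")

    dm = stage("distances", lambda: pairwise_matrix(library))
    dm.to_tsv(out / "distances.tsv")

    labels = library.labels
    gap_report = stage(
        "gap",
        lambda: gap.gap_statistics(
            dm,
            labels,
            singleton_policy=config.singleton_policy,
            collapse_subspecies=config.collapse_subspecies,
        ),
    )
    gap_report.per_sequence.to_csv(out / "gap_per_sequence.tsv", sep="\t", index=False)
    gap_report.per_species.to_csv(out / "gap_per_species.tsv", sep="\t", index=False)

    thr_result = None
    if config.threshold_mode == "optimise":
        thr_result = stage("threshold", lambda: threshold.optimise_threshold(dm))
        thr = thr_result.selected
    else:
        thr = config.fixed_threshold

    per_seq, per_species = stage(
        "bcm", lambda: bcm.classify_library(dm, labels, thr, ties=config.bcm_ties)
    )
    per_seq.to_csv(out / "bcm_per_sequence.tsv", sep="\t", index=False)
    per_species.to_csv(out / "bcm_per_species.tsv", sep="\t", index=False)

    tree = stage("nj_tree", lambda: treecheck.nj_tree(dm))
    tree.write(str(out / "nj_tree.nwk"))
    clusters = stage(
        "clusters",
        lambda: treecheck.threshold_clusters(dm, thr, linkage_method=config.cluster_linkage),
    )
    clusters.rename_axis("record_id").to_frame().to_csv(out / "clusters.tsv", sep="\t")
    consistency = stage(
        "consistency", lambda: treecheck.consistency_report(tree, clusters, labels)
    )
    consistency.per_species.to_csv(out / "consistency_per_species.tsv", sep="\t", index=False)

    overall = bcm.overall_accuracy(per_seq)
    summary = {
        "name": config.name,
        "n_records": len(library),
        "n_species": int(library.species_counts().size),
        "threshold": float(thr),
        "threshold_mode": config.threshold_mode,
        "removed_singleton_species": removed_singletons,
        "bcm": overall,
        "n_gap_absent": gap_report.n_gap_absent,
        "n_heterospecific_clusters": consistency.n_heterospecific_clusters,
        "n_species_split_across_clusters": consistency.n_species_split_across_clusters,
        "total_flagged_tci": int(consistency.per_species["tci"].sum()),
        "total_flagged_cl_het": int(consistency.per_species["cl_het"].sum()),
        "n_missing_distance_pairs": dm.n_missing_pairs,
        "seed": config.seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return PipelineResult(
        library=library,
        distance_matrix=dm,
        gap_report=gap_report,
        threshold_used=float(thr),
        threshold_result=thr_result,
        bcm_per_sequence=per_seq,
        bcm_per_species=per_species,
        consistency=consistency,
        summary=summary,
    )


def configure_logging(logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
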