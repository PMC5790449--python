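"""End-to-end pipeline: simulate -> preprocess -> phase 1 -> phase 2 ->
normalize/batch-center -> census -> stability -> classify.

Each stage writes its TSV/JSON artifacts under the output directory and the
run finishes with a machine-readable ``manifest.json`` carrying the seed,
parameters and per-stage read accounting. Samples are processed one at a
time through the read-level stages so memory stays bounded.
"""

from __future__ import annotations

import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
import yaml

from . import __version__
from .census import detect_features, paired_correlation, pca_embed, top_expressed, venn_partition
from .classify import chi_square_merit, merit_frame, train_evaluate
from .io import iter_fastq, read_tsv, write_fastq, write_json, write_tsv
from .matrix import CountMatrix
from .mirna import (
    accumulate_isomir_support,
    build_mirna_counts,
    calls_from_support,
    isomirs_to_frame,
)
from .normalize import batch_center, normalize_counts, size_factors
from .preprocess import PreprocessConfig, preprocess_reads
from .simulate import (
    Cohort,
    GroundTruth,
    SimulationConfig,
    build_reference,
    iter_sample_reads,
    simulate_truth_counts,
    write_reference,
)
from .sncrna import build_sncrna_counts
from .stability import reference_report, stability_rank, records_to_frame


@dataclass
class PipelineConfig:
    """Everything a run needs; all randomness flows from ``seed``."""

    out_dir: str = "rnacensus_out"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    fastq_dir: str | None = None  # optional: reuse existing simulated FASTQs
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    max_mismatches: int = 3
    max_genome_mismatches: int = 2
    min_overlap: float = 0.9
    detection_threshold: float = 20.0
    isomir_support: int = 20
    batch_method: str = "median-center"  # or "none"
    top_k: int = 10
    folds: int = 10
    n_trees: int = 500
    bins: int = 10
    write_intermediate: bool = True

    def __post_init__(self) -> None:
        if self.batch_method not in ("median-center", "none"):
            raise ValueError("batch_method must be 'median-center' or 'none'")
        self.simulation.seed = self.seed
        self.preprocess.adapter = self.simulation.adapter

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        return cls(simulation=sim, preprocess=pre, **raw)


def _iter_cohort_reads(
    config: PipelineConfig, truth: GroundTruth, bundle
) -> Iterator[tuple[str, list[tuple[str, str, str]]]]:
    if config.fastq_dir is not None:
        fastq_dir = Path(config.fastq_dir)
        for sid in truth.sample_sheet["sample_id"]:
            yield sid, list(iter_fastq(fastq_dir / f"{sid}.fastq"))
    else:
        yield from iter_sample_reads(config.simulation, bundle, truth)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            "max_mismatches": config.max_mismatches,
            "max_genome_mismatches": config.max_genome_mismatches,
            "min_overlap": config.min_overlap,
            "detection_threshold": config.detection_threshold,
            "isomir_support": config.isomir_support,
            "batch_method": config.batch_method,
            "min_length": config.preprocess.min_length,
            "quality_threshold": config.preprocess.quality_threshold,
            "adapter": config.preprocess.adapter,
        },
        "stages": [],
        "warnings": [],
    }

    def stage(name: str, **info) -> None:
        manifest["stages"].append({"name": name, **info})

    # --- reference + truth ---------------------------------------------
    sim = config.simulation
    bundle = build_reference(sim)
    write_reference(bundle, out / "reference")
    if config.fastq_dir is not None:
        sheet = read_tsv(Path(config.fastq_dir) / "sample_sheet.tsv")
        truth_counts = read_tsv(Path(config.fastq_dir) / "truth_counts.tsv", index_col="feature")
        from .simulate import planted_sets

        truth = GroundTruth(counts=truth_counts, sample_sheet=sheet, planted=planted_sets(sim, bundle))
    else:
        truth = simulate_truth_counts(sim, bundle)
    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    write_tsv(reads_dir / "sample_sheet.tsv", truth.sample_sheet)
    write_tsv(reads_dir / "truth_counts.tsv", truth.counts, index_label="feature")
    stage("simulate", n_samples=len(truth.sample_sheet), depth=sim.depth)

    # --- per-sample read stages ----------------------------------------
    (out / "preprocess").mkdir(exist_ok=True)
    (out / "mirna").mkdir(exist_ok=True)
    (out / "sncrna").mkdir(exist_ok=True)
    trim_rows = []
    mirna_cols: dict[str, pd.Series] = {}
    phase1_rows = []
    phase2_rows = []
    snc_cols: dict[str, pd.Series] = {}
    isomir_support: dict[tuple, dict[str, int]] = {}
    mirna_matrix = None
    snc_matrix = None
    sheet = truth.sample_sheet
    for sid, raw_reads in _iter_cohort_reads(config, truth, bundle):
        if config.write_intermediate and config.fastq_dir is None:
            write_fastq(reads_dir / f"{sid}.fastq", raw_reads)
        clean, report = preprocess_reads(raw_reads, config.preprocess)
        trim_rows.append({"sample_id": sid, **vars(report)})
        one_sheet = sheet[sheet["sample_id"] == sid]
        p1 = build_mirna_counts({sid: clean}, bundle, one_sheet, config.max_mismatches)
        seqs = {r.id: r.sequence for r in clean}
        accumulate_isomir_support(sid, p1.aligned[sid], bundle, isomir_support, seqs)
        mirna_cols[sid] = p1.matrix.counts[sid]
        phase1_rows.append(p1.report.loc[sid].to_dict() | {"sample_id": sid})
        p2 = build_sncrna_counts(
            {sid: p1.unmapped[sid]}, bundle, one_sheet,
            config.max_genome_mismatches, config.min_overlap,
        )
        snc_cols[sid] = p2.matrix.counts[sid]
        phase2_rows.append(p2.report.loc[sid].to_dict() | {"sample_id": sid})
        if config.write_intermediate:
            write_fastq(
                out / "sncrna" / f"{sid}.unassigned.fastq",
                ((r.id, r.sequence, r.quality) for r in p2.unassigned[sid]),
            )
    trim_report = pd.DataFrame(trim_rows).set_index("sample_id")
    write_tsv(out / "preprocess" / "trim_report.tsv", trim_report, index_label="sample_id")
    mirna_counts = pd.DataFrame(mirna_cols)
    snc_counts = pd.DataFrame(snc_cols)
    mirna_matrix = CountMatrix.from_sheet(mirna_counts, sheet)
    snc_matrix = CountMatrix.from_sheet(snc_counts, sheet)
    phase1_report = pd.DataFrame(phase1_rows).set_index("sample_id")
    phase2_report = pd.DataFrame(phase2_rows).set_index("sample_id")
    write_tsv(out / "mirna" / "counts.tsv", mirna_counts, index_label="feature")
    write_tsv(out / "mirna" / "alignment_report.tsv", phase1_report, index_label="sample_id")
    write_tsv(out / "sncrna" / "counts.tsv", snc_counts, index_label="feature")
    write_tsv(out / "sncrna" / "alignment_report.tsv", phase2_report, index_label="sample_id")
    stage(
        "preprocess",
        n_input=int(trim_report["n_input"].sum()),
        n_retained=int(trim_report["n_retained"].sum()),
    )
    stage(
        "mirna_quant",
        n_aligned=int(phase1_report["n_aligned"].sum()),
        n_unmapped=int(phase1_report["n_unmapped"].sum()),
        reads_aligned_min=int(phase1_report["n_aligned"].min()),
        reads_aligned_max=int(phase1_report["n_aligned"].max()),
        reads_aligned_mean=float(phase1_report["n_aligned"].mean()),
    )
    stage(
        "sncrna_quant",
        n_genome_mapped=int(phase2_report["n_genome_mapped"].sum()),
        n_assigned=int(phase2_report["n_assigned"].sum()),
        n_genome_unmapped=int(phase2_report["n_genome_unmapped"].sum()),
    )

    # --- isomiRs --------------------------------------------------------
    specimens_of = dict(zip(sheet["sample_id"], sheet["specimen"]))
    calls = calls_from_support(isomir_support, specimens_of, config.isomir_support)
    write_tsv(out / "mirna" / "isomirs.tsv", isomirs_to_frame(calls))
    stage("isomir", n_calls=len(calls))

    # --- normalization + batch centering --------------------------------
    (out / "normalized").mkdir(exist_ok=True)
    batches = dict(zip(sheet["sample_id"], sheet["batch"]))
    normalized = {}
    for label, matrix in (("mirna", mirna_matrix), ("sncrna", snc_matrix)):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            factors = size_factors(matrix)
            nm = normalize_counts(matrix, factors)
            if config.batch_method == "median-center":
                nm = batch_center(nm, batches)
            else:
                nm.notes.append("batch correction disabled by configuration")
        manifest["warnings"].extend(str(w.message) for w in caught)
        normalized[label] = nm
        write_tsv(out / "normalized" / f"{label}_normalized.tsv", nm.values, index_label="feature")
        write_tsv(
            out / "normalized" / f"{label}_size_factors.tsv",
            factors.to_frame(), index_label="sample_id",
        )
    stage(
        "normalize",
        batch_corrected={k: v.batch_corrected for k, v in normalized.items()},
        notes={k: v.notes for k, v in normalized.items()},
    )

    # --- census ----------------------------------------------------------
    (out / "census").mkdir(exist_ok=True)
    detections = {}
    venns = {}
    for label, nm in normalized.items():
        table = detect_features(nm, threshold=config.detection_threshold)
        detections[label] = table
        venn = venn_partition(table)
        venns[label] = venn
        write_tsv(out / "census" / f"detection_{label}.tsv", table.frame, index_label="feature")
        write_json(out / "census" / f"venn_{label}.json", venn.counts)
        cells = pd.DataFrame(
            [
                {"pattern": "+".join(sorted(cell)), "feature": f}
                for cell, feats in sorted(venn.cells.items(), key=lambda kv: sorted(kv[0]))
                for f in sorted(feats)
            ],
            columns=["pattern", "feature"],
        )
        write_tsv(out / "census" / f"venn_cells_{label}.tsv", cells)
        tops = []
        for group in table.groups:
            top = top_expressed(nm, group, config.top_k).reset_index()
            top["specimen"] = group
            tops.append(top)
        write_tsv(out / "census" / f"top_expressed_{label}.tsv", pd.concat(tops, ignore_index=True))
        detected = list(table.detected_anywhere())
        if len(detected) >= 2:
            coords, explained = pca_embed(nm, features=detected)
            write_tsv(out / "census" / f"pca_{label}.tsv", coords, index_label="sample_id")
            write_json(
                out / "census" / f"pca_{label}_variance.json",
                {"explained_variance": [float(v) for v in explained]},
            )
        for pair in (("plasma", "stool"), ("plasma", "urine")):
            pairs = truth.pairs(*pair)
            both = [
                f
                for f in detected
                if f in table.detected_in(pair[0]) and f in table.detected_in(pair[1])
            ] if set(pair) <= set(table.groups) else []
            if len(pairs) >= 3 and both:
                corr = paired_correlation(nm, pairs, pair, features=both)
                write_tsv(
                    out / "census" / f"paired_{label}_{pair[0]}_{pair[1]}.tsv",
                    corr, index_label="feature",
                )
        stage(
            f"census_{label}",
            n_detected=len(detected),
            venn=venn.counts,
        )

    # --- stability --------------------------------------------------------
    (out / "stability").mkdir(exist_ok=True)
    for label, nm in normalized.items():
        table = detections[label]
        venn = venns[label]
        records = []
        for group in table.groups:
            candidates = sorted(venn.singletons().get(group, set()))
            if not candidates:
                continue
            records.extend(stability_rank(nm, group, candidates))
        write_tsv(out / "stability" / f"stability_{label}.tsv", records_to_frame(records))
        write_tsv(
            out / "stability" / f"reference_report_{label}.tsv",
            reference_report(records, config.top_k),
        )
    stage("stability")

    # --- classification ---------------------------------------------------
    (out / "classify").mkdir(exist_ok=True)
    for label, nm in normalized.items():
        detected = list(detections[label].detected_anywhere())
        if len(detected) < 2:
            continue
        sub = nm.values.loc[detected]
        labels = nm.specimen_groups()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            report = train_evaluate(sub, labels, seed=config.seed, folds=config.folds,
                                    n_trees=config.n_trees)
        manifest["warnings"].extend(str(w.message) for w in caught)
        write_json(out / "classify" / f"report_{label}.json", report.to_dict())
        merits = chi_square_merit(sub, labels, bins=config.bins)
        write_tsv(out / "classify" / f"merit_{label}.tsv", merit_frame(merits))
        stage(f"classify_{label}", accuracy=report.accuracy,
              n_misclassified=report.n_misclassified)

    write_json(out / "manifest.json", manifest)
    return manifest
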