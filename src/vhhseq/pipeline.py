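"""End-to-end orchestration: QC/merge -> characterize -> regions -> compare."""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrichment import ComparisonReport, compare_libraries, enrichment_frame
from .library import (
    ClusterSet,
    LibraryStats,
    cluster_exact,
    compute_library_stats,
    filter_functional,
    translate,
)
from .readprep import (
    MergedSequence,
    ProcessingConfig,
    ProcessingReport,
    process_fastq_pair,
    write_merged_fasta,
)
from .reference import ReferenceConstruct, default_reference
from .regions import position_profile, rank_mutations


@dataclass
class PipelineConfig:
    """Configuration for a full pre/post comparison run."""

    reference_fasta: str | None = None
    region_yaml: str | None = None
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    region: str = "CDR3"
    aa_positions: tuple[int, ...] = (1, 2, 4, 6, 9)
    error_threshold_pct: float = 0.1
    pid_threshold_pct: float = 95.0
    top_k_mutations: int = 5
    seed: int = 0

    def load_reference(self) -> ReferenceConstruct:
        if self.reference_fasta and self.region_yaml:
            return ReferenceConstruct.from_files(self.reference_fasta, self.region_yaml)
        if self.reference_fasta or self.region_yaml:
            raise ValueError("reference_fasta and region_yaml must be given together")
        return default_reference()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        processing = ProcessingConfig(**raw.pop("processing", {}))
        if "aa_positions" in raw:
            raw["aa_positions"] = tuple(raw["aa_positions"])
        return cls(processing=processing, **raw)


@dataclass
class LibraryCharacterization:
    """All per-library stage outputs needed downstream."""

    label: str
    raw_pairs: int
    processing_report: ProcessingReport | None
    merged_sequences: list[str]
    nt_clusters: ClusterSet
    functional_sequences: list[str]
    aa_clusters: ClusterSet
    stats: LibraryStats


def characterize_library(
    merged_sequences: list[str],
    ref: ReferenceConstruct,
    raw_pairs: int | None = None,
    label: str = "library",
    processing_report: ProcessingReport | None = None,
) -> LibraryCharacterization:
    """Translate, filter, cluster and tabulate one merged library."""
    if raw_pairs is None:
        raw_pairs = len(merged_sequences)
    nt_clusters = cluster_exact(merged_sequences, level="nucleotide")
    translated = [translate(seq, ref.frame_offset) for seq in merged_sequences]
    functional, _low_quality = filter_functional(translated)
    aa_clusters = cluster_exact(functional, level="amino_acid")
    stats = compute_library_stats(
        raw_pairs, merged_sequences, nt_clusters, functional, aa_clusters
    )
    return LibraryCharacterization(
        label=label,
        raw_pairs=raw_pairs,
        processing_report=processing_report,
        merged_sequences=merged_sequences,
        nt_clusters=nt_clusters,
        functional_sequences=functional,
        aa_clusters=aa_clusters,
        stats=stats,
    )


def process_and_characterize(
    forward_fastq: str | Path,
    reverse_fastq: str | Path,
    ref: ReferenceConstruct,
    cfg: ProcessingConfig,
    label: str,
) -> LibraryCharacterization:
    for path in (forward_fastq, reverse_fastq):
        if not Path(path).exists():
            raise FileNotFoundError(f"qc-merge stage: missing FASTQ input {path}")
    merged, report = process_fastq_pair(forward_fastq, reverse_fastq, cfg)
    return characterize_library(
        [m.bases for m in merged],
        ref,
        raw_pairs=report.raw_pairs,
        label=label,
        processing_report=report,
    )


def run_pipeline(
    config: PipelineConfig,
    pre_fastq_pair: tuple[str | Path, str | Path],
    post_fastq_pair: tuple[str | Path, str | Path],
    out_dir: str | Path,
    log=sys.stderr,
) -> ComparisonReport:
    """Run the full pipeline over both libraries and write every output.

    Outputs under ``out_dir``: merged FASTA, processing report JSON,
    library statistics TSV and cluster tables per library; region profile
    and mutation-rank TSVs at nucleotide and amino-acid level; the
    comparison (stats, histogram, codon enrichment) TSVs; and a manifest
    recording parameters and versions so a rerun is reproducible.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = config.load_reference()
    libraries: dict[str, LibraryCharacterization] = {}
    for label, pair in (("pre", pre_fastq_pair), ("post", post_fastq_pair)):
        lib = process_and_characterize(pair[0], pair[1], ref, config.processing, label)
        libraries[label] = lib
        print(
            f"[{label}] raw={lib.raw_pairs} merged={len(lib.merged_sequences)} "
            f"nt_clusters={lib.nt_clusters.n_clusters} "
            f"functional={len(lib.functional_sequences)} "
            f"aa_clusters={lib.aa_clusters.n_clusters}",
            file=log,
        )
        write_merged_fasta(
            [MergedSequence(f"{label}_{i}", s, f"{label}_{i}")
             for i, s in enumerate(lib.merged_sequences)],
            out / f"{label}_merged.fasta",
        )
        if lib.processing_report is not None:
            lib.processing_report.write_json(out / f"{label}_processing.json")
        lib.stats.write_tsv(out / f"{label}_stats.tsv")
        lib.nt_clusters.write_tsv(out / f"{label}_nt_clusters.tsv")
        lib.aa_clusters.write_tsv(out / f"{label}_aa_clusters.tsv")
        for level, denominator in (("nt", "reads"), ("aa", "clusters")):
            pool = lib.nt_clusters if level == "nt" else lib.aa_clusters
            profile = position_profile(
                pool, config.region, ref, level=level, denominator=denominator
            )
            profile.write_tsv(out / f"{label}_{config.region}_{level}_profile.tsv")
            ranked = rank_mutations(profile, config.top_k_mutations)
            if ranked:
                import pandas as pd

                pd.DataFrame([vars(m) for m in ranked]).to_csv(
                    out / f"{label}_{config.region}_{level}_top_mutations.tsv",
                    sep="\t", index=False,
                )

    report = compare_libraries(
        libraries["pre"],
        libraries["post"],
        ref,
        aa_positions=list(config.aa_positions),
        error_threshold_pct=config.error_threshold_pct,
        pid_threshold_pct=config.pid_threshold_pct,
        region=config.region,
    )
    report.stats_frame().to_csv(out / "comparison_stats.tsv", sep="\t")
    for label, hist in report.copy_number_histograms.items():
        hist.to_csv(out / f"{label}_copy_number_histogram.tsv", sep="\t", index=False)
    if report.codon_records:
        enrichment_frame(report.codon_records).to_csv(
            out / "codon_enrichment.tsv", sep="\t", index=False
        )
    manifest = {
        "vhhseq_version": __version__,
        "python": sys.version.split()[0],
        "reference_id": ref.id,
        "reference_length": len(ref.sequence),
        "config": {
            "region": config.region,
            "aa_positions": list(config.aa_positions),
            "error_threshold_pct": config.error_threshold_pct,
            "pid_threshold_pct": config.pid_threshold_pct,
            "top_k_mutations": config.top_k_mutations,
            "seed": config.seed,
            "processing": vars(config.processing) | {"adapters": list(config.processing.adapters)},
        },
        "inputs": {
            "pre": [str(p) for p in pre_fastq_pair],
            "post": [str(p) for p in post_fastq_pair],
        },
        "counts": {
            label: lib.stats.to_series().to_dict() for label, lib in libraries.items()
        },
        "diversity_delta_pct": report.diversity_delta_pct,
        "reference_region_fractions": report.reference_region_fractions,
        "conserved_positions": report.conserved_positions,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report
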