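"""Translation, functional filtering, exact clustering and library statistics.

The characterization ledger mirrors the standard two-column comparison of a
pre- and a post-selection antibody library: merged read counts, nucleotide
and amino-acid cluster counts (clusters are exact-identity equivalence
classes), the functional fraction (translations without stop codons), and
DNA/protein diversity percentages.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .reference import ReferenceConstruct
from .seqops import pct, round_half_up, translate

__all__ = [
    "ClusterSet",
    "LibraryStats",
    "translate",
    "filter_functional",
    "cluster_exact",
    "compute_library_stats",
    "length_deviation_fraction",
]


@dataclass
class ClusterSet:
    """Deduplicated sequence pool with per-cluster copy counts."""

    level: str  # "nucleotide" | "amino_acid"
    clusters: dict[str, int]

    def __post_init__(self) -> None:
        if self.level not in ("nucleotide", "amino_acid"):
            raise ValueError(f"unknown cluster level {self.level!r}")
        for seq, count in self.clusters.items():
            if count < 1:
                raise ValueError(f"cluster {seq[:12]}... has non-positive count")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def total_sequences(self) -> int:
        return sum(self.clusters.values())

    @property
    def single_occurrence(self) -> int:
        return sum(1 for c in self.clusters.values() if c == 1)

    @property
    def multi_copy(self) -> int:
        return self.n_clusters - self.single_occurrence

    def to_frame(self) -> pd.DataFrame:
        """Clusters as a (sequence, copies) table, largest first."""
        rows = sorted(self.clusters.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["sequence", "copies"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def cluster_exact(seqs: Iterable[str], level: str = "nucleotide") -> ClusterSet:
    """Cluster sequences at 100% identity (exact string equality).

    ``N``/``X`` are literal symbols here: two sequences differing only in
    an ambiguous base fall into different clusters, i.e. the merged pool is
    deduplicated exactly as written.
    """
    return ClusterSet(level, dict(Counter(seqs)))


def filter_functional(aa_seqs: Iterable[str]) -> tuple[list[str], int]:
    """Split translated sequences into functional (stop-free) and low-quality.

    Returns the retained sequences and the number removed; the partition is
    exact, so ``len(functional) + low_quality == len(input)``.
    """
    functional: list[str] = []
    low_quality = 0
    for seq in aa_seqs:
        if "*" in seq:
            low_quality += 1
        else:
            functional.append(seq)
    return functional, low_quality


@dataclass
class LibraryStats:
    """The library characterization ledger.

    Percentages are rounded half-up to two decimals; ``headline`` exposes
    the 0-decimal diversity figures used in summary reporting.  The
    protein-diversity denominator is the functional (translated, stop-free)
    pool, the denominator consistent with every published worked example.
    """

    raw_reads: int
    merged_reads: int
    nt_clusters: int
    functional_sequences: int
    low_quality_sequences: int
    aa_clusters: int
    single_occurrence_clusters: int
    multi_copy_clusters: int
    dna_diversity_pct: float
    protein_diversity_pct: float
    functional_pct: float
    low_quality_pct: float
    single_occurrence_pct_of_clusters: float
    single_occurrence_pct_of_translated: float
    multi_copy_pct_of_clusters: float
    multi_copy_pct_of_translated: float

    @property
    def headline(self) -> dict[str, int]:
        return {
            "dna_diversity_pct": int(round_half_up(self.dna_diversity_pct, 0)),
            "protein_diversity_pct": int(round_half_up(self.protein_diversity_pct, 0)),
        }

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))

    def write_tsv(self, path: str | Path) -> None:
        self.to_series().rename("value").to_csv(path, sep="\t")


def _as_count(value) -> int:
    return value if isinstance(value, int) else len(value)


def compute_library_stats(
    raw_reads: int,
    merged,
    nt_clusters: ClusterSet | int,
    functional,
    aa_clusters: ClusterSet,
) -> LibraryStats:
    """Fill the statistics ledger from the pipeline stage outputs.

    ``merged`` and ``functional`` may be counts or sequence collections;
    ``nt_clusters`` may be a ClusterSet or a plain cluster count.
    """
    merged_count = _as_count(merged)
    functional_count = _as_count(functional)
    nt_cluster_count = (
        nt_clusters.n_clusters if isinstance(nt_clusters, ClusterSet) else nt_clusters
    )
    if merged_count == 0:
        raise ZeroDivisionError("zero denominator: merged_reads")
    if functional_count == 0:
        raise ZeroDivisionError("zero denominator: functional_sequences")
    if aa_clusters.n_clusters == 0:
        raise ZeroDivisionError("zero denominator: aa_clusters")
    low_quality = merged_count - functional_count
    single = aa_clusters.single_occurrence
    multi = aa_clusters.multi_copy
    return LibraryStats(
        raw_reads=raw_reads,
        merged_reads=merged_count,
        nt_clusters=nt_cluster_count,
        functional_sequences=functional_count,
        low_quality_sequences=low_quality,
        aa_clusters=aa_clusters.n_clusters,
        single_occurrence_clusters=single,
        multi_copy_clusters=multi,
        dna_diversity_pct=pct(nt_cluster_count, merged_count),
        protein_diversity_pct=pct(aa_clusters.n_clusters, functional_count),
        functional_pct=pct(functional_count, merged_count),
        low_quality_pct=pct(low_quality, merged_count),
        single_occurrence_pct_of_clusters=pct(single, aa_clusters.n_clusters),
        single_occurrence_pct_of_translated=pct(single, functional_count),
        multi_copy_pct_of_clusters=pct(multi, aa_clusters.n_clusters),
        multi_copy_pct_of_translated=pct(multi, functional_count),
    )


def length_deviation_fraction(
    nt_clusters: ClusterSet, ref: ReferenceConstruct
) -> float:
    """Percent of sequences (count-weighted) whose length differs from the reference."""
    total = nt_clusters.total_sequences
    if total == 0:
        raise ValueError("empty cluster set")
    deviant = sum(
        count
        for seq, count in nt_clusters.clusters.items()
        if len(seq) != len(ref.sequence)
    )
    return pct(deviant, total)
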