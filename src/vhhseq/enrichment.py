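"""Pre- vs post-selection comparison and synonymous codon enrichment.

After a selection round the library is expected to lose diversity and to
enrich specific clones.  Beyond the library-statistics delta and the
cluster copy-number histogram, the discriminating signal is codon-level:
independent enrichment of several synonymous codons for the same
amino-acid replacement indicates selection acting on the protein rather
than sequencing noise.  Codon frequencies whose post-selection value sits
below the sequencing error rate (default 0.1% for MiSeq chemistry) are
flagged as not significantly enriched.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .library import ClusterSet, LibraryStats
from .reference import ReferenceConstruct
from .regions import position_profile, region_pool
from .seqops import CODON_TO_AA, round_half_up


@dataclass
class CodonEnrichmentRecord:
    """Frequency of one codon at one CDR3 position in both libraries."""

    aa_position: int  # 1-based within CDR3
    codon: str
    encoded_aa: str
    freq_pre_pct: float
    freq_post_pct: float
    fold_enrichment: float  # inf when the codon is absent pre-selection
    significant: bool

    def rounded(self) -> dict:
        fold = (
            math.inf
            if math.isinf(self.fold_enrichment)
            else round_half_up(self.fold_enrichment, 2)
        )
        return {
            "aa_position": self.aa_position,
            "codon": self.codon,
            "encoded_aa": self.encoded_aa,
            "freq_pre_pct": round_half_up(self.freq_pre_pct, 2),
            "freq_post_pct": round_half_up(self.freq_post_pct, 2),
            "fold_enrichment": fold,
            "significant": self.significant,
        }


def fold_enrichment(freq_pre_pct: float, freq_post_pct: float) -> float:
    """Post/pre frequency ratio; infinite for codons new to the post pool."""
    if freq_pre_pct == 0:
        return math.inf if freq_post_pct > 0 else 0.0
    return freq_post_pct / freq_pre_pct


def is_significant(freq_post_pct: float, error_threshold_pct: float = 0.1) -> bool:
    """Enrichment calls require the post frequency to clear the sequencing
    error rate; the rule applies to the post-selection frequency only."""
    return freq_post_pct >= error_threshold_pct


def codon_position_frequencies(
    nt_clusters: ClusterSet,
    ref: ReferenceConstruct,
    aa_positions: list[int],
    region: str = "CDR3",
) -> tuple[dict[int, dict[str, float]], dict[int, int], int]:
    """Per-position codon frequencies over cluster representatives.

    Returns ``(frequencies, ambiguous_counts, n_clusters)``: frequencies are
    percentages of all clusters in the set; clusters whose codon at a
    position contains N or is disrupted by a gap are excluded from the
    numerators and tallied in ``ambiguous_counts``.
    """
    start, end = ref.region(region)
    n_aa = (end - start) // 3
    for p in aa_positions:
        if not 1 <= p <= n_aa:
            raise ValueError(f"amino-acid position {p} outside {region} (1..{n_aa})")
    extracted = region_pool(nt_clusters, region, ref, level="nt")
    n_clusters = len(extracted)
    freqs: dict[int, dict[str, float]] = {p: {} for p in aa_positions}
    ambiguous: dict[int, int] = {p: 0 for p in aa_positions}
    counts: dict[int, Counter] = {p: Counter() for p in aa_positions}
    for seq, _copies, has_gap in extracted:
        for p in aa_positions:
            codon = seq[3 * (p - 1) : 3 * p]
            if has_gap or len(codon) < 3 or "N" in codon:
                ambiguous[p] += 1
            else:
                counts[p][codon] += 1
    for p in aa_positions:
        freqs[p] = {
            codon: 100.0 * n / n_clusters for codon, n in sorted(counts[p].items())
        }
    return freqs, ambiguous, n_clusters


def codon_enrichment(
    pre_nt_clusters: ClusterSet,
    post_nt_clusters: ClusterSet,
    ref: ReferenceConstruct,
    aa_positions: list[int],
    error_threshold_pct: float = 0.1,
    region: str = "CDR3",
) -> list[CodonEnrichmentRecord]:
    """Codon-level enrichment between the two clustered nucleotide pools.

    Frequencies are percentages of clusters containing each codon at each
    requested CDR3 amino-acid position; fold enrichment is post/pre.
    Records are sorted by position then codon.
    """
    pre, _, _ = codon_position_frequencies(pre_nt_clusters, ref, aa_positions, region)
    post, _, _ = codon_position_frequencies(post_nt_clusters, ref, aa_positions, region)
    records: list[CodonEnrichmentRecord] = []
    for p in aa_positions:
        for codon in sorted(set(pre[p]) | set(post[p])):
            f_pre = pre[p].get(codon, 0.0)
            f_post = post[p].get(codon, 0.0)
            records.append(
                CodonEnrichmentRecord(
                    aa_position=p,
                    codon=codon,
                    encoded_aa=CODON_TO_AA[codon],
                    freq_pre_pct=f_pre,
                    freq_post_pct=f_post,
                    fold_enrichment=fold_enrichment(f_pre, f_post),
                    significant=is_significant(f_post, error_threshold_pct),
                )
            )
    records.sort(key=lambda r: (r.aa_position, r.codon))
    return records


def enrichment_frame(records: list[CodonEnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.rounded() for r in records])


def copy_number_histogram(
    clusters: ClusterSet, max_bucket: int = 10
) -> pd.DataFrame:
    """Cluster counts bucketed by copy number (1, 2, ..., >=max_bucket).

    The percent column is relative to the number of clusters, so the
    single-copy bucket matches the single-occurrence cluster percentage of
    the library statistics ledger.
    """
    if clusters.n_clusters == 0:
        raise ValueError("empty cluster set")
    tallies = Counter(
        min(count, max_bucket) for count in clusters.clusters.values()
    )
    rows = []
    for bucket in range(1, max_bucket + 1):
        label = str(bucket) if bucket < max_bucket else f">={max_bucket}"
        n = tallies.get(bucket, 0)
        rows.append(
            {
                "copies": label,
                "clusters": n,
                "pct_of_clusters": round_half_up(100.0 * n / clusters.n_clusters, 2),
            }
        )
    frame = pd.DataFrame(rows)
    assert frame["clusters"].sum() == clusters.n_clusters
    return frame


@dataclass
class ComparisonReport:
    """Side-by-side report of a pre- and a post-selection library."""

    pre_stats: LibraryStats
    post_stats: LibraryStats
    diversity_delta_pct: float
    copy_number_histograms: dict[str, pd.DataFrame]
    reference_region_fractions: dict[str, float]
    conserved_positions: list[int]
    codon_records: list[CodonEnrichmentRecord] = field(default_factory=list)

    def stats_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre_selection": self.pre_stats.to_series(),
                "post_selection": self.post_stats.to_series(),
            }
        )


def compare_libraries(
    pre,
    post,
    ref: ReferenceConstruct,
    aa_positions: list[int] | None = None,
    error_threshold_pct: float = 0.1,
    pid_threshold_pct: float = 95.0,
    region: str = "CDR3",
) -> ComparisonReport:
    """Assemble the full pre/post comparison.

    ``pre`` and ``post`` are :class:`~vhhseq.pipeline.LibraryCharacterization`
    bundles.  The diversity delta is the drop in protein diversity
    (percentage points); conserved positions are CDR3 amino acids with
    PID above ``pid_threshold_pct`` in both pools (cluster-weighted).
    """
    for label, lib in (("pre", pre), ("post", post)):
        for stage in ("stats", "nt_clusters", "aa_clusters", "merged_sequences"):
            if getattr(lib, stage, None) is None:
                raise ValueError(f"{label} library is missing stage output: {stage}")
    delta = round_half_up(
        pre.stats.protein_diversity_pct - post.stats.protein_diversity_pct, 2
    )
    histograms = {
        "pre_selection": copy_number_histogram(pre.aa_clusters),
        "post_selection": copy_number_histogram(post.aa_clusters),
    }
    fractions = {
        "pre_reads_nt": reference_region_fraction_cached(pre, region, ref, "nt", "reads"),
        "post_reads_nt": reference_region_fraction_cached(post, region, ref, "nt", "reads"),
        "pre_clusters_aa": reference_region_fraction_cached(pre, region, ref, "aa", "clusters"),
        "post_clusters_aa": reference_region_fraction_cached(post, region, ref, "aa", "clusters"),
    }
    conserved = []
    pre_profile = position_profile(
        pre.aa_clusters, region, ref, level="aa", denominator="clusters"
    )
    post_profile = position_profile(
        post.aa_clusters, region, ref, level="aa", denominator="clusters"
    )
    for i in range(len(pre_profile.pid)):
        if (
            pre_profile.pid[i] > pid_threshold_pct
            and post_profile.pid[i] > pid_threshold_pct
        ):
            conserved.append(i + 1)
    records: list[CodonEnrichmentRecord] = []
    if aa_positions:
        records = codon_enrichment(
            pre.nt_clusters, post.nt_clusters, ref, aa_positions,
            error_threshold_pct, region,
        )
    return ComparisonReport(
        pre_stats=pre.stats,
        post_stats=post.stats,
        diversity_delta_pct=delta,
        copy_number_histograms=histograms,
        reference_region_fractions=fractions,
        conserved_positions=conserved,
        codon_records=records,
    )


def reference_region_fraction_cached(lib, region, ref, level, denominator) -> float:
    """Reference-region fraction from a characterization bundle."""
    from .regions import reference_region_fraction

    pool = lib.nt_clusters if level == "nt" else lib.aa_clusters
    return round_half_up(
        reference_region_fraction(pool, region, ref, level, denominator), 2
    )
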