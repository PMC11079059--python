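"""Alignment to the reference and per-region positional analyses.

Every pool sequence (or cluster representative) is aligned pairwise to the
reference construct with a global affine-gap aligner; region sequences are
read off the reference columns of the alignment.  From the extracted
regions the module computes per-position symbol frequencies, percent
identity to the reference (PID), sequence-logo information content in
bits, ranked mutation lists, and per-clone mutation reports annotated
with region, transition/transversion class and synonymous status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from Bio import Align

from .library import ClusterSet
from .reference import ReferenceConstruct
from .seqops import (
    AMINO_ACIDS,
    NUCLEOTIDES,
    is_transition,
    round_half_up,
    translate,
)

# Global affine-gap scoring: match +1, mismatch -1, gap open -4 (charged on
# the first gapped position), gap extend -1.  End gaps are penalized.
_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1
_ALIGNER.mismatch_score = -1
_ALIGNER.open_gap_score = -4
_ALIGNER.extend_gap_score = -1


@dataclass
class PairwiseAlignment:
    """A query aligned globally against the reference."""

    aligned_ref: str
    aligned_query: str
    score: float
    substitutions: list[tuple[int, str, str]]
    insertions: list[tuple[int, str, str]]
    deletions: list[tuple[int, str, str]]

    @property
    def is_identity(self) -> bool:
        return not (self.substitutions or self.insertions or self.deletions)


class RegionExtract(NamedTuple):
    sequence: str
    has_gap: bool


def _ref_string(ref: ReferenceConstruct | str, level: str) -> str:
    if isinstance(ref, str):
        return ref
    return ref.sequence if level == "nt" else ref.aa_sequence


def _columns_to_alignment(aligned_ref: str, aligned_query: str, score: float) -> PairwiseAlignment:
    subs: list[tuple[int, str, str]] = []
    ins: list[tuple[int, str, str]] = []
    dels: list[tuple[int, str, str]] = []
    ref_pos = 0
    for r, q in zip(aligned_ref, aligned_query):
        if r == "-":
            ins.append((ref_pos, "-", q))
        elif q == "-":
            dels.append((ref_pos, r, "-"))
            ref_pos += 1
        else:
            if r != q:
                subs.append((ref_pos, r, q))
            ref_pos += 1
    return PairwiseAlignment(aligned_ref, aligned_query, score, subs, ins, dels)


def align_to_reference(
    query: str, ref: ReferenceConstruct | str, level: str = "nt"
) -> PairwiseAlignment:
    """Global affine-gap alignment of a query to the reference sequence."""
    if not query:
        raise ValueError("empty query")
    ref_seq = _ref_string(ref, level)
    aln = _ALIGNER.align(ref_seq, query)[0]
    return _columns_to_alignment(aln[0], aln[1], float(aln.score))


def _fast_or_full_alignment(query: str, ref_seq: str) -> PairwiseAlignment:
    """Identity-mapped alignment for near-reference equal-length queries.

    Equal-length sequences within 20% mismatches cannot profit from gap
    placement under the affine scoring used here, so the gap-free column
    mapping is the optimal alignment and the dynamic program is skipped.
    """
    if len(query) == len(ref_seq):
        mismatches = sum(a != b for a, b in zip(ref_seq, query))
        if mismatches <= 0.2 * len(ref_seq):
            score = float(len(ref_seq) - 2 * mismatches)
            return _columns_to_alignment(ref_seq, query, score)
    return align_to_reference(query, ref_seq)


def extract_region(
    alignment: PairwiseAlignment,
    region: str,
    ref: ReferenceConstruct,
    level: str = "nt",
) -> RegionExtract:
    """Query sequence over the reference columns of a region.

    Gaps are dropped from the returned sequence but flagged: a deletion in
    the region or an insertion strictly inside it sets ``has_gap``.
    """
    if level == "nt":
        start, end = ref.region(region)
    else:
        start, end = ref.region_aa_bounds(region)
    chars: list[str] = []
    has_gap = False
    ref_pos = 0
    for r, q in zip(alignment.aligned_ref, alignment.aligned_query):
        if r == "-":
            if start < ref_pos < end:
                has_gap = True
            continue
        if start <= ref_pos < end:
            if q == "-":
                has_gap = True
            else:
                chars.append(q)
        ref_pos += 1
        if ref_pos >= end:
            break
    return RegionExtract("".join(chars), has_gap)


def _pool_items(pool) -> list[tuple[str, int]]:
    """Normalize a pool argument to (sequence, copy count) pairs."""
    if isinstance(pool, ClusterSet):
        return list(pool.clusters.items())
    if isinstance(pool, dict):
        return list(pool.items())
    return [(seq, 1) for seq in pool]


def region_pool(
    pool,
    region: str,
    ref: ReferenceConstruct,
    level: str = "nt",
) -> list[tuple[str, int, bool]]:
    """Extract a region from every pool member: (region_seq, copies, has_gap)."""
    ref_seq = _ref_string(ref, level)
    out = []
    for seq, count in _pool_items(pool):
        aln = _fast_or_full_alignment(seq, ref_seq)
        extract = extract_region(aln, region, ref, level)
        out.append((extract.sequence, count, extract.has_gap))
    return out


@dataclass
class PositionProfile:
    """Per-position composition of a region across a pool.

    ``frequencies`` is a positions x symbols table in percent of the
    counted units (reads or clusters); ``pid`` is the per-position percent
    identity to the reference symbol; ``information_bits`` is
    ``log2(|alphabet|)`` minus the Shannon entropy of the canonical-symbol
    frequencies renormalized after removing the ambiguous (N/X) mass,
    whose percentage is reported separately in ``ambiguous_pct``.
    """

    region: str
    level: str
    denominator: str
    ref_symbols: str
    frequencies: pd.DataFrame
    pid: np.ndarray
    region_mean_pid: float
    information_bits: np.ndarray
    ambiguous_pct: np.ndarray
    total_units: int
    excluded_units: int

    def to_frame(self) -> pd.DataFrame:
        table = self.frequencies.copy()
        table.insert(0, "ref", list(self.ref_symbols))
        table["pid"] = np.round(self.pid, 2)
        table["bits"] = np.round(self.information_bits, 4)
        table["ambiguous_pct"] = np.round(self.ambiguous_pct, 2)
        return table

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="position")


def position_profile(
    pool,
    region: str,
    ref: ReferenceConstruct,
    level: str = "nt",
    denominator: str = "reads",
) -> PositionProfile:
    """Per-position symbol frequencies, PID and information content.

    ``denominator="reads"`` weights each sequence by its copy count;
    ``"clusters"`` counts each distinct sequence once.  Units whose
    extracted region is gapped or of deviant length are excluded from the
    tallies and reported in ``excluded_units``.
    """
    items = region_pool(pool, region, ref, level)
    if not items:
        raise ValueError("empty pool")
    ref_region = (
        ref.region_nt(region) if level == "nt" else ref.region_aa(region)
    )
    length = len(ref_region)
    canonical = NUCLEOTIDES if level == "nt" else AMINO_ACIDS
    ambiguous_symbol = "N" if level == "nt" else "X"

    counts: list[dict[str, float]] = [dict() for _ in range(length)]
    total = 0
    excluded = 0
    for seq, copies, has_gap in items:
        weight = copies if denominator == "reads" else 1
        if has_gap or len(seq) != length:
            excluded += weight
            continue
        total += weight
        for i, symbol in enumerate(seq):
            counts[i][symbol] = counts[i].get(symbol, 0) + weight
    if total == 0:
        raise ValueError("no region-length units in pool")

    symbols = sorted({s for c in counts for s in c} | set(canonical))
    col = {s: j for j, s in enumerate(symbols)}
    matrix = np.zeros((length, len(symbols)))
    for i, c in enumerate(counts):
        for symbol, n in c.items():
            matrix[i, col[symbol]] = 100.0 * n / total
    freq = pd.DataFrame(
        matrix, index=pd.RangeIndex(1, length + 1, name="position"), columns=symbols
    )

    pid = np.array([matrix[i, col[ref_region[i]]] for i in range(length)])
    ambiguous = (
        matrix[:, col[ambiguous_symbol]].copy()
        if ambiguous_symbol in col
        else np.zeros(length)
    )
    bits = np.zeros(length)
    log2_a = math.log2(len(canonical))
    canon_cols = [col[s] for s in canonical]
    for i in range(length):
        canon = matrix[i, canon_cols]
        mass = canon.sum()
        if mass > 0:
            p = canon[canon > 0] / mass
            bits[i] = log2_a + float(np.sum(p * np.log2(p)))
    return PositionProfile(
        region=region,
        level=level,
        denominator=denominator,
        ref_symbols=ref_region,
        frequencies=freq,
        pid=pid,
        region_mean_pid=float(np.mean(pid)),
        information_bits=bits,
        ambiguous_pct=ambiguous,
        total_units=total,
        excluded_units=excluded,
    )


@dataclass
class MutationRecord:
    region: str
    position: int  # 1-based within region
    reference_symbol: str
    observed_symbol: str
    frequency_pct: float
    denominator: str


def rank_mutations(profile: PositionProfile, top_k: int = 5) -> list[MutationRecord]:
    """Most frequent non-reference, non-ambiguous symbols across the region.

    Sorted by frequency descending, then position ascending, then symbol.
    """
    ambiguous_symbol = "N" if profile.level == "nt" else "X"
    records: list[MutationRecord] = []
    for i, position in enumerate(profile.frequencies.index):
        ref_symbol = profile.ref_symbols[i]
        for symbol in profile.frequencies.columns:
            if symbol in (ref_symbol, ambiguous_symbol, "-", "*"):
                continue
            f = float(profile.frequencies.loc[position, symbol])
            if f > 0:
                records.append(
                    MutationRecord(
                        profile.region, int(position), ref_symbol, symbol,
                        round_half_up(f, 2), profile.denominator,
                    )
                )
    records.sort(key=lambda m: (-m.frequency_pct, m.position, m.observed_symbol))
    return records[:top_k]


@dataclass
class CloneMutation:
    """One mutation of a clone relative to the reference, annotated."""

    nt_position: int  # 1-based on the reference
    region: str | None
    ref_symbol: str
    observed_symbol: str
    mutation_class: str  # transition | transversion | insertion | deletion
    synonymous: bool | None
    ref_codon: str | None = None
    observed_codon: str | None = None
    ref_aa: str | None = None
    observed_aa: str | None = None
    in_primer: bool = False


def clone_report(clone_seq: str, ref: ReferenceConstruct) -> list[CloneMutation]:
    """Mutation listing for one clone against the reference.

    Substitutions are classified as transition/transversion and as
    synonymous or not from their codon context (single-substitution
    replacement within the reference codon); indels are reported with
    ``synonymous=None``.
    """
    aln = align_to_reference(clone_seq, ref, level="nt")
    records: list[CloneMutation] = []
    for pos, r, q in aln.substitutions:
        codon_ref = codon_obs = aa_ref = aa_obs = None
        synonymous = None
        if q in NUCLEOTIDES and pos >= ref.frame_offset:
            codon_index = (pos - ref.frame_offset) // 3
            codon_start = ref.frame_offset + 3 * codon_index
            if codon_start + 3 <= len(ref.sequence):
                codon_ref = ref.sequence[codon_start : codon_start + 3]
                offset = pos - codon_start
                codon_obs = codon_ref[:offset] + q + codon_ref[offset + 1 :]
                aa_ref = translate(codon_ref)
                aa_obs = translate(codon_obs)
                synonymous = aa_ref == aa_obs
        mutation_class = (
            "transition"
            if q in NUCLEOTIDES and is_transition(r, q)
            else "transversion"
            if q in NUCLEOTIDES
            else "ambiguous"
        )
        records.append(
            CloneMutation(
                nt_position=pos + 1,
                region=ref.region_of_position(pos),
                ref_symbol=r,
                observed_symbol=q,
                mutation_class=mutation_class,
                synonymous=synonymous,
                ref_codon=codon_ref,
                observed_codon=codon_obs,
                ref_aa=aa_ref,
                observed_aa=aa_obs,
                in_primer=ref.in_primer(pos),
            )
        )
    for pos, r, q in aln.deletions:
        records.append(
            CloneMutation(pos + 1, ref.region_of_position(pos), r, "-", "deletion",
                          None, in_primer=ref.in_primer(pos))
        )
    for pos, r, q in aln.insertions:
        region = ref.region_of_position(pos) if pos < len(ref.sequence) else None
        records.append(
            CloneMutation(pos + 1, region, "-", q, "insertion", None,
                          in_primer=ref.in_primer(min(pos, len(ref.sequence) - 1)))
        )
    records.sort(key=lambda m: m.nt_position)
    return records


def clone_report_frame(clone_seq: str, ref: ReferenceConstruct) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in clone_report(clone_seq, ref)])


def reference_region_fraction(
    pool,
    region: str,
    ref: ReferenceConstruct,
    level: str = "nt",
    denominator: str = "reads",
) -> float:
    """Percent of units whose extracted region equals the reference exactly.

    Ambiguous symbols and gapped extractions count as non-matching; the
    denominator is all units in the pool.
    """
    items = region_pool(pool, region, ref, level)
    if not items:
        raise ValueError("empty pool")
    ref_region = ref.region_nt(region) if level == "nt" else ref.region_aa(region)
    total = 0
    matching = 0
    for seq, copies, has_gap in items:
        weight = copies if denominator == "reads" else 1
        total += weight
        if not has_gap and seq == ref_region:
            matching += weight
    return 100.0 * matching / total
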