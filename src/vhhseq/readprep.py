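"""Read QC and paired-end merging.

Native implementation of the amplicon pre-processing stage: adapter
removal, sliding-window quality trimming (mean Phred >= Q25 over 5-base
windows, reads < 150 bases dropped), and overlap-based merging of forward
and reverse mates into a single amplicon sequence.  Disagreements inside
the overlap are resolved by base quality; equal-quality disagreements
emit ``N``, the only source of ambiguous bases the pipeline itself
introduces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqops import revcomp


@dataclass
class ReadRecord:
    id: str
    bases: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.bases) != self.qualities.size:
            raise ValueError(f"read {self.id}: bases/qualities length mismatch")
        if self.qualities.size and (
            self.qualities.min() < 0 or self.qualities.max() > 60
        ):
            raise ValueError(f"read {self.id}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ProcessingConfig:
    """Knobs for QC and merging (defaults follow common MiSeq practice)."""

    quality_threshold: int = 25
    quality_window: int = 5
    min_length: int = 150
    adapters: tuple[str, ...] = ()
    min_overlap: int = 11
    max_overlap_mismatch_fraction: float = 1.0 / 3.0
    tie_policy: str = "N"

    def __post_init__(self) -> None:
        if self.quality_window < 1:
            raise ValueError("quality_window must be >= 1")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0.0 <= self.max_overlap_mismatch_fraction <= 1.0:
            raise ValueError("max_overlap_mismatch_fraction must be in [0, 1]")


@dataclass
class MergedSequence:
    id: str
    bases: str
    source_pair: str


@dataclass
class ProcessingReport:
    """Per-run QC ledger; raw always equals merged + discarded + unmerged."""

    raw_pairs: int = 0
    merged: int = 0
    discarded_short: int = 0
    unmerged: int = 0

    def reconciles(self) -> bool:
        return self.raw_pairs == self.merged + self.discarded_short + self.unmerged

    def to_dict(self) -> dict[str, int]:
        return {
            "raw_pairs": self.raw_pairs,
            "merged": self.merged,
            "discarded_short": self.discarded_short,
            "unmerged": self.unmerged,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def remove_adapter(
    read: ReadRecord, adapters: tuple[str, ...], min_overlap: int = 11
) -> ReadRecord:
    """Cut the read at the first adapter occurrence, if any.

    An adapter is recognized when a prefix of it of at least
    ``min_overlap`` bases matches the read (allowing one mismatch per ten
    compared bases); everything from the match position onward is removed.
    The read is returned unchanged when no adapter is found.
    """
    if not adapters:
        return read
    best_cut = len(read.bases)
    for adapter in adapters:
        if not adapter:
            raise ValueError("adapters must be non-empty strings")
        for pos in range(0, len(read.bases) - min_overlap + 1):
            if pos >= best_cut:
                break
            overlap = min(len(adapter), len(read.bases) - pos)
            window = read.bases[pos : pos + overlap]
            mismatches = sum(a != b for a, b in zip(adapter, window))
            if mismatches <= overlap // 10:
                best_cut = pos
                break
    if best_cut == len(read.bases):
        return read
    return ReadRecord(read.id, read.bases[:best_cut], read.qualities[:best_cut])


def quality_trim(read: ReadRecord, cfg: ProcessingConfig) -> ReadRecord | None:
    """Sliding-window quality trim; returns None when the read is discarded.

    Windows of ``quality_window`` bases slide 5'->3'; the read is truncated
    at the start of the first window whose mean Phred drops below
    ``quality_threshold``.  Reads shorter than ``min_length`` before or
    after truncation are discarded.
    """
    if len(read) < cfg.min_length:
        return None
    w = cfg.quality_window
    if len(read) >= w:
        means = np.convolve(read.qualities, np.ones(w) / w, mode="valid")
        failing = np.nonzero(means < cfg.quality_threshold)[0]
        if failing.size:
            cut = int(failing[0])
            if cut < cfg.min_length:
                return None
            return ReadRecord(read.id, read.bases[:cut], read.qualities[:cut])
    return read


def merge_pair(
    fwd: ReadRecord, rev: ReadRecord, cfg: ProcessingConfig
) -> MergedSequence | None:
    """Merge a forward/reverse pair by their best overlap, or return None.

    The reverse mate is reverse-complemented and slid against the forward
    mate; among overlaps of at least ``min_overlap`` bases whose mismatch
    fraction is within ``max_overlap_mismatch_fraction``, the one with the
    highest identity score (matches minus mismatches, ties broken toward
    the longest overlap) wins.  Consensus: agreement keeps the base;
    disagreement keeps the higher-quality base; an equal-quality
    disagreement emits the tie symbol (``N``).  Input ``N`` bases never
    count as mismatches and defer to the mate's base.
    """
    rc_bases = revcomp(rev.bases)
    rc_quals = rev.qualities[::-1]
    f = np.frombuffer(fwd.bases.encode(), dtype=np.uint8)
    r = np.frombuffer(rc_bases.encode(), dtype=np.uint8)
    n_code = ord("N")

    best: tuple[int, int] | None = None  # (score, overlap)
    max_overlap = min(f.size, r.size)
    for o in range(max_overlap, cfg.min_overlap - 1, -1):
        if best is not None and best[0] >= o:
            break  # no shorter overlap can beat the current score
        a, b = f[f.size - o :], r[:o]
        informative = (a != n_code) & (b != n_code)
        mismatches = int(((a != b) & informative).sum())
        if mismatches > cfg.max_overlap_mismatch_fraction * o:
            continue
        matches = int(((a == b) & informative).sum())
        score = matches - mismatches
        if best is None or score > best[0]:
            best = (score, o)
    if best is None:
        return None

    o = best[1]
    head = fwd.bases[: f.size - o]
    tail = rc_bases[o:]
    consensus = []
    fq = fwd.qualities[f.size - o :]
    rq = rc_quals[:o]
    for i in range(o):
        a, b = fwd.bases[f.size - o + i], rc_bases[i]
        if a == b:
            consensus.append(a)
        elif a == "N":
            consensus.append(b)
        elif b == "N":
            consensus.append(a)
        elif fq[i] > rq[i]:
            consensus.append(a)
        elif rq[i] > fq[i]:
            consensus.append(b)
        else:
            consensus.append(cfg.tie_policy)
    pair_id = _pair_id(fwd.id)
    return MergedSequence(pair_id, head + "".join(consensus) + tail, pair_id)


def _pair_id(read_id: str) -> str:
    base = read_id.split()[0] if read_id else read_id
    if base.endswith("/1") or base.endswith("/2"):
        base = base[:-2]
    return base


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load a Sanger Phred+33 FASTQ file into ReadRecords."""
    records = []
    parser = SeqIO.parse(str(path), "fastq")
    index = 0
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record {index + 1} in {path}: {exc}")
        records.append(
            ReadRecord(
                rec.id, str(rec.seq).upper(),
                np.asarray(rec.letter_annotations["phred_quality"]),
            )
        )
        index += 1
    return records


def process_fastq_pair(
    forward_path: str | Path,
    reverse_path: str | Path,
    cfg: ProcessingConfig,
) -> tuple[list[MergedSequence], ProcessingReport]:
    """Run adapter removal, quality trimming and merging over paired FASTQs."""
    fwd_reads = read_fastq(forward_path)
    rev_reads = read_fastq(reverse_path)
    if len(fwd_reads) != len(rev_reads):
        raise ValueError(
            f"unpaired inputs: {len(fwd_reads)} forward vs {len(rev_reads)} reverse reads"
        )
    report = ProcessingReport(raw_pairs=len(fwd_reads))
    merged: list[MergedSequence] = []
    for i, (fwd, rev) in enumerate(zip(fwd_reads, rev_reads)):
        if _pair_id(fwd.id) != _pair_id(rev.id):
            raise ValueError(
                f"mate id mismatch at record {i + 1}: {fwd.id!r} vs {rev.id!r}"
            )
        fwd = remove_adapter(fwd, cfg.adapters, cfg.min_overlap)
        rev = remove_adapter(rev, cfg.adapters, cfg.min_overlap)
        fwd_t = quality_trim(fwd, cfg)
        rev_t = quality_trim(rev, cfg)
        if fwd_t is None or rev_t is None:
            report.discarded_short += 1
            continue
        pair = merge_pair(fwd_t, rev_t, cfg)
        if pair is None:
            report.unmerged += 1
        else:
            merged.append(pair)
            report.merged += 1
    assert report.reconciles()
    return merged, report


def write_merged_fasta(merged: list[MergedSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(m.bases), id=m.id, description="") for m in merged
    ]
    SeqIO.write(records, str(path), "fasta")


def read_merged_fasta(path: str | Path) -> list[MergedSequence]:
    return [
        MergedSequence(rec.id, str(rec.seq).upper(), rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
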