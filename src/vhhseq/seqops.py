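"""Low-level sequence primitives shared across the pipeline.

Nucleotide sequences are plain upper-case strings over ``{A,C,G,T,N}``;
amino-acid sequences are one-letter strings with ``X`` for residues whose
codon contains an undetermined base and ``*`` for stop codons.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from Bio.Data import CodonTable

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: Standard genetic code, codon -> one-letter amino acid, stops as '*'.
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PURINES = frozenset("AG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame_offset: int = 0) -> str:
    """Translate ``seq`` with the standard genetic code.

    Parameters
    ----------
    seq:
        Nucleotide string over ``{A,C,G,T,N}``.
    frame_offset:
        Number of 5' bases skipped before the first codon (0, 1 or 2);
        an offset of 1 is the "frame 2" used for VHH amplicons whose
        reading frame starts at the second base.

    Any codon containing ``N`` translates to ``X``; stop codons translate
    to ``*``; a trailing partial codon is dropped.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"invalid nucleotide characters: {sorted(invalid)}")
    residues = []
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        residues.append("X" if "N" in codon else CODON_TO_AA[codon])
    return "".join(residues)


def is_transition(ref: str, alt: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine substitutions."""
    if ref == alt:
        raise ValueError("not a substitution: identical bases")
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise ValueError(f"cannot classify substitution {ref}->{alt}")
    return (ref in PURINES) == (alt in PURINES)


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as in the reported percentages."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage ``100*numerator/denominator`` rounded half-up."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in percentage")
    return round_half_up(100.0 * numerator / denominator, ndigits)
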