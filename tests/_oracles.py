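"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the slowest, most transparent
route available (exhaustive dynamic programming, O(n^2) partitioning,
hand-built lookup tables) so they share no code with the implementation
paths they check.
"""

from __future__ import annotations

# Hand-entered standard genetic code (independent of the package's table).
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(seq: str, frame_offset: int = 0) -> str:
    out = []
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else GENETIC_CODE[codon])
    return "".join(out)


def classify_substitution(ref: str, alt: str) -> str:
    purines = {"A", "G"}
    return "transition" if (ref in purines) == (alt in purines) else "transversion"


def brute_force_partition(seqs: list[str]) -> list[list[int]]:
    """O(n^2) pairwise-equality partition of sequence indices."""
    groups: list[list[int]] = []
    for i, seq in enumerate(seqs):
        for group in groups:
            if seqs[group[0]] == seq:
                group.append(i)
                break
        else:
            groups.append([i])
    return groups


def affine_alignment_score(
    x: str,
    y: str,
    match: float = 1,
    mismatch: float = -1,
    gap_open: float = -4,
    gap_extend: float = -1,
) -> float:
    """Exhaustive Gotoh DP for the global affine-gap score.

    Conventions: the first residue of a gap costs ``gap_open`` and each
    further residue ``gap_extend``; end gaps are penalized; an insertion
    may be adjacent to a deletion (no column may be gap in both rows).
    """
    n, m = len(x), len(y)
    neg = float("-inf")
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in y
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in x
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if x[i - 1] == y[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + gap_open,
                X[i - 1][j] + gap_extend,
                Y[i - 1][j] + gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
    return max(M[n][m], X[n][m], Y[n][m])
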