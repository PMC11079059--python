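"""Simulation of in vivo mutagenesis, internalization selection and sequencing.

The generator mirrors the experimental workflow the analysis pipeline was
designed for:

* ``mutate_pool`` — iterative rounds of random point mutagenesis by a
  low-fidelity DNA polymerase I (mutator strain), with a transition bias,
  a G->A predominance, and an ori-proximal hotspot on the plasmid.
* ``apply_selection`` — a single FACS-style selection round that samples a
  fixed number of internalization events with replacement, weighted by a
  per-clone affinity function.
* ``simulate_reads`` — 2x300 paired-end sequencing of the amplicon pool
  with a uniform per-base substitution error rate and a decaying quality
  profile, plus a truth table for read-level provenance.

All three are deterministic under fixed seeds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, NamedTuple

import numpy as np

from .reference import ReferenceConstruct
from .seqops import NUCLEOTIDES, revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(NUCLEOTIDES):
    _CODE[ord(_b)] = _i
_BYTE = np.frombuffer(NUCLEOTIDES.encode(), dtype=np.uint8)

# transition partner by base code: A<->G, C<->T
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("pool sequences must be over {A,C,G,T}")
    return codes


def _decode(row: np.ndarray) -> str:
    return _BYTE[row].tobytes().decode()


def default_substitution_weights(
    transition_fraction: float = 0.8, g_to_a_boost: float = 2.0
) -> np.ndarray:
    """Default 4x4 substitution weight matrix (rows/cols ordered A,C,G,T).

    Each row, renormalized, is the conditional target distribution for a
    substitution at that base: the single transition partner carries
    ``transition_fraction`` of the mass and the two transversions split the
    remainder, so the expected transition proportion among substitution
    events equals ``transition_fraction`` exactly, independent of base
    composition.  Row sums encode relative site mutability; the G row is
    scaled by ``g_to_a_boost`` so G sites mutate more often and G->A is the
    predominant single substitution, as expected for a low-fidelity
    polymerase I mutator.
    """
    weights = np.zeros((4, 4))
    tv = (1.0 - transition_fraction) / 2.0
    for b in range(4):
        for t in range(4):
            if t == b:
                continue
            weights[b, t] = transition_fraction if t == _TRANSITION[b] else tv
    weights[2] *= g_to_a_boost
    return weights


@dataclass
class MutagenesisModel:
    """Per-round random point mutagenesis with transition and hotspot bias.

    ``per_base_rate_per_round`` is the *mean* substitution probability per
    base per round: the per-position rate vector (site mutability from the
    substitution-weight row sums times the hotspot multiplier) is
    normalized to that mean over the reference, so the hotspot and the
    mutability bias redistribute mutations without inflating the total.
    """

    per_base_rate_per_round: float = 1.5e-3
    transition_fraction: float = 0.8
    substitution_weights: np.ndarray | None = None
    hotspot_weight: float = 5.0
    hotspot_window_bp: int = 750
    indel_rate: float = 0.0
    rounds: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_rate_per_round <= 1.0:
            raise ValueError("per_base_rate_per_round must be in [0, 1]")
        if not 0.0 <= self.transition_fraction <= 1.0:
            raise ValueError("transition_fraction must be in [0, 1]")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.hotspot_weight < 0:
            raise ValueError("hotspot_weight must be non-negative")
        if self.substitution_weights is None:
            self.substitution_weights = default_substitution_weights(
                self.transition_fraction
            )
        w = np.asarray(self.substitution_weights, dtype=float)
        if w.shape != (4, 4) or (w < 0).any() or np.diagonal(w).any():
            raise ValueError(
                "substitution_weights must be a non-negative 4x4 matrix "
                "with a zero diagonal"
            )
        if (w.sum(axis=1) == 0).any():
            raise ValueError("substitution_weights rows must be renormalizable")
        self.substitution_weights = w


@dataclass
class ClonePool:
    """A multiset of clone nucleotide sequences with copy counts."""

    clones: dict[str, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        for seq, count in self.clones.items():
            if not isinstance(count, (int, np.integer)) or count <= 0:
                raise ValueError(f"copy count for {seq[:12]}... must be a positive int")

    @property
    def total(self) -> int:
        return sum(self.clones.values())

    def __len__(self) -> int:
        return len(self.clones)


class MutationEvent(NamedTuple):
    """One substitution event applied during mutagenesis."""

    copy_index: int
    round: int
    position: int
    ref_base: str
    new_base: str


@dataclass
class SelectionModel:
    """Affinity-weighted sampling of a fixed number of sorted events."""

    weight_fn: Callable[[str], float]
    n_events: int = 706
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass
class SequencerModel:
    """Paired-end sequencer with per-base substitution errors.

    ``quality_profile`` holds the per-cycle mean Phred score; the default
    decays linearly from Q37 to Q30 over the read, the familiar 3' quality
    droop of 2x300 chemistry.  Per-base qualities are the profile plus
    Gaussian noise, clipped to [2, 41].  Substitution errors are applied
    independently of the reported quality.
    """

    read_length: int = 300
    substitution_error_rate: float = 1e-3
    quality_profile: np.ndarray | None = None
    quality_sd: float = 2.0
    depth: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if not 0.0 <= self.substitution_error_rate <= 1.0:
            raise ValueError("substitution_error_rate must be in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.quality_profile is None:
            self.quality_profile = np.linspace(37.0, 30.0, self.read_length)
        profile = np.asarray(self.quality_profile, dtype=float)
        if profile.shape != (self.read_length,):
            raise ValueError("quality_profile must have one entry per cycle")
        if profile.min() < 2 or profile.max() > 41:
            raise ValueError("quality_profile Phred values must lie in [2, 41]")
        self.quality_profile = profile


class SimulatedReads(NamedTuple):
    forward_path: Path
    reverse_path: Path
    truth_path: Path
    n_pairs: int


def _position_rates(
    codes: np.ndarray, ref: ReferenceConstruct, model: MutagenesisModel
) -> tuple[np.ndarray, float]:
    """Hotspot multiplier vector and mean-normalization constant."""
    length = codes.shape[-1]
    coords = ref.insert_offset_from_ori + np.arange(length)
    hotspot = np.where(coords < model.hotspot_window_bp, model.hotspot_weight, 1.0)
    row_sums = model.substitution_weights.sum(axis=1)
    ref_codes = _encode(ref.sequence[:length].ljust(length, ref.sequence[-1]))
    norm = float(np.mean(row_sums[ref_codes] * hotspot))
    if norm == 0:
        raise ValueError("degenerate mutation model: zero total weight")
    return hotspot, norm


def mutate_pool(
    pool: ClonePool,
    ref: ReferenceConstruct,
    model: MutagenesisModel,
    return_events: bool = False,
) -> ClonePool | tuple[ClonePool, list[MutationEvent]]:
    """Pass every copy in the pool through ``model.rounds`` mutation rounds.

    Copy counts are conserved.  With ``return_events=True`` the list of
    individual substitution events (per copy, round and position) is also
    returned, which gives unbiased tallies of the substitution spectrum
    even when a site is hit more than once.
    """
    if not pool.clones:
        raise ValueError("empty pool")
    rng = np.random.default_rng(model.seed)
    row_sums = model.substitution_weights.sum(axis=1)
    cond = model.substitution_weights / row_sums[:, None]
    cond_cum = np.cumsum(cond, axis=1)

    events: list[MutationEvent] = []
    out: Counter[str] = Counter()
    copy_base = 0
    # group clones by length so each group is a rectangular matrix
    by_length: dict[int, list[tuple[str, int]]] = {}
    for seq, count in pool.clones.items():
        by_length.setdefault(len(seq), []).append((seq, count))

    for length, members in sorted(by_length.items()):
        mat = np.concatenate(
            [np.tile(_encode(seq), (count, 1)) for seq, count in members]
        )
        hotspot, norm = _position_rates(mat, ref, model)
        for rnd in range(1, model.rounds + 1):
            rates = (
                model.per_base_rate_per_round * row_sums[mat] * hotspot[None, :] / norm
            )
            mask = rng.random(mat.shape) < np.clip(rates, 0.0, 1.0)
            rows, cols = np.nonzero(mask)
            if rows.size:
                old = mat[rows, cols]
                draws = rng.random(rows.size)
                new = (draws[:, None] > cond_cum[old]).sum(axis=1).astype(np.uint8)
                mat[rows, cols] = new
                if return_events:
                    events.extend(
                        MutationEvent(
                            copy_base + int(r), rnd, int(c),
                            NUCLEOTIDES[o], NUCLEOTIDES[n],
                        )
                        for r, c, o, n in zip(rows, cols, old, new)
                    )
        sequences = [_decode(row) for row in mat]
        if model.indel_rate > 0:
            p_indel = 1.0 - (1.0 - model.indel_rate) ** model.rounds
            sequences = [_apply_indels(s, p_indel, rng) for s in sequences]
        out.update(sequences)
        copy_base += mat.shape[0]

    mutated = ClonePool(dict(out), provenance=f"{pool.provenance}+mutagenesis")
    assert mutated.total == pool.total
    return (mutated, events) if return_events else mutated


def _apply_indels(seq: str, p_indel: float, rng: np.random.Generator) -> str:
    """Apply rare single-base insertions/deletions (50/50) to one copy."""
    n = rng.binomial(len(seq), p_indel)
    if n == 0:
        return seq
    chars = list(seq)
    for pos in sorted(rng.integers(0, len(chars), size=n), reverse=True):
        if rng.random() < 0.5:
            del chars[pos]
        else:
            chars.insert(pos, NUCLEOTIDES[rng.integers(0, 4)])
    return "".join(chars)


def apply_selection(pool: ClonePool, sel: SelectionModel) -> ClonePool:
    """Sample exactly ``sel.n_events`` copies with replacement.

    Clone probabilities are proportional to copy count times affinity
    weight; zero-weight clones are never sampled.
    """
    if not pool.clones:
        raise ValueError("empty pool")
    clones = list(pool.clones.items())
    weights = np.array([sel.weight_fn(seq) for seq, _ in clones], dtype=float)
    if (weights < 0).any():
        raise ValueError("affinity weights must be non-negative")
    mass = weights * np.array([count for _, count in clones], dtype=float)
    total = mass.sum()
    if total == 0:
        raise ValueError("no selectable clone")
    rng = np.random.default_rng(sel.seed)
    draws = rng.multinomial(sel.n_events, mass / total)
    selected = {
        clones[i][0]: int(k) for i, k in enumerate(draws) if k > 0
    }
    out = ClonePool(selected, provenance=f"{pool.provenance}+selection")
    assert out.total == sel.n_events
    return out


def simulate_reads(
    pool: ClonePool,
    ref: ReferenceConstruct,
    seqm: SequencerModel,
    out_prefix: str | Path,
) -> SimulatedReads:
    """Write paired FASTQ files plus a truth table for a clone pool.

    Each of ``seqm.depth`` read pairs samples a clone (with replacement,
    proportional to copy count); the forward read covers the first
    ``read_length`` bases of the amplicon and the reverse read the
    reverse complement of the last ``read_length`` bases, so a 371-bp
    amplicon is fully spanned by a 2x300 pair with ~229 bp overlap.
    The truth table (TSV) records read id, source clone sequence and the
    number of injected errors per mate.
    """
    if not pool.clones:
        raise ValueError("empty pool")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seqm.seed)
    clones = list(pool.clones.items())
    counts = np.array([count for _, count in clones], dtype=float)
    choices = rng.choice(len(clones), size=seqm.depth, p=counts / counts.sum())

    fwd_path = out_prefix.with_name(out_prefix.name + "_R1.fastq")
    rev_path = out_prefix.with_name(out_prefix.name + "_R2.fastq")
    truth_path = out_prefix.with_name(out_prefix.name + "_truth.tsv")
    min_len = min(len(seq) for seq, _ in clones)
    if min_len < 2 * 11:  # shorter than any usable overlap configuration
        import warnings

        warnings.warn("amplicon very short; read pairs may fail to merge")

    with open(fwd_path, "w") as fwd, open(rev_path, "w") as rev, open(
        truth_path, "w"
    ) as truth:
        truth.write("read_id\tclone\tn_errors_fwd\tn_errors_rev\n")
        for i, clone_idx in enumerate(choices):
            amplicon = clones[clone_idx][0]
            read_id = f"sim{i:06d}"
            f_bases, f_qual, f_err = _sequence_one(amplicon[: seqm.read_length], seqm, rng)
            r_template = revcomp(amplicon)[: seqm.read_length]
            r_bases, r_qual, r_err = _sequence_one(r_template, seqm, rng)
            fwd.write(f"@{read_id}/1\n{f_bases}\n+\n{f_qual}\n")
            rev.write(f"@{read_id}/2\n{r_bases}\n+\n{r_qual}\n")
            truth.write(f"{read_id}\t{amplicon}\t{f_err}\t{r_err}\n")
    return SimulatedReads(fwd_path, rev_path, truth_path, seqm.depth)


def _sequence_one(
    template: str, seqm: SequencerModel, rng: np.random.Generator
) -> tuple[str, str, int]:
    codes = _encode(template)
    n = codes.size
    err_mask = rng.random(n) < seqm.substitution_error_rate
    n_err = int(err_mask.sum())
    if n_err:
        # uniform over the three non-template bases
        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
        codes = codes.copy()
        codes[err_mask] = (codes[err_mask] + shift) % 4
    quals = np.clip(
        np.rint(seqm.quality_profile[:n] + rng.normal(0.0, seqm.quality_sd, size=n)),
        2,
        41,
    ).astype(int)
    qual_str = "".join(chr(q + 33) for q in quals)
    return _decode(codes), qual_str, n_err
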