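"""Reference VHH construct: sequence, reading frame and region map.

The amplicon analyzed by the pipeline is a single-domain antibody (VHH)
coding fragment of ~371 bp whose reading frame starts at the second base
("frame 2", ``frame_offset=1``).  Framework (FR1-FR4) and complementarity
determining regions (CDR1-CDR3) are described as 0-based half-open
nucleotide intervals on the construct.  On the mutagenesis plasmid the
fragment sits ``insert_offset_from_ori`` bp downstream of the ColE1
origin, which matters because the low-fidelity polymerase used for
in vivo mutagenesis preferentially mutates the first ~750 bp from ori.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqops import translate

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")


@dataclass(frozen=True)
class ReferenceConstruct:
    """A reference nucleotide sequence with reading frame and region map."""

    id: str
    sequence: str
    region_map: dict[str, tuple[int, int]]
    frame_offset: int = 1
    primer_intervals: tuple[tuple[int, int], ...] = ()
    insert_offset_from_ori: int = 292

    def __post_init__(self) -> None:
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise ValueError("reference sequence must be non-empty over {A,C,G,T}")
        prev_end = 0
        for name, (start, end) in self.region_map.items():
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"region {name} out of bounds: ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"region {name} overlaps or is out of order")
            prev_end = end
        if "CDR3" in self.region_map:
            start, end = self.region_map["CDR3"]
            if (end - start) % 3 or (start - self.frame_offset) % 3:
                raise ValueError("CDR3 must be an in-frame multiple of 3 nt")
        if "*" in self.aa_sequence:
            raise ValueError("reference translation contains a stop codon")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def aa_sequence(self) -> str:
        return translate(self.sequence, self.frame_offset)

    def region(self, name: str) -> tuple[int, int]:
        try:
            return self.region_map[name]
        except KeyError:
            raise KeyError(f"unknown region {name!r}; have {list(self.region_map)}")

    def region_nt(self, name: str) -> str:
        start, end = self.region(name)
        return self.sequence[start:end]

    def region_aa_bounds(self, name: str) -> tuple[int, int]:
        """Region interval in amino-acid coordinates (requires in-frame region)."""
        start, end = self.region(name)
        if (start - self.frame_offset) % 3 or (end - start) % 3:
            raise ValueError(f"region {name} is not in frame")
        return (start - self.frame_offset) // 3, (end - self.frame_offset) // 3

    def region_aa(self, name: str) -> str:
        start, end = self.region_aa_bounds(name)
        return self.aa_sequence[start:end]

    def region_of_position(self, nt_position: int) -> str | None:
        """Name of the region containing a 0-based nucleotide position."""
        for name, (start, end) in self.region_map.items():
            if start <= nt_position < end:
                return name
        return None

    def in_primer(self, nt_position: int) -> bool:
        return any(s <= nt_position < e for s, e in self.primer_intervals)

    def hotspot_mask(self, window_bp: int = 750) -> np.ndarray:
        """Boolean mask of positions within ``window_bp`` of the plasmid ori."""
        coords = self.insert_offset_from_ori + np.arange(len(self.sequence))
        return coords < window_bp

    # ---------------------------------------------------------------- I/O

    def write_fasta(self, path: str | Path) -> None:
        record = SeqRecord(Seq(self.sequence), id=self.id, description="")
        SeqIO.write([record], str(path), "fasta")

    def write_region_yaml(self, path: str | Path) -> None:
        payload = {
            "frame_offset": self.frame_offset,
            "insert_offset_from_ori": self.insert_offset_from_ori,
            "regions": {name: list(iv) for name, iv in self.region_map.items()},
            "primer_intervals": [list(iv) for iv in self.primer_intervals],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_files(cls, fasta: str | Path, region_yaml: str | Path) -> "ReferenceConstruct":
        record = next(SeqIO.parse(str(fasta), "fasta"))
        spec = yaml.safe_load(Path(region_yaml).read_text())
        return cls(
            id=record.id,
            sequence=str(record.seq).upper(),
            region_map={k: tuple(v) for k, v in spec["regions"].items()},
            frame_offset=int(spec.get("frame_offset", 1)),
            primer_intervals=tuple(tuple(iv) for iv in spec.get("primer_intervals", [])),
            insert_offset_from_ori=int(spec.get("insert_offset_from_ori", 292)),
        )


# Synthetic default construct.  The published study does not disclose the
# reference VHH sequence, so this scaffold is an artificial camelid-style
# VHH written for simulation and testing: generic FR residues, and a
# 10-residue CDR3 whose named positions (P1, Q2, R4, S5, A6, R7, L8, S9)
# follow the positional analyses the pipeline reproduces; positions 3 and
# 10 are arbitrary filler.
_FRAMEWORK_AA = {
    "FR1": "QVQLQESGGGLVQAGGSLRLSCAAS",
    "CDR1": "GRTFSSYA",
    "FR2": "MGWFRQAPGKEREFVAA",
    "CDR2": "ISWSGGST",
    "FR3": "YYADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYC",
    "CDR3": "PQGRSARLSS",
    "FR4": "WGQGTQVTVSSEPKTPK",
}

_PREFERRED_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

# CDR3 codons are fixed individually so that synonymous-codon analyses have
# a defined wild-type codon per position.
_CDR3_CODONS = ("CCT", "CAG", "GGT", "CGC", "AGC", "GCA", "CGG", "CTG", "TCC", "AGT")


def default_reference() -> ReferenceConstruct:
    """Bundled synthetic 371-bp VHH reference construct (frame 2)."""
    frame_offset = 1
    parts: list[str] = []
    region_map: dict[str, tuple[int, int]] = {}
    cursor = frame_offset
    for name in REGION_ORDER:
        aa = _FRAMEWORK_AA[name]
        if name == "CDR3":
            nt = "".join(_CDR3_CODONS)
            assert translate(nt) == aa
        else:
            nt = "".join(_PREFERRED_CODON[res] for res in aa)
        region_map[name] = (cursor, cursor + len(nt))
        parts.append(nt)
        cursor += len(nt)
    sequence = "G" + "".join(parts) + "C"  # pad to 371 nt around the frame
    return ReferenceConstruct(
        id="vhh_ref_synthetic",
        sequence=sequence,
        region_map=region_map,
        frame_offset=frame_offset,
        primer_intervals=((0, 21), (len(sequence) - 21, len(sequence))),
        insert_offset_from_ori=292,
    )
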