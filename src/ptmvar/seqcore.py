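"""Protein I/O, window extraction and one-hot encoding.

Every prediction in this package starts from a fixed-length peptide window
centered on a candidate modification site.  Windows are cut from the parent
protein with explicit ``'X'`` padding where the protein ends, then encoded
as an ``n x 22`` one-hot matrix: one channel per standard residue plus the
uncommon selenocysteine (U) and pyrrolysine (O); the pad character maps to
the all-zero row, so the alphabet has 23 symbols but only 22 channels.

All public positions are 1-based, matching modification-site table
conventions; indices internal to arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

#: channel order: 20 standard residues alphabetically, then U, then O
ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + "UO"
PAD = "X"
CHANNEL_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
N_CHANNELS = len(ALPHABET)  # 22

#: inclusive window-length bounds used in production mode
MIN_WINDOW, MAX_WINDOW = 31, 61

#: PTM type -> modifiable residues
PTM_TARGET_RESIDUES = {
    "phosphorylation": frozenset("STY"),
    "acetylation": frozenset("K"),
    "methylation": frozenset("KR"),
    "sumoylation": frozenset("K"),
    "ubiquitination": frozenset("K"),
    "n_glycosylation": frozenset("N"),
}

PTM_TYPES = tuple(sorted(PTM_TARGET_RESIDUES))


class FastaError(ValueError):
    """Malformed FASTA input or duplicate record ids."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession plus uppercase amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} out of range 1..{len(self.sequence)} "
                f"for protein {self.id!r}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SiteRef:
    """A candidate modification site: (protein, 1-based position, residue)."""

    protein_id: str
    position: int
    residue: str


@dataclass(frozen=True)
class PTMType:
    name: str
    target_residues: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.name not in PTM_TARGET_RESIDUES:
            raise ValueError(
                f"unknown PTM type {self.name!r}; valid names: "
                + ", ".join(PTM_TYPES)
            )
        expected = PTM_TARGET_RESIDUES[self.name]
        if not self.target_residues:
            object.__setattr__(self, "target_residues", expected)
        elif self.target_residues != expected:
            raise ValueError(
                f"target residues for {self.name} must be {set(expected)}"
            )


def residues_for_ptm(ptm: str | PTMType) -> frozenset:
    """Modifiable residues for a PTM type (e.g. {S,T,Y} for phosphorylation)."""
    if isinstance(ptm, PTMType):
        return ptm.target_residues
    return PTMType(ptm).target_residues


def as_ptm(ptm: str | PTMType) -> PTMType:
    return ptm if isinstance(ptm, PTMType) else PTMType(ptm)


@dataclass(frozen=True)
class SiteWindow:
    """Fixed-length peptide centered on a site, 'X'-padded past protein ends."""

    site: SiteRef
    n: int
    peptide: str

    def __post_init__(self) -> None:
        if len(self.peptide) != self.n:
            raise ValueError("peptide length must equal n")
        if self.peptide[(self.n - 1) // 2] != self.site.residue:
            raise ValueError("window center must equal the site residue")


def load_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords.

    The header token before the first whitespace becomes the id; sequences
    are uppercased.  Duplicate ids raise :class:`FastaError`.
    """
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise FastaError(f"could not parse FASTA file {path}: {exc}") from exc
    for rec in parsed:
        if not rec.id:
            raise FastaError(f"FASTA entry with empty header in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"FASTA entry {rec.id!r} has an empty sequence")
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise FastaError(f"duplicate FASTA ids: {', '.join(dups)}")
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def extract_window(
    protein: ProteinRecord, position: int, n: int, *, enforce_bounds: bool = False
) -> SiteWindow:
    """Cut an odd-length window of size ``n`` centered on a 1-based position.

    Flanks reaching past either protein end are filled with the pad
    character.  ``enforce_bounds`` additionally requires 31 <= n <= 61;
    smaller odd n are allowed otherwise so that small fixtures stay cheap.
    """
    if n % 2 == 0:
        raise ValueError(f"window length must be odd, got {n}")
    if enforce_bounds and not MIN_WINDOW <= n <= MAX_WINDOW:
        raise ValueError(f"window length must be in [{MIN_WINDOW}, {MAX_WINDOW}]")
    residue = protein.residue(position)  # also validates the position
    half = (n - 1) // 2
    seq = protein.sequence
    start = position - 1 - half
    end = position - 1 + half + 1
    left_pad = max(0, -start)
    right_pad = max(0, end - len(seq))
    core = seq[max(0, start) : min(len(seq), end)]
    peptide = PAD * left_pad + core + PAD * right_pad
    return SiteWindow(
        site=SiteRef(protein.id, position, residue), n=n, peptide=peptide
    )


def window_from_peptide(peptide: str, *, protein_id: str = "window") -> SiteWindow:
    """Wrap a raw odd-length peptide string as a SiteWindow (center = site)."""
    n = len(peptide)
    if n % 2 == 0:
        raise ValueError("peptide length must be odd")
    center = (n - 1) // 2
    return SiteWindow(
        site=SiteRef(protein_id, center + 1, peptide[center]), n=n, peptide=peptide
    )


def one_hot_encode(window: SiteWindow | str) -> np.ndarray:
    """Encode a window as an ``n x 22`` matrix; pad rows are all zero."""
    peptide = window.peptide if isinstance(window, SiteWindow) else window
    mat = np.zeros((len(peptide), N_CHANNELS), dtype=np.float32)
    for i, aa in enumerate(peptide):
        if aa == PAD:
            continue
        idx = CHANNEL_INDEX.get(aa)
        if idx is None:
            raise ValueError(
                f"character {aa!r} at position {i + 1} is outside the "
                f"amino-acid alphabet"
            )
        mat[i, idx] = 1.0
    return mat


def encode_batch(peptides) -> np.ndarray:
    """Stack one-hot encodings of equal-length peptides into (B, n, 22)."""
    return np.stack([one_hot_encode(p) for p in peptides])


def sequon_check(sequence: str, position: int) -> bool:
    """True iff the N at a 1-based position sits in an N-!P-[ST] sequon.

    The two downstream residues must exist within the given sequence; an N
    at the last or second-to-last position fails.
    """
    if sequence[position - 1] != "N":
        raise ValueError(
            f"residue at position {position} is {sequence[position - 1]!r}, "
            "expected 'N'"
        )
    if position + 2 > len(sequence):
        return False
    nxt, third = sequence[position], sequence[position + 1]
    return nxt != "P" and third in ("S", "T")
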