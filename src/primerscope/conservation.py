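"""Conserved-region detection and degenerate-consensus primer design.

Given a gapped multiple alignment of a marker gene, primer candidates are
placed in maximal runs of columns that are simultaneously well conserved
(majority-base frequency above a threshold) and essentially gap-free.
Within a chosen region, each column is collapsed to the IUPAC code that
covers every base observed at or above an inclusion frequency, yielding a
degenerate primer whose degeneracy (number of concrete variants) is the
product of per-position base-set sizes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import numpy as np
from Bio import SeqIO

from .iupac import code_for_bases, degeneracy, reverse_complement

__all__ = [
    "AlignmentMatrix",
    "ColumnProfile",
    "ConservedRegion",
    "DegeneratePrimer",
    "column_profiles",
    "find_conserved_regions",
    "degenerate_consensus",
    "degeneracy",
    "write_primer_outputs",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class AlignmentMatrix:
    """A gapped multiple alignment held as equal-length rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError("rows are not all the same length")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, source: str | Path | IO[str]) -> "AlignmentMatrix":
        """Read an aligned FASTA (gap character ``-``)."""
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        recs = list(SeqIO.parse(source, "fasta"))
        return cls(tuple(r.id for r in recs), tuple(str(r.seq) for r in recs))


@dataclass(frozen=True)
class ColumnProfile:
    """Per-column residue tally of an alignment.

    ``majority_base``/``majority_frequency`` are computed over A/C/G/T
    only: gaps and ambiguity codes carry no positional information and are
    excluded from the denominator.  Ties break alphabetically.
    """

    a: int
    c: int
    g: int
    t: int
    other: int
    gap: int
    majority_base: str
    majority_frequency: float
    gap_fraction: float

    @property
    def n(self) -> int:
        return self.a + self.c + self.g + self.t + self.other + self.gap

    def base_count(self, base: str) -> int:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}[base]


@dataclass(frozen=True)
class ConservedRegion:
    """A maximal run of conserved columns, [start, end) in alignment coords."""

    start: int
    end: int
    mean_majority_frequency: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DegeneratePrimer:
    """A named IUPAC primer written 5'->3' as it would be synthesised."""

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("primer sequence must be non-empty")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        degeneracy(self.sequence)  # validates the alphabet

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def _column_arrays(aln: AlignmentMatrix) -> np.ndarray:
    """Alignment as a (n_rows, n_cols) byte matrix."""
    return np.frombuffer(
        "".join(aln.rows).encode("ascii"), dtype=np.uint8
    ).reshape(aln.n_rows, aln.n_cols)


def column_profiles(aln: AlignmentMatrix) -> list[ColumnProfile]:
    """Tally every alignment column.

    Majority base and frequency are over unambiguous residues; alphabetic
    tie-break keeps the result deterministic.
    """
    mat = _column_arrays(aln)
    n_rows = aln.n_rows
    counts = {b: (mat == ord(b)).sum(axis=0) for b in _BASES}
    gaps = (mat == ord("-")).sum(axis=0)
    profiles: list[ColumnProfile] = []
    for j in range(aln.n_cols):
        acgt = {b: int(counts[b][j]) for b in _BASES}
        gap = int(gaps[j])
        other = n_rows - sum(acgt.values()) - gap
        denom = sum(acgt.values())
        if denom:
            best = max(acgt.values())
            majority = min(b for b in _BASES if acgt[b] == best)
            freq = best / denom
        else:
            majority, freq = "", 0.0
        profiles.append(
            ColumnProfile(
                a=acgt["A"], c=acgt["C"], g=acgt["G"], t=acgt["T"],
                other=other, gap=gap,
                majority_base=majority,
                majority_frequency=freq,
                gap_fraction=gap / n_rows,
            )
        )
    return profiles


def find_conserved_regions(
    profiles: Sequence[ColumnProfile],
    min_length: int = 20,
    min_majority_freq: float = 0.75,
    max_gap_fraction: float = 0.10,
) -> list[ConservedRegion]:
    """Maximal runs of columns passing both conservation thresholds.

    A column qualifies when ``majority_frequency >= min_majority_freq`` and
    ``gap_fraction <= max_gap_fraction``; runs shorter than ``min_length``
    are dropped.  Regions are returned sorted by start column.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if not (0 < min_majority_freq <= 1):
        raise ValueError("min_majority_freq must be in (0, 1]")
    ok = [
        p.majority_base != ""
        and p.majority_frequency >= min_majority_freq
        and p.gap_fraction <= max_gap_fraction
        for p in profiles
    ]
    regions: list[ConservedRegion] = []
    i, n = 0, len(profiles)
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n and ok[j]:
            j += 1
        if j - i >= min_length:
            mean_freq = float(
                np.mean([profiles[k].majority_frequency for k in range(i, j)])
            )
            regions.append(ConservedRegion(i, j, mean_freq))
        i = j
    return regions


def degenerate_consensus(
    aln: AlignmentMatrix,
    region: ConservedRegion,
    include_freq: float = 0.10,
    orientation: str = "forward",
    name: str | None = None,
) -> DegeneratePrimer:
    """Collapse a conserved region into a synthesizable degenerate primer.

    Per column, the emitted IUPAC code covers every base whose gap-excluded
    frequency is at least ``include_freq``, plus the majority base
    unconditionally.  For ``orientation="reverse"`` the sense-strand
    consensus is reverse-complemented so the primer string reads 5'->3' on
    its own (antisense) strand.
    """
    if not (0 < include_freq <= 0.5):
        raise ValueError("include_freq must be in (0, 0.5]")
    if not (0 <= region.start < region.end <= aln.n_cols):
        raise ValueError("region outside alignment")
    profiles = column_profiles(aln)[region.start : region.end]
    codes = []
    for j, p in enumerate(profiles):
        denom = p.a + p.c + p.g + p.t
        if denom == 0:
            raise ValueError(
                f"column {region.start + j} has no unambiguous residues"
            )
        keep = {b for b in _BASES if p.base_count(b) / denom >= include_freq}
        keep.add(p.majority_base)
        codes.append(code_for_bases(keep))
    sense = "".join(codes)
    seq = reverse_complement(sense) if orientation == "reverse" else sense
    if name is None:
        name = f"{'F' if orientation == 'forward' else 'R'}_{region.start}_{region.end}"
    return DegeneratePrimer(name=name, sequence=seq, orientation=orientation)


def write_primer_outputs(
    primers: Sequence[DegeneratePrimer],
    regions: Sequence[ConservedRegion],
    fasta_path: str | Path,
    tsv_path: str | Path,
    regions_path: str | Path | None = None,
) -> None:
    """Write primer FASTA/TSV and an alignment-coordinate region table."""
    with open(fasta_path, "w") as fh:
        for p in primers:
            fh.write(f">{p.name}\n{p.sequence}\n")
    with open(tsv_path, "w") as fh:
        fh.write("name\tsequence\torientation\tdegeneracy\n")
        for p in primers:
            fh.write(f"{p.name}\t{p.sequence}\t{p.orientation}\t{p.degeneracy}\n")
    if regions_path is not None:
        with open(regions_path, "w") as fh:
            fh.write("start\tend\tlength\tmean_majority_frequency\n")
            for r in regions:
                fh.write(f"{r.start}\t{r.end}\t{r.length}\t{r.mean_majority_frequency:.4f}\n")
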