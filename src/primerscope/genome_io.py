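"""GenBank parsing, small-subunit rRNA excision and annotation validation.

Mitochondrial genome records deposited in GenBank annotate the
small-subunit (12S) rRNA gene under a variety of labels ("12S ribosomal
RNA", "s-rRNA", "rrnS", "MT-RNR1", ...).  This module locates that feature
under a configurable dialect list, excises the gene in its own 5'->3'
orientation, and applies explicit validation rules so that records with
suspect annotations are removed with a logged reason rather than silently
propagated into downstream screening.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from .iupac import IUPAC_CODES, reverse_complement

__all__ = [
    "GenomeRecord",
    "GeneFeature",
    "ExcisedGene",
    "DEFAULT_SSU_DIALECTS",
    "AmbiguousAnnotationError",
    "MalformedRecordError",
    "parse_genbank",
    "read_genbank",
    "find_ssu_rrna",
    "excise_gene",
    "validate_excised",
    "reverse_complement",
    "write_excised_fasta",
    "write_manifest",
]

logger = logging.getLogger(__name__)

#: Label patterns (case-insensitive substrings) accepted as naming the
#: mitochondrial small-subunit rRNA gene across common annotation dialects.
DEFAULT_SSU_DIALECTS: tuple[str, ...] = (
    "12S",
    "s-rRNA",
    "rrnS",
    "small subunit ribosomal RNA",
    "12S ribosomal RNA",
    "MT-RNR1",
)

_VALID_CHARS = frozenset(IUPAC_CODES)
_UNAMBIGUOUS = frozenset("ACGT")


class MalformedRecordError(ValueError):
    """A GenBank record violates basic structural invariants."""


class AmbiguousAnnotationError(ValueError):
    """A record carries more than one plausible SSU rRNA annotation."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature, with 0-based half-open coordinates.

    GenBank locations are 1-based inclusive at the file boundary; they are
    converted on parse and back on report, so ``start``/``end`` here are
    always 0-based half-open on the record's sense strand.
    """

    kind: str
    label: str
    start: int
    end: int
    strand: int  # +1 or -1
    compound: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval_1based(self) -> tuple[int, int]:
        """(start, end) as 1-based inclusive, the GenBank convention."""
        return self.start + 1, self.end


@dataclass(frozen=True)
class GenomeRecord:
    """One annotated (mito)genome record."""

    accession: str
    organism: str
    lineage: tuple[str, ...]
    sequence: str
    features: tuple[GeneFeature, ...] = ()

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        for f in self.features:
            if f.end > len(self.sequence):
                raise MalformedRecordError(
                    f"{self.accession}: feature {f.label!r} ends at {f.end} "
                    f"but sequence is {len(self.sequence)} bp"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExcisedGene:
    """A gene subsequence oriented 5'->3' of the gene itself."""

    accession: str
    organism: str
    lineage: tuple[str, ...]
    sequence: str
    start: int
    end: int
    strand: int
    status: str = "kept"  # "kept" | "removed"
    reason: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match source interval")
        if self.status == "removed" and not self.reason:
            raise ValueError("removed genes must carry a reason")
        if self.status not in ("kept", "removed"):
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _feature_label(feat) -> str:
    q = feat.qualifiers
    for key in ("product", "gene", "note", "standard_name"):
        if key in q and q[key]:
            return str(q[key][0])
    return ""


def parse_genbank(stream: IO[str] | str) -> list[GenomeRecord]:
    """Parse GenBank flat-file text into :class:`GenomeRecord` objects.

    Accepts a text stream or a string of one or more concatenated records.
    All feature classes are retained; the taxonomy lineage is taken from
    the ORGANISM block in file order.  A record whose features overflow
    the sequence raises :class:`MalformedRecordError` naming the LOCUS.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(stream, "genbank"):
        feats = []
        for f in rec.features:
            if f.type == "source":
                continue
            loc = f.location
            if loc is None:
                continue
            compound = isinstance(loc, CompoundLocation)
            strand = 1 if (loc.strand is None or loc.strand >= 0) else -1
            feats.append(
                GeneFeature(
                    kind=f.type,
                    label=_feature_label(f),
                    start=int(loc.start),
                    end=int(loc.end),
                    strand=strand,
                    compound=compound,
                )
            )
        try:
            records.append(
                GenomeRecord(
                    accession=rec.id or rec.name,
                    organism=rec.annotations.get("organism", ""),
                    lineage=tuple(rec.annotations.get("taxonomy", ())),
                    sequence=str(rec.seq),
                    features=tuple(feats),
                )
            )
        except MalformedRecordError:
            raise
        except ValueError as e:
            raise MalformedRecordError(f"{rec.name}: {e}") from e
    return records


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Read a GenBank file (plain or gzip-compressed) from disk."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return parse_genbank(fh)
    with open(path) as fh:
        return parse_genbank(fh)


def find_ssu_rrna(
    record: GenomeRecord,
    dialects: Sequence[str] = DEFAULT_SSU_DIALECTS,
) -> GeneFeature | None:
    """Locate the unique small-subunit rRNA feature of a record.

    Matches rRNA features whose label contains any dialect pattern
    (case-insensitive).  Returns ``None`` when no feature matches; raises
    :class:`AmbiguousAnnotationError` when two or more distinct features
    match or the match has a compound (multi-interval) location --- both
    signal an annotation needing manual review.
    """
    pats = [d.lower() for d in dialects]
    hits = []
    for f in record.features:
        if f.kind != "rRNA":
            continue
        label = f.label.lower()
        if any(p in label for p in pats):
            hits.append(f)
    distinct = {(f.start, f.end, f.strand) for f in hits}
    if len(distinct) > 1:
        raise AmbiguousAnnotationError(
            f"{record.accession}: {len(distinct)} distinct SSU rRNA annotations"
        )
    if not hits:
        return None
    feat = hits[0]
    if feat.compound:
        raise AmbiguousAnnotationError(
            f"{record.accession}: SSU rRNA has a compound (multi-interval) location"
        )
    return feat


def excise_gene(record: GenomeRecord, feature: GeneFeature) -> ExcisedGene:
    """Cut the feature interval out of the record, gene-oriented 5'->3'.

    Minus-strand features are reverse-complemented so the emitted sequence
    always reads in the gene's own orientation.
    """
    if feature.end > record.length:
        raise ValueError(f"feature does not fit record {record.accession}")
    sub = record.sequence[feature.start : feature.end]
    if feature.strand == -1:
        sub = reverse_complement(sub)
    return ExcisedGene(
        accession=record.accession,
        organism=record.organism,
        lineage=record.lineage,
        sequence=sub,
        start=feature.start,
        end=feature.end,
        strand=feature.strand,
    )


def validate_excised(
    gene: ExcisedGene,
    min_len: int = 300,
    max_len: int = 2500,
    max_ambiguous_frac: float = 0.10,
) -> ExcisedGene:
    """Apply explicit keep/remove rules to an excised gene.

    A gene is removed (with a reason) when its length falls outside
    ``[min_len, max_len]`` or more than ``max_ambiguous_frac`` of its bases
    are ambiguity codes.  The bounds default to [300, 2500] bp and 10%
    ambiguity, generous envelopes around known mitochondrial SSU lengths;
    records failing them almost always carry mis-drawn coordinates.
    """
    if not min_len < max_len:
        raise ValueError("min_len must be < max_len")
    n = gene.length
    if n < min_len:
        return replace(gene, status="removed", reason=f"too short ({n} < {min_len} bp)")
    if n > max_len:
        return replace(gene, status="removed", reason=f"too long ({n} > {max_len} bp)")
    ambiguous = sum(1 for c in gene.sequence if c not in _UNAMBIGUOUS)
    if n and ambiguous / n > max_ambiguous_frac:
        return replace(
            gene,
            status="removed",
            reason=f"ambiguous bases {ambiguous}/{n} exceed {max_ambiguous_frac:.0%}",
        )
    return replace(gene, status="kept", reason="")


def write_excised_fasta(genes: Iterable[ExcisedGene], path: str | Path) -> int:
    """Write kept genes as FASTA (``>accession|organism``); returns count."""
    n = 0
    with open(path, "w") as fh:
        for g in genes:
            if g.status != "kept":
                continue
            fh.write(f">{g.accession}|{g.organism}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i : i + 70] + "\n")
            n += 1
    return n


def write_manifest(genes: Iterable[ExcisedGene], path: str | Path) -> None:
    """Write the per-record excision manifest as TSV."""
    cols = "accession\tlineage\tstart\tend\tstrand\tlength\tstatus\treason\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for g in genes:
            s1, e1 = g.start + 1, g.end
            fh.write(
                f"{g.accession}\t{';'.join(g.lineage)}\t{s1}\t{e1}\t"
                f"{'+' if g.strand == 1 else '-'}\t{g.length}\t{g.status}\t{g.reason}\n"
            )
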