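"""Seeded synthetic mitogenome-like datasets with known ground truth.

Every downstream module is testable without database downloads because the
generator plants what the screen is later asked to recover: each synthetic
gene is ``left flank + forward primer site + insert + reverse-complemented
reverse primer site + right flank``, with per-position substitution
probabilities inside the primer sites, a noisy shared template outside
them, variable insert lengths, both annotation strands, and a configurable
fraction of deliberately corrupted annotations.  The emitted truth table
records, per record, the planted gene coordinates, the exact per-primer
mismatch counts (substitutions at primer positions are drawn from outside
the code's base set, so a planted mismatch is a mismatch by construction),
the mismatch category, and the insert length.

These fixtures are statistical stand-ins, not biological mimics: there is
no phylogeny, no rate heterogeneity, and flank/insert divergence is plain
i.i.d. substitution noise on one template.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .conservation import AlignmentMatrix, DegeneratePrimer
from .genome_io import DEFAULT_SSU_DIALECTS, GeneFeature, GenomeRecord
from .iupac import EXPANSIONS, code_for_bases, reverse_complement
from .matching import categorize

__all__ = [
    "FixtureSpec",
    "FixtureDataset",
    "generate_dataset",
    "corrupt_annotation",
    "plant_conserved_alignment",
    "DEFAULT_PHYLA",
]

_BASES = "ACGT"

#: Small fake lineage hierarchy so rank grouping is testable offline.
DEFAULT_PHYLA: dict[str, tuple[str, ...]] = {
    "Alphaphora": ("Metazoa", "Eumetazoa", "Bilateria", "Alphaphora"),
    "Betazoa": ("Metazoa", "Eumetazoa", "Bilateria", "Betazoa"),
    "Gammatoda": ("Metazoa", "Eumetazoa", "Pseudocoelomata", "Gammatoda"),
    "Deltaria": ("Metazoa", "Eumetazoa", "Deltaria"),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic cohort.

    ``fwd_site_sub_prob``/``rev_site_sub_prob`` may be a single probability
    applied to every primer position or a per-position sequence ordered
    5'->3' along the primer.  ``background_sub_rate`` is the per-base
    substitution probability applied to flanks and insert relative to a
    dataset-wide template; the default (0.35) keeps the regions outside the
    primer sites visibly diverged, as in a variable marker-gene region,
    while the primer sites stay conserved.
    """

    seed: int = 0
    n_per_phylum: Mapping[str, int] = field(
        default_factory=lambda: {p: 8 for p in DEFAULT_PHYLA}
    )
    phylum_lineages: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PHYLA)
    )
    forward_primer: str = "GGTYGGTAAAWCTCGTGCCAGC"
    reverse_primer: str = "CATAGTGGGGTATCTAATCCYAGT"
    left_flank_len: int = 120
    right_flank_len: int = 140
    insert_len_range: tuple[int, int] = (350, 700)
    fwd_site_sub_prob: float | Sequence[float] = 0.02
    rev_site_sub_prob: float | Sequence[float] = 0.02
    background_sub_rate: float = 0.35
    minus_strand_fraction: float = 0.5
    upstream_len_range: tuple[int, int] = (150, 400)
    downstream_len_range: tuple[int, int] = (150, 400)
    corrupt_fraction: float = 0.0
    corrupt_modes: tuple[str, ...] = ("shifted", "truncated", "mislabelled")

    def __post_init__(self) -> None:
        for p in self._probs(self.fwd_site_sub_prob, len(self.forward_primer)):
            if not 0 <= p <= 1:
                raise ValueError("substitution probabilities must be in [0, 1]")
        for p in self._probs(self.rev_site_sub_prob, len(self.reverse_primer)):
            if not 0 <= p <= 1:
                raise ValueError("substitution probabilities must be in [0, 1]")
        if self.insert_len_range[0] > self.insert_len_range[1] or self.insert_len_range[0] < 0:
            raise ValueError("invalid insert length range")
        if not 0 <= self.corrupt_fraction <= 1:
            raise ValueError("corrupt_fraction must be in [0, 1]")

    @staticmethod
    def _probs(p, L: int) -> list[float]:
        if isinstance(p, (int, float)):
            return [float(p)] * L
        probs = [float(x) for x in p]
        if len(probs) != L:
            raise ValueError("per-position probabilities must match primer length")
        return probs


@dataclass(frozen=True)
class FixtureDataset:
    """A generated cohort plus everything needed to verify a screen of it."""

    genbank_text: str
    alignment_fasta: str
    truth: pd.DataFrame
    forward_primer: DegeneratePrimer
    reverse_primer: DegeneratePrimer
    records: tuple[GenomeRecord, ...]

    @property
    def alignment(self) -> AlignmentMatrix:
        return AlignmentMatrix.from_fasta(StringIO(self.alignment_fasta))

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genbank": out_dir / "cohort.gb",
            "alignment": out_dir / "genes_aligned.fasta",
            "truth": out_dir / "truth.tsv",
            "primers": out_dir / "primers.tsv",
        }
        paths["genbank"].write_text(self.genbank_text)
        paths["alignment"].write_text(self.alignment_fasta)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["primers"], "w") as fh:
            fh.write("name\tsequence\torientation\tdegeneracy\n")
            for p in (self.forward_primer, self.reverse_primer):
                fh.write(f"{p.name}\t{p.sequence}\t{p.orientation}\t{p.degeneracy}\n")
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.nonzero(hits)[0]:
        choices = [b for b in _BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def _realize_site(
    rng: np.random.Generator, primer_seq: str, probs: Sequence[float]
) -> tuple[str, int]:
    """Concrete realization of a degenerate site with planted mismatches.

    Positions selected for substitution receive a base *outside* the
    primer code's expansion set, so the returned mismatch count is exact
    by construction; all other positions receive a base from inside it.
    """
    out = []
    mismatches = 0
    for code, p in zip(primer_seq, probs):
        inside = sorted(EXPANSIONS[code])
        if rng.random() < p and len(inside) < 4:
            outside = sorted(set(_BASES) - set(inside))
            out.append(outside[rng.integers(len(outside))])
            mismatches += 1
        else:
            out.append(inside[rng.integers(len(inside))])
    return "".join(out), mismatches


def corrupt_annotation(
    record: GenomeRecord, mode: str, rng: np.random.Generator | None = None
) -> GenomeRecord:
    """Damage a record's gene annotation in a controlled way.

    ``shifted`` moves the feature interval away from the true gene,
    ``truncated`` cuts it to 40 bp, and ``mislabelled`` renames it to a
    large-subunit label that no SSU dialect matches.
    """
    rng = rng or np.random.default_rng(0)
    feats = [f for f in record.features if f.kind == "rRNA"]
    if not feats:
        raise ValueError(f"{record.accession}: no rRNA feature to corrupt")
    feat = feats[0]
    others = tuple(f for f in record.features if f is not feat)
    if mode == "shifted":
        span = feat.end - feat.start
        delta = max(60, span // 2)
        new_start = max(0, feat.start - delta) if feat.start >= delta else min(
            record.length - span, feat.start + delta
        )
        new = replace(feat, start=new_start, end=new_start + span)
    elif mode == "truncated":
        new = replace(feat, end=min(feat.start + 40, record.length))
    elif mode == "mislabelled":
        new = replace(feat, label="16S ribosomal RNA")
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")
    return GenomeRecord(
        accession=record.accession,
        organism=record.organism,
        lineage=record.lineage,
        sequence=record.sequence,
        features=others + (new,),
    )


def _to_genbank(records: Sequence[GenomeRecord]) -> str:
    seqs = []
    for r in records:
        sr = SeqRecord(
            Seq(r.sequence),
            id=r.accession,
            name=r.accession.split(".")[0],
            description=f"{r.organism} mitochondrion, complete genome (synthetic)",
        )
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "circular"
        sr.annotations["organism"] = r.organism
        sr.annotations["taxonomy"] = list(r.lineage)
        sr.annotations["accessions"] = [r.accession.split(".")[0]]
        for f in r.features:
            sr.features.append(
                SeqFeature(
                    FeatureLocation(f.start, f.end, strand=f.strand),
                    type=f.kind,
                    qualifiers={"product": [f.label]},
                )
            )
        seqs.append(sr)
    buf = StringIO()
    SeqIO.write(seqs, buf, "genbank")
    return buf.getvalue()


def generate_dataset(spec: FixtureSpec) -> FixtureDataset:
    """Generate a truth-annotated synthetic cohort from a spec.

    Deterministic for a fixed spec: the same seed yields byte-identical
    GenBank text, alignment and truth table.
    """
    fwd = DegeneratePrimer("SYNF", spec.forward_primer, "forward")
    rev = DegeneratePrimer("SYNR", spec.reverse_primer, "reverse")
    max_insert = spec.insert_len_range[1]
    gene_floor = (
        spec.left_flank_len + len(fwd) + spec.insert_len_range[0]
        + len(rev) + spec.right_flank_len
    )
    if gene_floor <= len(fwd) + len(rev):
        raise ValueError("primer sites longer than the gene they must fit in")

    rng = np.random.default_rng(spec.seed)
    fwd_probs = FixtureSpec._probs(spec.fwd_site_sub_prob, len(fwd))
    rev_probs = FixtureSpec._probs(spec.rev_site_sub_prob, len(rev))

    # dataset-wide template for the non-site portions of the gene
    tmpl_left = _random_seq(rng, spec.left_flank_len)
    tmpl_right = _random_seq(rng, spec.right_flank_len)
    tmpl_insert = _random_seq(rng, max_insert)

    dialects = [d for d in DEFAULT_SSU_DIALECTS]
    records: list[GenomeRecord] = []
    aln_rows: list[tuple[str, str]] = []
    truth_rows: list[dict] = []

    idx = 0
    for phylum, n in spec.n_per_phylum.items():
        lineage = tuple(spec.phylum_lineages.get(phylum, ("Metazoa", phylum)))
        for k in range(n):
            idx += 1
            acc = f"SYN{idx:06d}.1"
            organism = f"{phylum[:-1]}us specimen-{k + 1}"
            insert_len = int(rng.integers(spec.insert_len_range[0], max_insert + 1))
            left = _mutate(rng, tmpl_left, spec.background_sub_rate)
            right = _mutate(rng, tmpl_right, spec.background_sub_rate)
            insert = _mutate(rng, tmpl_insert[:insert_len], spec.background_sub_rate)
            fwd_site, fwd_mm = _realize_site(rng, fwd.sequence, fwd_probs)
            rev_site, rev_mm = _realize_site(rng, rev.sequence, rev_probs)
            gene = left + fwd_site + insert + reverse_complement(rev_site) + right

            upstream = _random_seq(
                rng, int(rng.integers(*spec.upstream_len_range))
            )
            downstream = _random_seq(
                rng, int(rng.integers(*spec.downstream_len_range))
            )
            minus = bool(rng.random() < spec.minus_strand_fraction)
            genome_gene = reverse_complement(gene) if minus else gene
            genome = upstream + genome_gene + downstream
            start = len(upstream)
            end = start + len(gene)
            label = dialects[idx % len(dialects)]
            rec = GenomeRecord(
                accession=acc,
                organism=organism,
                lineage=lineage,
                sequence=genome,
                features=(
                    GeneFeature(
                        kind="rRNA", label=label, start=start, end=end,
                        strand=-1 if minus else 1,
                    ),
                ),
            )
            records.append(rec)
            pad = "-" * (max_insert - insert_len)
            aln_rows.append((acc, left + fwd_site + insert + pad
                             + reverse_complement(rev_site) + right))
            truth_rows.append(
                {
                    "accession": acc,
                    "organism": organism,
                    "phylum": phylum,
                    "lineage": ";".join(lineage),
                    "gene_start": start,
                    "gene_end": end,
                    "strand": "-" if minus else "+",
                    "gene_length": len(gene),
                    "insert_length": insert_len,
                    "fwd_mismatches": fwd_mm,
                    "rev_mismatches": rev_mm,
                    "fwd_category": categorize(fwd_mm).value,
                    "rev_category": categorize(rev_mm).value,
                    "corrupted": False,
                    "corruption_mode": "",
                }
            )

    if spec.corrupt_fraction > 0:
        n_bad = int(round(spec.corrupt_fraction * len(records)))
        bad_idx = rng.choice(len(records), size=n_bad, replace=False)
        for i in sorted(int(x) for x in bad_idx):
            mode = spec.corrupt_modes[rng.integers(len(spec.corrupt_modes))]
            records[i] = corrupt_annotation(records[i], mode, rng)
            truth_rows[i]["corrupted"] = True
            truth_rows[i]["corruption_mode"] = mode

    aln_fasta = "".join(f">{acc}\n{row}\n" for acc, row in aln_rows)
    return FixtureDataset(
        genbank_text=_to_genbank(records),
        alignment_fasta=aln_fasta,
        truth=pd.DataFrame(truth_rows),
        forward_primer=fwd,
        reverse_primer=rev,
        records=tuple(records),
    )


def plant_conserved_alignment(
    seed: int,
    n_rows: int = 16,
    block_lengths: tuple[int, int] = (22, 24),
    flank_lengths: tuple[int, int] = (30, 30),
    insert_length: int = 40,
    include_freq: float = 0.10,
    min_majority_freq: float = 0.75,
    degenerate_fraction: float = 0.3,
    gap_columns_in_insert: int = 0,
):
    """Alignment with exactly two conserved blocks at known columns.

    Block columns are built to pass the conservation thresholds by
    construction: each holds one or two bases, any minor base planted in
    enough rows to reach ``include_freq`` while keeping the majority at or
    above ``min_majority_freq``.  Every column outside the blocks receives
    a balanced shuffle of all four bases, so its majority frequency is
    ~0.25 and can never reach a conservation threshold above 0.5.

    Returns ``(alignment, truth)`` where truth carries the planted column
    intervals and the exact degenerate consensus strings they encode
    (forward for the first block, reverse-complemented for the second,
    matching primer orientations).
    """
    if n_rows < 8:
        raise ValueError("need at least 8 rows to plant minor bases reliably")
    rng = np.random.default_rng(seed)
    import math

    minor_lo = max(1, math.ceil(include_freq * n_rows))
    minor_hi = math.floor((1 - min_majority_freq) * n_rows)
    if minor_lo > minor_hi:
        raise ValueError("include_freq and min_majority_freq leave no room for minor bases")

    def conserved_column() -> tuple[list[str], str]:
        major = _BASES[rng.integers(4)]
        if rng.random() < degenerate_fraction:
            minor = [b for b in _BASES if b != major][rng.integers(3)]
            m = int(rng.integers(minor_lo, minor_hi + 1))
            col = [major] * n_rows
            for i in rng.choice(n_rows, size=m, replace=False):
                col[int(i)] = minor
            return col, code_for_bases({major, minor})
        return [major] * n_rows, major

    def noise_column() -> list[str]:
        base = list(_BASES) * (n_rows // 4) + list(_BASES)[: n_rows % 4]
        rng.shuffle(base)
        return base

    cols: list[list[str]] = []
    codes1: list[str] = []
    codes2: list[str] = []

    for _ in range(flank_lengths[0]):
        cols.append(noise_column())
    b1_start = len(cols)
    for _ in range(block_lengths[0]):
        col, code = conserved_column()
        cols.append(col)
        codes1.append(code)
    b1_end = len(cols)
    insert_cols = [noise_column() for _ in range(insert_length)]
    if gap_columns_in_insert:
        gap_idx = rng.choice(insert_length, size=gap_columns_in_insert, replace=False)
        for j in gap_idx:
            col = insert_cols[int(j)]
            n_gaps = int(rng.integers(max(1, n_rows // 2), n_rows + 1))
            for i in rng.choice(n_rows, size=n_gaps, replace=False):
                col[int(i)] = "-"
    cols.extend(insert_cols)
    b2_start = len(cols)
    for _ in range(block_lengths[1]):
        col, code = conserved_column()
        cols.append(col)
        codes2.append(code)
    b2_end = len(cols)
    for _ in range(flank_lengths[1]):
        cols.append(noise_column())

    rows = tuple(
        "".join(cols[j][i] for j in range(len(cols))) for i in range(n_rows)
    )
    ids = tuple(f"row{i:03d}" for i in range(n_rows))
    truth = {
        "regions": [(b1_start, b1_end), (b2_start, b2_end)],
        "forward_consensus": "".join(codes1),
        "reverse_consensus": reverse_complement("".join(codes2)),
    }
    return AlignmentMatrix(ids, rows), truth
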