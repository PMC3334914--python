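"""High-level workflows: excise -> screen -> report.

Thin composition layer over the per-step modules, shared by the command
line interface, the example scripts and the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .conservation import DegeneratePrimer
from .genome_io import (
    DEFAULT_SSU_DIALECTS,
    AmbiguousAnnotationError,
    ExcisedGene,
    GenomeRecord,
    excise_gene,
    find_ssu_rrna,
    validate_excised,
)
from .matching import (
    AmpliconPrediction,
    PositionalProfile,
    PrimerSiteHit,
    best_site,
    categorize,
    positional_profile,
    predict_amplicon,
)
from .report import LengthSummary, ScreenResult, ScreenTable, group_by_rank, length_summary

__all__ = ["excise_all", "ScreenOutcome", "screen_targets", "load_primers"]

logger = logging.getLogger(__name__)


def excise_all(
    records: Sequence[GenomeRecord],
    dialects: Sequence[str] = DEFAULT_SSU_DIALECTS,
    min_len: int = 300,
    max_len: int = 2500,
    max_ambiguous_frac: float = 0.10,
) -> list[ExcisedGene]:
    """Locate, excise and validate the SSU rRNA gene of every record.

    Records with no matching annotation, an ambiguous one, or a gene
    failing validation are returned with ``status="removed"`` and a reason,
    so the manifest accounts for every input record.
    """
    out: list[ExcisedGene] = []
    for rec in records:
        try:
            feat = find_ssu_rrna(rec, dialects)
        except AmbiguousAnnotationError as e:
            out.append(
                ExcisedGene(
                    accession=rec.accession, organism=rec.organism,
                    lineage=rec.lineage, sequence="", start=0, end=0, strand=1,
                    status="removed", reason=f"ambiguous annotation: {e}",
                )
            )
            continue
        if feat is None:
            out.append(
                ExcisedGene(
                    accession=rec.accession, organism=rec.organism,
                    lineage=rec.lineage, sequence="", start=0, end=0, strand=1,
                    status="removed", reason="no SSU rRNA annotation found",
                )
            )
            continue
        gene = excise_gene(rec, feat)
        out.append(validate_excised(gene, min_len, max_len, max_ambiguous_frac))
    n_removed = sum(1 for g in out if g.status == "removed")
    logger.info("excised %d records, removed %d", len(out), n_removed)
    return out


def load_primers(path) -> list[DegeneratePrimer]:
    """Load primers from TSV (name, sequence, orientation columns).

    Lines starting with ``#`` are ignored; a header row is detected by the
    literal column name ``sequence`` in the second field.
    """
    primers: list[DegeneratePrimer] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"primer TSV needs 3 columns, got: {line!r}")
            if parts[1].lower() == "sequence":
                continue
            primers.append(DegeneratePrimer(parts[0], parts[1], parts[2]))
    return primers


@dataclass
class ScreenOutcome:
    """Everything a primer-pair screen of a cohort produces."""

    results: list[ScreenResult]
    hits: dict[str, list[PrimerSiteHit]]
    predictions: list[AmpliconPrediction]
    exclusions: list[tuple[str, str]]  # (target id, reason)
    table: ScreenTable | None = None
    profiles: dict[str, PositionalProfile] = field(default_factory=dict)
    lengths: LengthSummary | None = None


def screen_targets(
    primers: Sequence[DegeneratePrimer],
    targets: Sequence[ExcisedGene],
    rank: int | Sequence[str] | None = None,
    band: tuple[int, int] = (400, 600),
    flag_threshold: float = 0.35,
) -> ScreenOutcome:
    """Screen every kept target against every primer and aggregate.

    Each primer is placed independently at its best site; targets shorter
    than a primer (or already removed upstream) go to the exclusion list
    rather than into any denominator.  Amplicons are predicted only where
    the forward and reverse footprints sit in amplifiable order.
    """
    outcome = ScreenOutcome(results=[], hits={p.name: [] for p in primers},
                            predictions=[], exclusions=[])
    fwd = next((p for p in primers if p.orientation == "forward"), None)
    rev = next((p for p in primers if p.orientation == "reverse"), None)

    for g in targets:
        if g.status != "kept":
            outcome.exclusions.append((g.accession, g.reason or "removed"))
            continue
        cats = {}
        per_target: dict[str, PrimerSiteHit] = {}
        failed = None
        for p in primers:
            try:
                hit = best_site(p, g)
            except ValueError as e:
                failed = str(e)
                break
            per_target[p.name] = hit
            cats[p.name] = categorize(hit)
        if failed is not None:
            outcome.exclusions.append((g.accession, failed))
            continue
        for name, hit in per_target.items():
            outcome.hits[name].append(hit)
        outcome.results.append(
            ScreenResult(target_id=g.accession, lineage=g.lineage, categories=cats)
        )
        if fwd is not None and rev is not None:
            try:
                outcome.predictions.append(
                    predict_amplicon(per_target[fwd.name], per_target[rev.name])
                )
            except ValueError as e:
                outcome.exclusions.append((g.accession, str(e)))

    if rank is not None and outcome.results:
        outcome.table = group_by_rank(outcome.results, rank)
    for p in primers:
        if outcome.hits[p.name]:
            outcome.profiles[p.name] = positional_profile(
                p, outcome.hits[p.name], flag_threshold
            )
    if outcome.predictions:
        outcome.lengths = length_summary(outcome.predictions, band)
    return outcome
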