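"""IUPAC-aware ungapped primer-site search, mismatch profiling, amplicons.

The matching model is deliberately simple and positional: a primer binds a
target in an ungapped footprint, a primer code and a template base are
compatible when their IUPAC base sets intersect, and the best site is the
offset with the fewest incompatible positions (smallest offset on ties).
Mismatch counts feed the three-way compatibility categories used in
taxon-coverage tables (0 / 1 / >=2 mismatches); per-position statistics
are always reported counting from the primer's 3' end, the end that
matters most for polymerase extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .conservation import DegeneratePrimer
from .iupac import encode_masks, iupac_match, reverse_complement

__all__ = [
    "PrimerSiteHit",
    "MismatchCategory",
    "PositionalProfile",
    "AmpliconPrediction",
    "iupac_match",
    "best_site",
    "categorize",
    "positional_profile",
    "predict_amplicon",
]

_BASES = "ACGT"


class MismatchCategory(str, Enum):
    """Three-way primer-compatibility category of a best binding site."""

    NO_MISMATCH = "no_mismatch"
    ONE_MISMATCH = "one_mismatch"
    TWO_OR_MORE = "two_or_more"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CATEGORIES: tuple[MismatchCategory, ...] = (
    MismatchCategory.NO_MISMATCH,
    MismatchCategory.ONE_MISMATCH,
    MismatchCategory.TWO_OR_MORE,
)


@dataclass(frozen=True)
class PrimerSiteHit:
    """Best ungapped binding footprint of one primer on one target.

    ``match_flags[p-1]`` is the compatibility flag for primer position
    ``p`` counted from the 3' end (position 1 = 3' terminus), regardless
    of primer orientation.  ``footprint`` is the bound target subsequence
    on the target's sense strand.
    """

    target_id: str
    primer_name: str
    orientation: str
    offset: int
    footprint: str
    mismatch_count: int
    match_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.mismatch_count != sum(1 for f in self.match_flags if not f):
            raise ValueError("mismatch_count inconsistent with match_flags")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")

    @property
    def length(self) -> int:
        return len(self.footprint)

    @property
    def end(self) -> int:
        return self.offset + self.length

    def flags_3to5(self) -> str:
        """Match flags as a 0/1 string, 3' end first (1 = match)."""
        return "".join("1" if f else "0" for f in self.match_flags)


@dataclass(frozen=True)
class AmpliconPrediction:
    """Predicted PCR product from a compatible forward/reverse hit pair."""

    target_id: str
    forward: PrimerSiteHit
    reverse: PrimerSiteHit
    insert_length: int
    total_length: int


def _target_fields(target) -> tuple[str, str]:
    if isinstance(target, str):
        return "target", target
    if isinstance(target, tuple):
        return target
    return target.accession, target.sequence


def best_site(primer: DegeneratePrimer, target) -> PrimerSiteHit:
    """Minimum-mismatch ungapped placement of a primer on a target.

    ``target`` may be an :class:`~primerscope.genome_io.ExcisedGene`, an
    ``(id, sequence)`` pair, or a bare sequence string.  Reverse-orientation
    primers are reverse-complemented first so the footprint is located on
    the target's sense strand.  All offsets are scored; ties go to the
    smallest offset.  Raises ``ValueError`` if the target is shorter than
    the primer.
    """
    tid, tseq = _target_fields(target)
    fp_seq = (
        reverse_complement(primer.sequence)
        if primer.orientation == "reverse"
        else primer.sequence
    )
    L = len(fp_seq)
    if len(tseq) < L:
        raise ValueError(
            f"target {tid!r} ({len(tseq)} bp) shorter than primer {primer.name} ({L} bp)"
        )
    pmask = encode_masks(fp_seq)
    tmask = encode_masks(tseq)
    windows = sliding_window_view(tmask, L)
    matches = (windows & pmask) != 0  # (n_offsets, L)
    mm = L - matches.sum(axis=1)
    off = int(np.argmin(mm))  # argmin returns the first (smallest) offset
    sense_flags = matches[off]
    # 3'-end-first indexing: forward primers end 3' at the footprint's right
    # edge, reverse primers at its left edge.
    flags = sense_flags if primer.orientation == "reverse" else sense_flags[::-1]
    return PrimerSiteHit(
        target_id=tid,
        primer_name=primer.name,
        orientation=primer.orientation,
        offset=off,
        footprint=tseq[off : off + L],
        mismatch_count=int(mm[off]),
        match_flags=tuple(bool(f) for f in flags),
    )


def categorize(hit: PrimerSiteHit | int) -> MismatchCategory:
    """Map a best-site mismatch count to its three-way category."""
    mm = hit if isinstance(hit, int) else hit.mismatch_count
    if mm == 0:
        return MismatchCategory.NO_MISMATCH
    if mm == 1:
        return MismatchCategory.ONE_MISMATCH
    return MismatchCategory.TWO_OR_MORE


@dataclass(frozen=True)
class PositionalProfile:
    """Per-position target-base composition under a primer, 3' end first.

    Row ``p-1`` of ``base_counts`` tallies the template base observed under
    primer position ``p`` from the 3' end, read on the primer's own strand
    so it is directly comparable to the primer code at that position.
    ``flagged`` marks positions whose match fraction falls below the report
    threshold (by default 0.35 --- positions this poorly matched are likely
    to impair annealing).
    """

    primer_name: str
    primer_sequence: str
    n_hits: int
    base_counts: tuple[tuple[int, int, int, int, int], ...]  # A,C,G,T,other
    match_fraction: tuple[float, ...]
    flagged: tuple[bool, ...]
    flag_threshold: float

    def __len__(self) -> int:
        return len(self.match_fraction)

    def flagged_positions(self) -> tuple[int, ...]:
        """1-based positions from the 3' end flagged as poorly matched."""
        return tuple(i + 1 for i, f in enumerate(self.flagged) if f)


def positional_profile(
    primer: DegeneratePrimer,
    hits: Sequence[PrimerSiteHit],
    flag_threshold: float = 0.35,
) -> PositionalProfile:
    """Tally target bases under each primer position across many hits."""
    if not hits:
        raise ValueError("positional_profile needs at least one hit")
    L = len(primer.sequence)
    # primer codes ordered 3'->5' to match position numbering
    codes_3to5 = primer.sequence[::-1]
    counts = np.zeros((L, 5), dtype=np.int64)
    match_n = np.zeros(L, dtype=np.int64)
    for h in hits:
        if h.primer_name != primer.name:
            raise ValueError(f"hit for {h.primer_name!r} passed to {primer.name!r}")
        if len(h.footprint) != L:
            raise ValueError("hit footprint length differs from primer length")
        # read the bound template on the primer's strand, ordered 3'->5';
        # a reverse primer anneals to the antisense strand, so complement
        if primer.orientation == "reverse":
            obs = reverse_complement(h.footprint)[::-1]
        else:
            obs = h.footprint[::-1]
        for p in range(L):
            b = obs[p]
            col = _BASES.find(b)
            counts[p, col if col >= 0 else 4] += 1
            if iupac_match(b, codes_3to5[p]):
                match_n[p] += 1
    frac = match_n / len(hits)
    return PositionalProfile(
        primer_name=primer.name,
        primer_sequence=primer.sequence,
        n_hits=len(hits),
        base_counts=tuple(tuple(int(x) for x in row) for row in counts),
        match_fraction=tuple(float(f) for f in frac),
        flagged=tuple(bool(f < flag_threshold) for f in frac),
        flag_threshold=flag_threshold,
    )


def predict_amplicon(
    fwd: PrimerSiteHit, rev: PrimerSiteHit
) -> AmpliconPrediction:
    """Amplicon length from a forward and a reverse hit on one target.

    The insert length excludes both primer footprints; the total adds them
    back.  Footprints that overlap or sit in amplification-incompatible
    order raise ``ValueError``.
    """
    if fwd.target_id != rev.target_id:
        raise ValueError("hits are on different targets")
    insert = rev.offset - fwd.end
    if insert < 0:
        raise ValueError(
            f"no amplifiable orientation on {fwd.target_id!r}: "
            f"reverse footprint starts before the forward footprint ends"
        )
    return AmpliconPrediction(
        target_id=fwd.target_id,
        forward=fwd,
        reverse=rev,
        insert_length=insert,
        total_length=insert + fwd.length + rev.length,
    )
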