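"""Taxon-grouped coverage tables and amplicon-length summaries.

A screen of many targets against a primer pair is condensed into one row
per taxonomic group: the number of targets and, for each primer, the count
and percentage of targets whose best site has zero, one, or two-or-more
mismatches.  Grouping keys come from the lineage strings carried by the
source records --- no live taxonomy lookup --- and row order follows first
appearance in the input, mirroring how records are listed in the source
database.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import CATEGORIES, MismatchCategory, AmpliconPrediction, PositionalProfile

__all__ = [
    "ScreenResult",
    "ScreenTable",
    "LengthSummary",
    "group_by_rank",
    "length_summary",
    "write_reports",
]

UNASSIGNED = "unassigned"

_BASES = "ACGT"


@dataclass(frozen=True)
class ScreenResult:
    """Per-target screening outcome: one category per primer, plus lineage."""

    target_id: str
    lineage: tuple[str, ...]
    categories: Mapping[str, MismatchCategory]  # primer name -> category


@dataclass(frozen=True)
class ScreenTable:
    """Coverage table: one row per taxon group, counts/percentages per primer."""

    frame: pd.DataFrame
    primer_names: tuple[str, ...]
    rank: object

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.frame["group"])

    def total_n(self) -> int:
        return int(self.frame["n"].sum())


def _group_key(lineage: Sequence[str], rank) -> str:
    """Resolve a target's group from its lineage.

    ``rank`` may be an integer depth into the lineage (0 = root-most
    element; negative counts from the deepest element, so -1 is the finest
    clade recorded) or a collection of clade names, in which case the first
    lineage element found in that collection is the key.  Targets whose
    lineage cannot resolve the rank fall into the ``unassigned`` group.
    """
    if isinstance(rank, int):
        if -len(lineage) <= rank < len(lineage):
            return lineage[rank]
        return UNASSIGNED
    names = rank if isinstance(rank, (set, frozenset)) else set(rank)
    for clade in lineage:
        if clade in names:
            return clade
    return UNASSIGNED


def group_by_rank(
    results: Iterable[ScreenResult],
    rank: int | Collection[str],
) -> ScreenTable:
    """Aggregate per-target categories into a taxon-grouped coverage table.

    Counts and percentages (to 2 decimals) are produced per primer per
    category; within a row and primer the three counts always sum to the
    row's n.  Row order follows first appearance in the input.
    """
    results = list(results)
    primer_names: list[str] = []
    for r in results:
        for p in r.categories:
            if p not in primer_names:
                primer_names.append(p)

    order: list[str] = []
    tallies: dict[str, dict[tuple[str, MismatchCategory], int]] = {}
    sizes: dict[str, int] = {}
    for r in results:
        key = _group_key(r.lineage, rank)
        if key not in tallies:
            order.append(key)
            tallies[key] = {}
            sizes[key] = 0
        sizes[key] += 1
        for p, cat in r.categories.items():
            tallies[key][(p, cat)] = tallies[key].get((p, cat), 0) + 1

    rows = []
    for key in order:
        n = sizes[key]
        row: dict[str, object] = {"group": key, "n": n}
        for p in primer_names:
            for cat in CATEGORIES:
                c = tallies[key].get((p, cat), 0)
                row[f"{p}:{cat.value}:count"] = c
                row[f"{p}:{cat.value}:pct"] = round(100.0 * c / n, 2)
        rows.append(row)
    frame = pd.DataFrame(rows)
    return ScreenTable(frame=frame, primer_names=tuple(primer_names), rank=rank)


@dataclass(frozen=True)
class LengthSummary:
    """Distribution summary of predicted insert lengths (primers excluded)."""

    n: int
    min_bp: int
    max_bp: int
    bin_edges: tuple[int, ...]
    bin_counts: tuple[int, ...]
    band: tuple[int, int]
    band_count: int


def length_summary(
    preds: Sequence[AmpliconPrediction],
    band: tuple[int, int] = (400, 600),
    bin_width: int = 100,
) -> LengthSummary:
    """Min/max, histogram and focal-band count over predicted insert lengths.

    Lengths follow the "without primers" convention (insert only).  The
    band count is inclusive of both endpoints.
    """
    if not preds:
        raise ValueError("length_summary needs at least one prediction")
    lo, hi = band
    if lo > hi:
        raise ValueError("band lo must be <= hi")
    lengths = np.array([p.insert_length for p in preds], dtype=np.int64)
    left = (int(lengths.min()) // bin_width) * bin_width
    right = ((int(lengths.max()) // bin_width) + 1) * bin_width
    edges = np.arange(left, right + 1, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    return LengthSummary(
        n=len(lengths),
        min_bp=int(lengths.min()),
        max_bp=int(lengths.max()),
        bin_edges=tuple(int(e) for e in edges),
        bin_counts=tuple(int(c) for c in counts),
        band=(lo, hi),
        band_count=int(((lengths >= lo) & (lengths <= hi)).sum()),
    )


def screen_table_tsv(table: ScreenTable) -> str:
    """Render a ScreenTable as deterministic TSV text."""
    header = ["group", "n"]
    for p in table.primer_names:
        for cat in CATEGORIES:
            header += [f"{p}.{cat.value}.pct", f"{p}.{cat.value}.count"]
    lines = ["\t".join(header)]
    for _, row in table.frame.iterrows():
        cells = [str(row["group"]), str(int(row["n"]))]
        for p in table.primer_names:
            for cat in CATEGORIES:
                cells.append(f"{row[f'{p}:{cat.value}:pct']:.2f}")
                cells.append(str(int(row[f"{p}:{cat.value}:count"])))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def length_summary_tsv(summary: LengthSummary) -> str:
    lines = [
        "metric\tvalue",
        f"n\t{summary.n}",
        f"min_bp\t{summary.min_bp}",
        f"max_bp\t{summary.max_bp}",
        f"band\t{summary.band[0]}-{summary.band[1]}",
        f"band_count\t{summary.band_count}",
        "bin_start\tbin_end\tcount",
    ]
    for i, c in enumerate(summary.bin_counts):
        lines.append(f"{summary.bin_edges[i]}\t{summary.bin_edges[i + 1]}\t{c}")
    return "\n".join(lines) + "\n"


def profile_tsv(profile: PositionalProfile) -> str:
    lines = [
        f"# primer\t{profile.primer_name}\t{profile.primer_sequence}",
        f"# n_hits\t{profile.n_hits}",
        "position_3prime\tprimer_code\tA\tC\tG\tT\tother\tmatch_fraction\tflagged",
    ]
    codes = profile.primer_sequence[::-1]
    for p in range(len(profile)):
        a, c, g, t, o = profile.base_counts[p]
        lines.append(
            f"{p + 1}\t{codes[p]}\t{a}\t{c}\t{g}\t{t}\t{o}\t"
            f"{profile.match_fraction[p]:.4f}\t{int(profile.flagged[p])}"
        )
    return "\n".join(lines) + "\n"


def write_reports(
    out_dir: str | Path,
    table: ScreenTable | None = None,
    summary: LengthSummary | None = None,
    profiles: Sequence[PositionalProfile] = (),
    plot: bool = False,
) -> list[Path]:
    """Write deterministic TSV reports (and optionally a composition plot).

    Returns the paths written.  Output is byte-stable for identical inputs:
    fixed column order, fixed decimal formatting, ordering inherited from
    the inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if table is not None:
        p = out_dir / "screen_table.tsv"
        p.write_text(screen_table_tsv(table))
        written.append(p)
    if summary is not None:
        p = out_dir / "length_summary.tsv"
        p.write_text(length_summary_tsv(summary))
        written.append(p)
    for prof in profiles:
        p = out_dir / f"positional_profile_{prof.primer_name}.tsv"
        p.write_text(profile_tsv(prof))
        written.append(p)
        if plot:
            written.append(_plot_profile(prof, out_dir))
    return written


def _plot_profile(profile: PositionalProfile, out_dir: Path) -> Path:
    """Stacked-bar plot of target-base composition per primer position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    L = len(profile)
    xs = np.arange(1, L + 1)
    mat = np.array(profile.base_counts, dtype=float)
    fig, ax = plt.subplots(figsize=(max(6, L * 0.4), 4))
    bottom = np.zeros(L)
    colors = {"A": "#4daf4a", "C": "#377eb8", "G": "#ff7f00", "T": "#e41a1c", "other": "#999999"}
    for i, base in enumerate(list(_BASES) + ["other"]):
        ax.bar(xs, mat[:, i], bottom=bottom, label=base, color=colors[base])
        bottom += mat[:, i]
    ax.set_xlabel("primer position from 3' end")
    ax.set_ylabel("target base count")
    ax.set_title(f"{profile.primer_name} target composition (n={profile.n_hits})")
    ax.set_xticks(xs)
    ax.set_xticklabels(list(profile.primer_sequence[::-1]))
    ax.legend(ncol=5, fontsize=8)
    path = out_dir / f"positional_profile_{profile.primer_name}.svg"
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
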