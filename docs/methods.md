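# Methods

## Scope and model

`primerscope` models in-silico PCR compatibility as a purely positional,
ungapped problem. A primer is an IUPAC string read 5′→3′ as synthesised; a
target is an excised marker-gene sequence on its own sense strand. The
primer's footprint is an ungapped window of the target; a primer code and
a template base are compatible when their IUPAC base sets intersect; the
best site is the window with the fewest incompatible positions, ties going
to the smallest offset so results are deterministic. There is no
thermodynamic annealing model, no indel/bulge handling inside the
footprint, and no weighting of mismatches by position: the model is the
mismatch *count* plus, separately, the *location* of mismatches reported
from the 3′ end, which is how primer-compatibility surveys of marker genes
are usually summarised. The three-way category (0, 1, ≥2 mismatches) is a
deliberate simplification: one 3′-terminal mismatch can abort a reaction
that three 5′ mismatches would survive, so the categories are paired with
the 3′-anchored positional profile rather than replaced by a severity
score.

Set-intersection semantics make ambiguity in the *target* (N and friends)
count as a match whenever the sets overlap. This is a neutrality choice:
an unknown base is not evidence of incompatibility, so mismatch counts are
not inflated by sequencing ambiguity. The cost is that a fully degenerate
target region can never register mismatches; the validation stage bounds
this by removing genes with more than 10% ambiguous bases.

The implementation encodes each code as a 4-bit base mask (A=1, C=2, G=4,
T=8); compatibility is a bitwise AND, and the best-site scan is a
vectorised sliding-window reduction over the mask arrays. Its
equivalence to the naive double-loop minimum-Hamming search is asserted
exhaustively in the test suite and re-measured by the acceptance script.

## Gene excision and validation

GenBank records are parsed with Biopython; coordinates are converted to
0-based half-open internally and back to 1-based inclusive in manifests,
so round-trips with the flat-file format are lossless. The SSU rRNA
feature is located by case-insensitive substring match of the feature
label against a configurable dialect list (`12S`, `s-rRNA`, `rrnS`,
`small subunit ribosomal RNA`, `12S ribosomal RNA`, `MT-RNR1`); public
mitogenome annotations do not use a single controlled vocabulary, and the
list is config so users can extend it. Two or more distinct matching
features, or a compound (multi-interval) location, raise an "ambiguous
annotation" error rather than guessing: the SSU gene is contiguous in
mitogenomes, so a compound location is itself evidence of an annotation
problem. Minus-strand features are reverse-complemented so excised genes
always read 5′→3′ of the gene.

Validation is an explicit keep/remove rule with a logged reason: length
within [300, 2500] bp and at most 10% ambiguous bases. The bounds are
generous envelopes around known metazoan mitochondrial SSU lengths
(roughly 600–1000 bp in most phyla, shorter in some nematodes and
chaetognaths); genes failing them almost always carry mis-drawn
coordinates rather than real biology. Widening the bounds can only move
records from removed to kept (a property the tests assert), so the rule
is monotone and auditable.

## Conservation and consensus

Column profiles count A/C/G/T, other (ambiguity codes) and gaps per
column; majority base and frequency are computed over A/C/G/T only, since
gaps and ambiguity codes carry no positional information, and ties break
alphabetically for determinism. A column qualifies as conserved when
majority frequency ≥ `min_majority_freq` (default 0.75) and gap fraction
≤ `max_gap_fraction` (default 0.10); conserved regions are maximal runs of
qualifying columns of length ≥ `min_length` (default 20, a workable primer
footprint). Gap-rich columns disqualify rather than being deleted because
a primer cannot span an indel-rich site. The defaults are design choices,
not published constants: a 0.75 majority over a broad taxonomic sample is
strict enough to reject variable-region columns yet loose enough to keep
sites that need one degenerate position.

The degenerate consensus of a region covers, per column, every base with
gap-excluded frequency ≥ `include_freq` (default 0.10) plus the majority
base unconditionally; lowering `include_freq` can only add bases, so
degeneracy is monotone in it (asserted as a property). Reverse-orientation
primers are emitted as the reverse complement of the sense consensus so
the string is directly synthesisable. When a design run yields two or more
regions, the first becomes the forward and the last the reverse primer —
the pair flanks the variable region between them, which is what gives the
amplicon its taxonomic signal.

Locating the primer-homologous region in sequences that resist global
alignment is handled by the same best-site search used for screening,
rather than by a second, seeded alignment engine: both procedures answer
"where does this primer-shaped pattern sit in this sequence", and one
engine keeps the two answers consistent by construction.

## Screening and reporting

Each primer is screened independently (coverage tables report forward and
reverse columns separately); amplicon prediction additionally requires the
reverse footprint to start at or after the forward footprint's end, and
reports the insert length excluding both footprints — the "without
primers" convention — plus the total with them. Targets that cannot be
scored (removed upstream, or shorter than a primer) are excluded from all
denominators and listed in a sidecar exclusions file.

Grouping uses the lineage strings carried by the GenBank records
themselves — no live taxonomy service, so runs are reproducible offline.
The rank is either an integer depth into the lineage (negative indexes
from the deepest element; −1, the default, groups by the finest recorded
clade) or a set of clade names. Rows follow first appearance in the
input, percentages are printed to 2 decimals, and all report files are
byte-deterministic for identical inputs. Per-row, per-primer category
counts always sum to the row's n; rounded percentages sum to 100.00
within ±0.02.

Positional profiles tally the template base observed under each primer
position across all hits, on the primer's own strand so the tally is
directly comparable to the primer code, ordered 3′→5′ (position 1 = 3′
terminus). Positions with match fraction below `flag_threshold` (default
0.35) are flagged as likely annealing liabilities.

## Synthetic cohorts

The generator plants what the pipeline must recover. Each synthetic gene
is `left flank + forward site + insert + revcomp(reverse site) + right
flank`; each genome wraps the gene (on a random strand, half minus by
default) in random flanking sequence with a GenBank rRNA annotation whose
label cycles through the dialect list. Primer-site realisations draw each
position from inside the code's expansion set, or — with the configured
per-position substitution probability — from *outside* it, so the recorded
per-primer mismatch count is exact by construction rather than estimated.
Flanks and insert derive from one dataset-wide template mutated at
`background_sub_rate` (default 0.35), keeping the regions outside the
primer sites visibly diverged, as in a variable marker region, while the
sites stay conserved. Insert lengths are uniform on [350, 700] bp and
flanks fixed at 120/140 bp, giving genes of ~650–1000 bp — the scale of
real mitochondrial SSU genes and of the amplicon sizes a survey of them
would predict. An aligned-FASTA variant pads the variable insert with
gaps at fixed columns; a `corrupt_fraction` of records receives shifted,
truncated or mislabelled annotations so the validation path is exercised
with known flags.

For conservation tests, a second generator (`plant_conserved_alignment`)
builds alignments whose truth is exact by construction: block columns hold
one or two bases with the minor base planted in enough rows to clear
`include_freq` while keeping the majority at or above `min_majority_freq`,
and every column outside the blocks is a balanced shuffle of all four
bases, whose majority frequency (~0.25–0.33) can never reach a threshold
above 0.5. Recovery of the planted intervals and consensus strings is
therefore a sharp, not statistical, check.

What the fixtures do *not* emulate: phylogenetic correlation between
records, rate heterogeneity along the gene, indels inside primer sites,
and compositional bias. Passing tests therefore demonstrate that the
machinery is correct — coordinates, orientations, counting, grouping,
arithmetic — not that any particular real primer pair will perform as
predicted on real genomes; that judgement still needs real sequence
collections, which the same pipeline accepts as GenBank or FASTA input.

Planted-site recovery assumes substitution rates in the regime of real
conserved primer sites (roughly ≤0.25 per position). At extreme rates the
planted site accumulates so many mismatches that some random offset
legitimately scores better, and the best-site search — correctly — reports
that offset instead; the generator guarantees mismatch counts *at the
planted site*, not global minimality under arbitrary noise.

## Numerical and interface choices

- Best-site ties break to the smallest offset; majority-base ties break
  alphabetically; both purely for determinism.
- Degeneracy of the empty string is 1 (empty product), though primers are
  required non-empty.
- Category percentages are computed as 100·count/n and rounded to 2
  decimals at the reporting boundary only; internal arithmetic is exact
  integer counting.
- The acceptance script scales the brute-force equivalence check to 2,000
  random pairs and the end-to-end screen to 2,000 records (4 phyla × 500),
  sizes at which every statistical check is already decisive; the test
  suite runs the equivalence check at 10,000 pairs.
- Statistical assertions in the tests use 3 binomial standard errors per
  comparison at cohort scale, and a family-wise 4-SE bound where ~22
  positions are checked simultaneously at small n (a per-position 3-SE
  band would false-alarm on ~6% of correct runs).
- Exit codes of the CLI: 0 success (warnings allowed), 1 usage or
  configuration error, 2 data error.

## Known limitations

- No melting-temperature, GC-content or secondary-structure scoring; the
  design stage ranks by conservation only.
- One best site per primer per target: multi-site templates (e.g. nuclear
  mitochondrial insertions) yield only their best footprint, and only one
  amplicon per template is predicted.
- Circular-genome features spanning the origin, and compound feature
  locations generally, are rejected rather than resolved.
- Coverage categories weight all mismatch positions equally; use the
  positional profiles to judge 3′-end risk.
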