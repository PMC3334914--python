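"""Design a degenerate primer pair from a gapped multiple alignment.

Builds an alignment with two planted conserved blocks flanking a variable
insert (the situation a primer designer looks for in a marker gene), finds
maximal conserved column runs, and collapses each into an IUPAC-degenerate
consensus primer: forward from the upstream block, reverse (reverse-
complemented, 5'->3' as synthesised) from the downstream block.
"""

from primerscope import (
    column_profiles,
    degenerate_consensus,
    find_conserved_regions,
    plant_conserved_alignment,
)

aln, truth = plant_conserved_alignment(
    seed=202, n_rows=16, block_lengths=(22, 24), insert_length=40,
    degenerate_fraction=0.3,
)
print(f"alignment: {aln.n_rows} rows x {aln.n_cols} columns")

profiles = column_profiles(aln)
regions = find_conserved_regions(
    profiles, min_length=20, min_majority_freq=0.75, max_gap_fraction=0.10
)
for r in regions:
    print(f"conserved region: columns [{r.start}, {r.end}) "
          f"({r.length} cols, mean majority frequency {r.mean_majority_frequency:.3f})")

fwd = degenerate_consensus(aln, regions[0], include_freq=0.10,
                           orientation="forward", name="F1")
rev = degenerate_consensus(aln, regions[-1], include_freq=0.10,
                           orientation="reverse", name="R1")
for p in (fwd, rev):
    print(f"{p.name} ({p.orientation:>7}): 5'-{p.sequence}-3'  "
          f"degeneracy={p.degeneracy}")

print("\nforward consensus equals the planted truth:",
      fwd.sequence == truth["forward_consensus"])
print("reverse consensus equals the planted truth:",
      rev.sequence == truth["reverse_consensus"])
print("degeneracy is the number of concrete oligo variants one synthesis "
      "of the degenerate string covers.")
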