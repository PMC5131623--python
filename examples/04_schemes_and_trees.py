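"""The six concatenation schemes and tree inference against known truth.

Builds the analysis schemes (non-coding, filtered, coding, degenerate-
recoded, protein, combined) from a simulated cohort, infers the NJ tree of
the combined scheme and measures its Robinson-Foulds distance to the tree
the sequences were actually generated along.
"""

from plastsurvey.pipeline import build_scheme_set
from plastsurvey.simulate import simulate_cohort
from plastsurvey.trees import nj_from_alignment, rf_distance

cohort = simulate_cohort(n_taxa=8, seed=2)
schemes = build_scheme_set(cohort.genomes, min_ir=1_000)

print("scheme widths (alignment columns):")
for name, aln in schemes.schemes.items():
    print(f"  {name:15s} {aln.width:>7,}")

full_tree = nj_from_alignment(schemes.schemes["full"])
print("\nRF distance of the full-scheme NJ tree to the generating tree:",
      rf_distance(full_tree, cohort.tree))

# RF 0 means the inferred unrooted topology is identical to the truth; the
# combined scheme concatenates ~50 kb per taxon, far more signal than any
# single marker provides.
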