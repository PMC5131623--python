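"""Quadripartite structure of one annotated plastome.

Simulates a small cohort, takes one genome, finds the inverted repeat de
novo and prints the region table and the four junction contexts.
"""

from plastsurvey import detect_inverted_repeats, region_stats, report_junctions
from plastsurvey.simulate import simulate_cohort

genome = simulate_cohort(n_taxa=4, seed=1).genomes[0]
partition = detect_inverted_repeats(genome, min_ir=1_000)
stats = region_stats(genome, partition)

print(f"genome {genome.id}: {genome.length:,} bp")
for region in ("lsc", "ssc", "ir", "full"):
    print(f"  {region.upper():4s} {stats.lengths[region]:>7,} bp  GC {stats.gc[region]:.3f}")
print("tiling check: LSC + SSC + 2*IR =",
      stats.lengths["lsc"] + stats.lengths["ssc"] + 2 * stats.lengths["ir"])

print("\njunctions (boundary position -> gene containing it, or flanking spacer):")
for j in report_junctions(genome, partition):
    where = ", ".join(j.within) if j.within else f"between {j.flanking[0]} and {j.flanking[1]}"
    print(f"  {j.junction:8s} at {j.position:>7,}: {where}")

# The four regions tile the circle exactly; the two IR copies are exact
# reverse complements, so their lengths and GC are identical by construction.
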