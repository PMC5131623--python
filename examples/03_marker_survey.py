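"""End-to-end marker-informativeness survey on a simulated cohort.

One spacer is made to evolve five times faster than everything else; the
survey extracts all introns and PCR-sized spacers, builds per-marker
bootstrap NJ trees, compares them to the cohort's own full-scheme tree and
ranks by the composite score.  The fast marker should surface at rank 1.
"""

from plastsurvey.ranking import survey
from plastsurvey.simulate import simulate_cohort

cohort = simulate_cohort(n_taxa=8, seed=5, rate_multipliers={"trnS-trnG spacer": 5.0})
table = survey(cohort.genomes, min_ir=1_000, replicates=50, seed=1)

cols = ["rank", "marker", "variable_n", "k80_mean", "bootstrap_mean", "rf_to_reference", "score"]
print(table[cols].head(8).to_string(index=False))

# score = (1*v_rel + 2*b_rel + 3*d_rel) / 6 over column-relative metrics;
# a marker that accumulates substitutions faster has more variable sites,
# better-supported trees, and a topology closer to the whole-plastome tree.
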