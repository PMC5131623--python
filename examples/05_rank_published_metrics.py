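"""Composite ranking applied to the published top-10 marker metrics.

Scores the shipped per-marker survey metrics (variable sites, mean
bootstrap, RF distance to the whole-plastome tree) with the survey-wide
column maxima and prints the resulting order next to the published ranks.
"""

from plastsurvey.alnstats import AlignmentSummary
from plastsurvey.published import SURVEY_COLUMN_MAX, marker_table
from plastsurvey.ranking import MarkerReport, rank_markers

reports = []
table = marker_table()
for row in table.itertuples():
    summary = AlignmentSummary(
        name=row.marker, mclass=row.mclass, n_taxa=16,
        aligned_length=int(row.aligned_bp), mean_seq_length=float(row.bases_mean),
        min_seq_length=int(row.bases_min), max_seq_length=int(row.bases_max),
        n_variable=int(row.variable_n), pct_variable=row.variable_n / row.aligned_bp,
        n_pis=int(row.pis_n), pct_pis=row.pis_n / row.aligned_bp,
        mean_k80=float(row.k80_mean),
    )
    reports.append(MarkerReport(summary, float(row.bootstrap_mean), int(row.rf_to_reference)))

ranked = rank_markers(reports, column_max=SURVEY_COLUMN_MAX)
published = dict(zip(table.marker, table.published_rank))
print(f"{'computed':>8s}  {'published':>9s}  marker")
for r in ranked:
    print(f"{r.rank:>8d}  {published[r.summary.name]:>9d}  {r.summary.name}  (score {r.score:.3f})")

# Relative values divide each metric by its survey-wide maximum (RF
# inverted); weights 1/2/3 for variability, support, and topological
# agreement put trnS-trnG first and ndhF-rpl32 second.
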