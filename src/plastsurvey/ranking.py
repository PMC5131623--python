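"""Composite marker-informativeness score and the survey report.

Each surveyed marker (intron or intergenic spacer) gets a score in [0, 1]:
a weighted mean of three relative metrics — number of variable sites
(weight 1), mean bootstrap support of its own tree (weight 2), and
topological closeness of that tree to the reference plastome tree
(weight 3, Robinson-Foulds distance inverted).  Relative values are raw
values divided by the survey-wide column maximum, with RF inverted as
``1 - d/max(d)`` so that agreeing with the reference scores high.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alnstats import AlignmentSummary, summarize_alignment
from .errors import DegenerateSurveyError, SaturationError, TooFewTaxaError, TreeError
from .model import CircularGenome, MarkerAlignment
from .trees import PhyloTree, bootstrap_support, mean_support, pruned, rf_distance

log = logging.getLogger(__name__)

WEIGHTS = {"variable": 1.0, "bootstrap": 2.0, "rf": 3.0}


def composite_score(v_rel: float, b_rel: float, d_rel: float) -> float:
    """Weighted mean ``(1*v + 2*b + 3*d) / 6`` of three relative metrics."""
    for x in (v_rel, b_rel, d_rel):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"relative value {x} outside [0, 1]")
    return (WEIGHTS["variable"] * v_rel + WEIGHTS["bootstrap"] * b_rel + WEIGHTS["rf"] * d_rel) / 6.0


@dataclass
class MarkerReport:
    """One survey row: summary statistics plus tree metrics, score and rank."""

    summary: AlignmentSummary
    bootstrap_mean: float | None
    rf_to_reference: int | None
    score: float | None = None
    rank: int | None = None
    reason: str | None = None  # why the marker is unranked, if it is

    def as_row(self) -> dict:
        s = self.summary
        return {
            "marker": s.name,
            "mclass": s.mclass,
            "n_taxa": s.n_taxa,
            "bases_mean": s.mean_seq_length,
            "bases_min": s.min_seq_length,
            "bases_max": s.max_seq_length,
            "aligned_bp": s.aligned_length,
            "variable_n": s.n_variable,
            "variable_pct": s.pct_variable,
            "pis_n": s.n_pis,
            "pis_pct": s.pct_pis,
            "k80_mean": s.mean_k80,
            "rf_to_reference": self.rf_to_reference,
            "bootstrap_mean": self.bootstrap_mean,
            "score": self.score,
            "rank": self.rank,
            "reason": self.reason,
        }


def rank_markers(
    reports: list[MarkerReport],
    column_max: dict[str, float] | None = None,
    normalization: str = "max",
) -> list[MarkerReport]:
    """Score and rank survey rows in place; returns them sorted.

    Relative values divide each metric by its column maximum (RF inverted:
    closer to the reference tree is better).  ``column_max`` may supply
    survey-wide maxima explicitly — useful when scoring a subset of a
    larger survey whose ranges are known.  ``normalization="minmax"``
    rescales by column range instead.  Markers without tree metrics are
    left unranked at the bottom with their reason.  A survey with no
    variation anywhere raises :class:`DegenerateSurveyError`.
    """
    if len(reports) < 2:
        raise ValueError("ranking needs >= 2 markers")
    rankable = [r for r in reports if r.bootstrap_mean is not None and r.rf_to_reference is not None]
    if not rankable:
        raise DegenerateSurveyError("no marker produced a tree")

    cols = {
        "variable": np.array([float(r.summary.n_variable) for r in rankable]),
        "bootstrap": np.array([float(r.bootstrap_mean) for r in rankable]),
        "rf": np.array([float(r.rf_to_reference) for r in rankable]),
    }
    cmax = {k: (column_max or {}).get(k, cols[k].max()) for k in cols}
    cmin = {k: cols[k].min() for k in cols}
    if cmax["variable"] <= 0:
        raise DegenerateSurveyError("no variable sites in any marker")

    def rel(kind: str, value: float) -> float:
        # a degenerate column (max 0 / zero span) carries no signal; its
        # relative value is 0, which for RF means "no disagreement anywhere"
        if normalization == "max":
            rel_v = value / cmax[kind] if cmax[kind] > 0 else 0.0
        elif normalization == "minmax":
            span = cmax[kind] - cmin[kind]
            rel_v = (value - cmin[kind]) / span if span > 0 else 0.0
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        return min(max(rel_v, 0.0), 1.0)

    for r in rankable:
        r.score = composite_score(
            rel("variable", r.summary.n_variable),
            rel("bootstrap", r.bootstrap_mean),
            1.0 - rel("rf", r.rf_to_reference),
        )
    rankable.sort(key=lambda r: (-r.score, r.summary.name))
    for pos, r in enumerate(rankable, start=1):
        r.rank = pos
    unranked = sorted(
        (r for r in reports if r not in rankable), key=lambda r: r.summary.name
    )
    return rankable + unranked


def reports_to_frame(reports: list[MarkerReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in reports])


def survey_alignments(
    alignments: dict[str, MarkerAlignment],
    reference: PhyloTree,
    replicates: int = 100,
    seed: int = 0,
    column_max: dict[str, float] | None = None,
    normalization: str = "max",
) -> pd.DataFrame:
    """Rank per-marker alignments against a reference tree.

    Runs summary statistics, NJ + bootstrap and RF-to-reference for every
    marker, then the composite ranking.  Markers whose tree cannot be
    built are reported unranked with a reason code.
    """
    reports: list[MarkerReport] = []
    for name in sorted(alignments):
        aln = alignments[name]
        summary = summarize_alignment(aln)
        try:
            tree = bootstrap_support(aln, replicates=replicates, seed=seed)
            ref = pruned(reference, set(aln.labels)) if set(aln.labels) < reference.taxa else reference
            reports.append(
                MarkerReport(summary, mean_support(tree), rf_distance(tree, ref))
            )
        except (TreeError, SaturationError, TooFewTaxaError) as exc:
            log.warning("marker %s unranked: %s", name, exc)
            reports.append(MarkerReport(summary, None, None, reason=str(exc)))
    return reports_to_frame(rank_markers(reports, column_max, normalization))


def survey(
    genomes: list[CircularGenome],
    reference: PhyloTree | None = None,
    min_len: int = 400,
    max_len: int = 1_600,
    min_taxa: int = 4,
    replicates: int = 100,
    seed: int = 0,
    min_ir: int = 10_000,
) -> pd.DataFrame:
    """End-to-end marker survey over a cohort of annotated plastomes.

    Extracts introns and PCR-sized spacers, collates them across taxa,
    computes per-marker statistics and bootstrap NJ trees, measures each
    tree's RF distance to ``reference`` (by default the tree inferred from
    the cohort's own "full" concatenated scheme) and ranks the markers by
    the composite score.  Needs at least four genomes.
    """
    from .markers import survey_markers
    from .pipeline import marker_sets_to_alignments, build_scheme_set

    if len(genomes) < 4:
        raise TooFewTaxaError("survey needs >= 4 genomes")
    sets = survey_markers(genomes, min_len=min_len, max_len=max_len, min_taxa=min_taxa)
    alignments = marker_sets_to_alignments(sets)
    if reference is None:
        from .trees import nj_from_alignment

        schemes = build_scheme_set(genomes, min_ir=min_ir)
        reference = nj_from_alignment(schemes.schemes["full"])
    return survey_alignments(alignments, reference, replicates=replicates, seed=seed)
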