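"""Alignment summaries, K80 distances, codon recoding, analysis schemes.

Site counts and distances treat alignment gaps, N and every other IUPAC
ambiguity code as missing data: a column contributes only through its
unambiguous A/C/G/T residues, and pairwise distances use pairwise deletion
(each pair of rows is compared over the columns where both are unambiguous).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .errors import AlignmentError, FrameError, SaturationError
from .model import MarkerAlignment

log = logging.getLogger(__name__)

_BASES = (b"A", b"C", b"G", b"T")


def _base_indicator(mat: np.ndarray) -> np.ndarray:
    """(4, n_taxa, width) boolean stack: is the residue A/C/G/T."""
    return np.stack([mat == b for b in _BASES])


# ---------------------------------------------------------------------------
# Site counts
# ---------------------------------------------------------------------------


def count_variable_sites(aln: MarkerAlignment) -> int:
    """Columns with at least two distinct unambiguous bases."""
    if aln.n_taxa < 2:
        raise AlignmentError("variable-site count needs >= 2 rows")
    ind = _base_indicator(aln.matrix())
    present = ind.any(axis=1)  # (4, width): base occurs in the column
    return int((present.sum(axis=0) >= 2).sum())


def count_parsimony_informative(aln: MarkerAlignment) -> int:
    """Columns with >= 2 unambiguous bases each carried by >= 2 taxa."""
    if aln.n_taxa < 4:
        raise AlignmentError("PIS count needs >= 4 rows")
    ind = _base_indicator(aln.matrix())
    counts = ind.sum(axis=1)  # (4, width): taxa carrying each base
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


# ---------------------------------------------------------------------------
# K80 distance
# ---------------------------------------------------------------------------

_PURINE = {b"A", b"G"}


def _k80_from_counts(m: int, ti: int, tv: int) -> float:
    if m == 0:
        raise AlignmentError("no comparable columns between the two sequences")
    P, Q = ti / m, tv / m
    a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        raise SaturationError(f"K80 undefined for P={P:.4f}, Q={Q:.4f}")
    return -0.5 * float(np.log(a1 * np.sqrt(a2)))


def k80_distance(x: str, y: str) -> float:
    """Kimura two-parameter distance between two equal-length rows.

    ``d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q))`` with P and Q the transition
    and transversion proportions over pairwise-deleted columns.  Raises
    :class:`SaturationError` when the correction diverges.
    """
    if len(x) != len(y):
        raise AlignmentError("sequences differ in length")
    xa = np.frombuffer(x.upper().encode(), dtype="S1")
    ya = np.frombuffer(y.upper().encode(), dtype="S1")
    okx = np.isin(xa, _BASES)
    oky = np.isin(ya, _BASES)
    both = okx & oky
    xa, ya = xa[both], ya[both]
    diff = xa != ya
    purx = (xa == b"A") | (xa == b"G")
    pury = (ya == b"A") | (ya == b"G")
    ti = int((diff & (purx == pury)).sum())  # A<->G or C<->T
    tv = int((diff & (purx != pury)).sum())
    return _k80_from_counts(int(both.sum()), ti, tv)


def k80_matrix(aln: MarkerAlignment) -> tuple[list[str], np.ndarray]:
    """All-pairs K80 distances; saturated/undefined pairs become NaN."""
    n = aln.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = k80_distance(aln.rows[i], aln.rows[j])
            except (SaturationError, AlignmentError) as exc:
                log.warning("%s: pair (%s, %s) dropped: %s", aln.name, aln.labels[i], aln.labels[j], exc)
                d[i, j] = d[j, i] = np.nan
    return list(aln.labels), d


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentSummary:
    """One marker's worth of survey statistics."""

    name: str
    mclass: str
    n_taxa: int
    aligned_length: int
    mean_seq_length: float
    min_seq_length: int
    max_seq_length: int
    n_variable: int
    pct_variable: float
    n_pis: int
    pct_pis: float
    mean_k80: float

    def __post_init__(self) -> None:
        assert self.n_pis <= self.n_variable <= self.aligned_length


def summarize_alignment(aln: MarkerAlignment) -> AlignmentSummary:
    """All Table-style summary fields for one marker alignment.

    ``mean_k80`` averages every defined pair; saturated pairs are excluded
    (with a logged warning from :func:`k80_matrix`).
    """
    if aln.n_taxa < 4:
        raise AlignmentError(f"{aln.name}: summary needs >= 4 rows")
    ungapped = [len(r) - r.count("-") for r in aln.rows]
    n_var = count_variable_sites(aln)
    n_pis = count_parsimony_informative(aln)
    _, d = k80_matrix(aln)
    upper = d[np.triu_indices(aln.n_taxa, k=1)]
    defined = upper[~np.isnan(upper)]
    width = aln.width
    return AlignmentSummary(
        name=aln.name,
        mclass=aln.mclass,
        n_taxa=aln.n_taxa,
        aligned_length=width,
        mean_seq_length=float(np.mean(ungapped)),
        min_seq_length=int(min(ungapped)),
        max_seq_length=int(max(ungapped)),
        n_variable=n_var,
        pct_variable=n_var / width if width else 0.0,
        n_pis=n_pis,
        pct_pis=n_pis / width if width else 0.0,
        mean_k80=float(np.mean(defined)) if defined.size else 0.0,
    )


# ---------------------------------------------------------------------------
# Codon recoding and translation (plastid code, translation table 11)
# ---------------------------------------------------------------------------

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_AA = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    _AA[_stop] = "*"

# family-wise degenerate codons: one IUPAC codon per synonymous family
_DEGENERATE = {}
for _codon, _aa in _AA.items():
    if _aa == "L":
        _DEGENERATE[_codon] = "YTN"
    elif _aa == "R":
        _DEGENERATE[_codon] = "MGN"
    elif _aa == "S":
        _DEGENERATE[_codon] = "AGY" if _codon.startswith("AG") else "TCN"


def _check_frame(aln: MarkerAlignment) -> None:
    if aln.width % 3:
        raise FrameError(f"{aln.name}: length {aln.width} not divisible by 3")


def ambiguate_rls_codons(aln: MarkerAlignment) -> MarkerAlignment:
    """Degenerate-recode every Leu, Arg and Ser codon (frame = column 0).

    Leucine codons become YTN, arginine MGN, serine TCN or AGY depending on
    family — the IUPAC codon covering the whole synonymous family, which
    removes synonymous signal from these six-fold amino acids while keeping
    the alignment length.  Codons containing gaps or ambiguity are left
    unchanged, which makes the operation idempotent.
    """
    _check_frame(aln)
    rows = []
    for row in aln.rows:
        codons = [row[i : i + 3] for i in range(0, len(row), 3)]
        rows.append("".join(_DEGENERATE.get(c, c) for c in codons))
    return MarkerAlignment(aln.name, list(aln.labels), rows, aln.mclass)


def translate_cds(aln: MarkerAlignment) -> MarkerAlignment:
    """Translate a codon alignment under the bacterial/plastid code.

    Pure-gap codons become ``-``; codons containing N, ambiguity or a
    partial gap become ``X``.  A terminal stop column is dropped; internal
    stops are replaced by ``X`` with a warning.
    """
    _check_frame(aln)
    prot_rows = []
    for row in aln.rows:
        aas = []
        for i in range(0, len(row), 3):
            codon = row[i : i + 3]
            if codon == "---":
                aas.append("-")
            elif set(codon) <= set("ACGT"):
                aas.append(_AA[codon])
            else:
                aas.append("X")
        prot_rows.append("".join(aas))
    if prot_rows and any(r.endswith("*") for r in prot_rows):
        prot_rows = [r[:-1] for r in prot_rows]
    n_internal = sum(r.count("*") for r in prot_rows)
    if n_internal:
        log.warning("%s: %d internal stop codon(s) replaced by X", aln.name, n_internal)
    fixed = [r.replace("*", "X") for r in prot_rows]
    return MarkerAlignment(aln.name, list(aln.labels), fixed, "protein")


# ---------------------------------------------------------------------------
# Poorly-aligned-site mask
# ---------------------------------------------------------------------------


def mask_poorly_aligned(
    aln: MarkerAlignment, window: int = 5, max_gap_frac: float = 0.5
) -> MarkerAlignment:
    """Drop columns inside any gappy sliding window (deterministic filter).

    Column badness is the fraction of rows that are gap or ambiguity; every
    window of ``window`` consecutive columns whose mean badness exceeds
    ``max_gap_frac`` has all its columns removed.  A crude but reproducible
    stand-in for interactive alignment-masking tools.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    mat = aln.matrix()
    bad = (~np.isin(mat, _BASES)).mean(axis=0)
    if aln.width < window:
        keep = np.ones(aln.width, dtype=bool)
        if bad.mean() > max_gap_frac:
            keep[:] = False
        return aln.subset_columns(keep)
    win_means = np.convolve(bad, np.ones(window) / window, mode="valid")
    drop = np.zeros(aln.width, dtype=bool)
    for start in np.nonzero(win_means > max_gap_frac)[0]:
        drop[start : start + window] = True
    return aln.subset_columns(~drop)


# ---------------------------------------------------------------------------
# Concatenation and the six analysis schemes
# ---------------------------------------------------------------------------

SCHEME_NAMES = ("ncs", "ncs_filtered", "cds", "cds_ambiguated", "protein", "full")


@dataclass
class SchemeSet:
    """Six concatenated datasets plus per-scheme partition maps."""

    schemes: dict[str, MarkerAlignment]
    partitions: dict[str, list[tuple[str, int, int]]]  # marker -> [start, end)


def concatenate(
    per_marker: dict[str, MarkerAlignment], name: str, taxa: list[str] | None = None
) -> tuple[MarkerAlignment, list[tuple[str, int, int]]]:
    """Concatenate marker alignments over the union of taxa, gap-filling.

    Markers are laid out in sorted-name order; a taxon missing from a
    marker contributes gaps for that block (logged).  Returns the combined
    alignment and the partition map ``[(marker, start, end), ...]``.
    """
    if not per_marker:
        raise AlignmentError("nothing to concatenate")
    if taxa is None:
        taxa = sorted({t for a in per_marker.values() for t in a.labels})
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    parts: list[tuple[str, int, int]] = []
    offset = 0
    for mname in sorted(per_marker):
        aln = per_marker[mname]
        for t in taxa:
            if t in aln.labels:
                chunks[t].append(aln.row(t))
            else:
                log.info("%s: taxon %s missing from %s; gap-filled", name, t, mname)
                chunks[t].append("-" * aln.width)
        parts.append((mname, offset, offset + aln.width))
        offset += aln.width
    rows = ["".join(chunks[t]) for t in taxa]
    return MarkerAlignment(name, taxa, rows, "concat"), parts


def build_schemes(
    ncs_markers: dict[str, MarkerAlignment],
    cds_markers: dict[str, MarkerAlignment],
    window: int = 5,
    max_gap_frac: float = 0.5,
) -> SchemeSet:
    """Assemble the six analysis schemes from per-marker alignments.

    1. ``ncs``            all non-coding markers, concatenated
    2. ``ncs_filtered``   the same after the gap-window mask
    3. ``cds``            all coding genes, concatenated in frame
    4. ``cds_ambiguated`` scheme 3 with Leu/Arg/Ser codons degenerate-recoded
    5. ``protein``        scheme 3 translated (plastid code)
    6. ``full``           scheme 2 + scheme 3

    Inputs are expected to come from genomes with one IR copy already
    removed (see :func:`plastsurvey.simulate.remove_ir_copy`), so IR loci
    are not over-represented.
    """
    taxa = sorted(
        {t for a in ncs_markers.values() for t in a.labels}
        | {t for a in cds_markers.values() for t in a.labels}
    )
    schemes: dict[str, MarkerAlignment] = {}
    partitions: dict[str, list[tuple[str, int, int]]] = {}

    schemes["ncs"], partitions["ncs"] = concatenate(ncs_markers, "ncs", taxa)
    filtered = {
        name: mask_poorly_aligned(aln, window, max_gap_frac) for name, aln in ncs_markers.items()
    }
    schemes["ncs_filtered"], partitions["ncs_filtered"] = concatenate(filtered, "ncs_filtered", taxa)
    schemes["cds"], partitions["cds"] = concatenate(cds_markers, "cds", taxa)
    ambiguated = {name: ambiguate_rls_codons(aln) for name, aln in cds_markers.items()}
    schemes["cds_ambiguated"], partitions["cds_ambiguated"] = concatenate(
        ambiguated, "cds_ambiguated", taxa
    )
    proteins = {name: translate_cds(aln) for name, aln in cds_markers.items()}
    schemes["protein"], partitions["protein"] = concatenate(proteins, "protein", taxa)

    full_rows = [
        schemes["ncs_filtered"].row(t) + schemes["cds"].row(t) for t in taxa
    ]
    schemes["full"] = MarkerAlignment("full", taxa, full_rows, "concat")
    shift = schemes["ncs_filtered"].width
    partitions["full"] = partitions["ncs_filtered"] + [
        (m, s + shift, e + shift) for m, s, e in partitions["cds"]
    ]
    return SchemeSet(schemes, partitions)


def write_partition_file(parts: list[tuple[str, int, int]], path) -> None:
    """RAxML-style partition text: ``DNA, name = start-end`` (1-based)."""
    from pathlib import Path

    lines = [f"DNA, {m} = {s + 1}-{e}" for m, s, e in parts]
    Path(path).write_text("\n".join(lines) + "\n")
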