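"""Marker extraction: introns, intergenic spacers, cross-taxon collation.

A "marker" here is a plastid locus short enough to amplify and sequence on
its own — an intron, an intergenic spacer, or a protein-coding gene — that
can be compared across the genomes of a survey.  Extraction works purely
from the annotation: introns are the gaps between consecutive exon parts of
a spliced gene; spacers are the inter-feature stretches between adjacent
genes on the circle, named ``<left>-<right> spacer`` in genome order.
"""

from __future__ import annotations

import logging
from collections import Counter

import numpy as np

from .errors import ExtractionError, TooFewTaxaError
from .model import CircularGenome, Feature, MarkerDefinition, revcomp

log = logging.getLogger(__name__)


def _gene_level_features(genome: CircularGenome) -> list[Feature]:
    """One feature per locus: gene features, plus CDS/tRNA/rRNA without one."""
    named = {f.name for f in genome.features if f.ftype == "gene"}
    out = [f for f in genome.features if f.ftype == "gene"]
    out += [f for f in genome.features if f.ftype in ("CDS", "tRNA", "rRNA") and f.name not in named]
    return out


def _disambiguate(feats: list[Feature]) -> dict[int, str]:
    """Unique display name per feature; IR duplicates get /1, /2 suffixes."""
    counts = Counter(f.name for f in feats)
    running: Counter[str] = Counter()
    names = {}
    for k, f in enumerate(feats):
        if counts[f.name] > 1:
            running[f.name] += 1
            names[k] = f"{f.name}/{running[f.name]}"
        else:
            names[k] = f.name
    return names


def extract_introns(genome: CircularGenome) -> list[tuple[MarkerDefinition, str]]:
    """Intron sequences from every spliced gene, strand-normalized.

    One intron per gap between consecutive exon parts, named
    ``<gene> intron`` (or ``<gene> intron 1/2`` for two-intron genes such as
    clpP and ycf3).  Trans-spliced genes whose parts sit on opposite strands
    (plastid rps12) are skipped for the discontiguous interval with a
    warning: the "intron" between trans-spliced exons is not a locus.

    Raises :class:`ExtractionError` if a gene's exon parts overlap.
    """
    n = genome.length
    out: list[tuple[MarkerDefinition, str]] = []
    for feat in genome.features:
        if feat.ftype not in ("gene", "CDS", "tRNA", "rRNA") or len(feat.parts) < 2:
            continue
        if feat.ftype != "gene" and any(
            g.ftype == "gene" and g.name == feat.name for g in genome.features
        ):
            continue  # the gene feature carries the exon structure already
        parts = sorted(feat.parts, key=lambda p: p[0])
        for (s1, e1, st1), (s2, e2, st2) in zip(parts, parts[1:]):
            if s2 < e1:
                raise ExtractionError(f"{genome.id}: gene {feat.name!r} has overlapping parts")
        gaps = []
        for idx, ((s1, e1, st1), (s2, e2, st2)) in enumerate(zip(parts, parts[1:])):
            if st1 != st2:
                log.warning(
                    "%s: %s parts on opposite strands (trans-spliced); intron %d skipped",
                    genome.id, feat.name, idx + 1,
                )
                continue
            gaps.append((e1, s2))
        for idx, (gs, ge) in enumerate(gaps):
            # number introns in transcript order: on the minus strand the
            # first transcribed intron is the last one in genome coordinates
            t_idx = idx + 1 if feat.strand == 1 else len(gaps) - idx
            name = f"{feat.name} intron" if len(gaps) == 1 else f"{feat.name} intron {t_idx}"
            seq = genome.fetch(gs, ge)
            if feat.strand == -1:
                seq = revcomp(seq)
            out.append((MarkerDefinition(name, "intron", (feat.name,)), seq))
    return out


def extract_spacers(
    genome: CircularGenome, min_len: int = 1, max_len: int | None = None
) -> list[tuple[MarkerDefinition, str]]:
    """Intergenic spacers between adjacent features on the circle.

    Features are taken at gene level (IR duplicates distinguished by /1, /2)
    and sorted by start; each gap between the end of one and the start of
    the next is a spacer named ``<left>-<right> spacer``.  Zero-length gaps
    (abutting or overlapping genes) are omitted.  ``min_len``/``max_len``
    filter *this genome's* spacer lengths; the PCR-size filter over the
    cohort mean is applied at survey level (:func:`survey_markers`).
    """
    feats = _gene_level_features(genome)
    if not feats:
        return []
    names = _disambiguate(feats)
    order = sorted(range(len(feats)), key=lambda k: (feats[k].start, feats[k].end))
    n = genome.length
    out: list[tuple[MarkerDefinition, str]] = []
    for a, b in zip(order, order[1:] + order[:1]):
        left, right = feats[a], feats[b]
        gs, ge = left.end % n, right.start % n
        gap = (ge - gs) % n
        if gap == 0 or gap > n // 2:
            continue  # abutting genes, or an overlap wrapped around the circle
        if gap < min_len or (max_len is not None and gap > max_len):
            continue
        name = f"{names[a]}-{names[b]} spacer"
        out.append(
            (MarkerDefinition(name, "spacer", (left.name, right.name)), genome.fetch(gs, gs + gap))
        )
    return out


def extract_cds(genome: CircularGenome) -> list[tuple[MarkerDefinition, str]]:
    """Spliced, strand-normalized coding sequences (one per CDS feature)."""
    feats = genome.features_of_type("CDS")
    names = _disambiguate(feats)
    return [
        (MarkerDefinition(names[k], "cds", (f.name,)), genome.extract(f))
        for k, f in enumerate(feats)
    ]


def extract_markers(genome: CircularGenome) -> dict[str, tuple[MarkerDefinition, str]]:
    """All introns and spacers of one genome, keyed by marker name."""
    out = {}
    for mdef, seq in extract_introns(genome) + extract_spacers(genome):
        out[mdef.name] = (mdef, seq)
    return out


def _reversed_spacer_name(name: str) -> str | None:
    """``A-B spacer`` -> ``B-A spacer`` (the same locus seen flipped)."""
    if not name.endswith(" spacer"):
        return None
    stem = name[: -len(" spacer")]
    left, sep, right = stem.partition("-")
    if not sep:
        return None
    return f"{right}-{left} spacer"


def _merge_marker(
    store: dict[str, dict[str, str]],
    name: str,
    mclass: str,
    taxon: str,
    seq: str,
    own_names: set[str],
) -> str:
    """Register one extracted marker, canonicalising spacer orientation.

    A genome whose single-copy region is flipped relative to the rest of
    the cohort yields the same spacer reverse-complemented and with the
    flank names swapped; such sequences are folded onto the first-seen
    orientation so every taxon's row is comparable.  Folding only applies
    when the contributing genome does not itself carry the direct-name
    marker (a two-gene circle genuinely has both ``A-B`` and ``B-A``
    spacers as distinct loci).
    """
    if mclass == "spacer" and name not in store:
        rev = _reversed_spacer_name(name)
        if rev is not None and rev in store and rev not in own_names:
            store[rev][taxon] = revcomp(seq)
            return rev
    store.setdefault(name, {})[taxon] = seq
    return name


def collate_marker(
    genomes: list[CircularGenome], marker: MarkerDefinition, min_taxa: int = 4
) -> tuple[dict[str, str], list[str]]:
    """Per-taxon sequences of one marker; returns (present, missing labels).

    Sequences come out in a common orientation because extraction is
    strand-normalized to the anchor gene in every genome.  Fewer than
    ``min_taxa`` genomes possessing the marker raises
    :class:`TooFewTaxaError` (no unrooted tree is possible below four).
    """
    rev_name = _reversed_spacer_name(marker.name) if marker.mclass == "spacer" else None
    present: dict[str, str] = {}
    missing: list[str] = []
    for g in genomes:
        extracted = extract_markers(g)
        found = extracted.get(marker.name)
        if found is not None:
            present[g.id] = found[1]
        elif rev_name is not None and rev_name in extracted:
            present[g.id] = revcomp(extracted[rev_name][1])
        else:
            missing.append(g.id)
    if len(present) < min_taxa:
        raise TooFewTaxaError(
            f"marker {marker.name!r} present in {len(present)} genomes (< {min_taxa})"
        )
    return present, missing


def survey_markers(
    genomes: list[CircularGenome], min_len: int = 400, max_len: int = 1_600, min_taxa: int = 4
) -> dict[str, dict[str, str]]:
    """Cross-taxon marker sets for a cohort, PCR-size filtered.

    All introns are kept; spacers are kept when their *cohort mean* length
    lies in ``[min_len, max_len]`` — a proxy for "amplifiable at Sanger
    scale".  Returns ``{marker name: {taxon: sequence}}`` for markers
    present in at least ``min_taxa`` genomes.
    """
    per_marker: dict[str, dict[str, str]] = {}
    classes: dict[str, str] = {}
    for g in genomes:
        extracted = extract_markers(g)
        own = set(extracted)
        for name, (mdef, seq) in extracted.items():
            stored = _merge_marker(per_marker, name, mdef.mclass, g.id, seq, own)
            classes[stored] = mdef.mclass
    kept: dict[str, dict[str, str]] = {}
    for name, seqs in per_marker.items():
        if len(seqs) < min_taxa:
            continue
        if classes[name] == "spacer":
            mean_len = float(np.mean([len(s) for s in seqs.values()]))
            if not (min_len <= mean_len <= max_len):
                continue
        kept[name] = seqs
    return kept
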