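"""Readers and writers: GenBank flat files, FASTA alignments, plain FASTA.

GenBank records use 1-based inclusive coordinates; internally everything is
0-based half-open (the conversion is ``(a, b) -> (a-1, b)``).  Biopython does
the flat-file parsing; this module owns the mapping onto the circular
:class:`~plastsurvey.model.CircularGenome` model, including unwrapping of
origin-spanning ``join`` locations.
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, GenomeParseError
from .model import CircularGenome, Feature, MarkerAlignment

log = logging.getLogger(__name__)

# GenBank feature keys carried through to the model; everything else is
# ignored on read (sources, misc annotations from external annotators).
_READ_TYPES = {
    "gene": "gene",
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "intron": "intron",
    "misc_feature": "other",
}
_WRITE_KEYS = {
    "gene": "gene",
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "intron": "intron",
    "spacer": "misc_feature",
    "other": "misc_feature",
}


def _feature_name(bio_feat, index: int) -> str:
    for key in ("gene", "product", "note", "label"):
        if key in bio_feat.qualifiers:
            return str(bio_feat.qualifiers[key][0])
    return f"{bio_feat.type}_{index}"


def _unwrap_parts(parts: list[tuple[int, int, int]], length: int) -> tuple[tuple[int, int, int], ...]:
    """Merge a ``join(x..length, 1..y)`` split into one origin-spanning part."""
    merged: list[tuple[int, int, int]] = []
    for part in parts:
        if merged:
            ps, pe, pst = merged[-1]
            s, e, st = part
            if pe % length == s % length == 0 and st == pst and pe == length:
                merged[-1] = (ps, pe + (e - s), pst)
                continue
        merged.append(part)
    return tuple(merged)


def read_genbank(path: str | Path) -> CircularGenome:
    """Parse a GenBank flat file into a :class:`CircularGenome`.

    Raises :class:`GenomeParseError` if the record has no sequence or a
    feature lies outside it.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad files
        raise GenomeParseError(f"{path}: {exc}") from exc
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) < 2:
        raise GenomeParseError(f"{path}: record has no sequence (missing ORIGIN block?)")
    n = len(seq)

    features: list[Feature] = []
    for i, bf in enumerate(record.features):
        ftype = _READ_TYPES.get(bf.type)
        if ftype is None:
            continue
        note = " ".join(bf.qualifiers.get("note", []))
        if ftype == "other" and "spacer" in note.lower():
            ftype = "spacer"
        parts: list[tuple[int, int, int]] = []
        locs = bf.location.parts if isinstance(bf.location, CompoundLocation) else [bf.location]
        for loc in locs:
            s, e = int(loc.start), int(loc.end)
            strand = loc.strand if loc.strand in (1, -1) else 1
            parts.append((s, e, strand))
        if bf.location.strand == -1 and isinstance(bf.location, CompoundLocation):
            # Biopython lists complement(join(...)) parts in transcript
            # order; restore ascending genome order for the model.
            parts.sort(key=lambda p: p[0])
        parts = list(_unwrap_parts(parts, n))
        name = _feature_name(bf, i)
        for s, e, _ in parts:
            if e - s > n or not (0 <= s <= n):
                raise GenomeParseError(
                    f"{path}: feature {name!r} interval ({s},{e}) outside sequence of length {n}"
                )
        parts = [(s % n, s % n + (e - s), st) for s, e, st in parts]
        features.append(Feature(name=name, ftype=ftype, parts=tuple(parts), pseudo="pseudo" in bf.qualifiers))
    return CircularGenome(id=record.id or record.name, seq=seq, features=features)


def _to_location(feat: Feature, length: int) -> CompoundLocation | SimpleLocation:
    locs: list[SimpleLocation] = []
    for s, e, strand in feat.parts:
        s %= length
        e = s + (e - s)
        if e <= length:
            locs.append(SimpleLocation(s, e, strand))
        else:  # origin-spanning: render as join across the origin
            locs.append(SimpleLocation(s, length, strand))
            locs.append(SimpleLocation(0, e - length, strand))
    if len(locs) == 1:
        return locs[0]
    if feat.strand == -1:
        locs = list(reversed(locs))
    return CompoundLocation(locs)


def write_genbank(genome: CircularGenome, path: str | Path) -> Path:
    """Write ``genome`` as a circular GenBank flat file (inverse of read)."""
    record = SeqRecord(
        Seq(genome.seq),
        id=genome.id,
        name=genome.id[:16].replace(" ", "_"),
        description=f"{genome.id} plastome, {genome.length} bp",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    for feat in genome.features:
        qualifiers = {"gene": [feat.name]}
        if feat.ftype in ("spacer", "other"):
            qualifiers["note"] = [f"{feat.ftype}: {feat.name}"]
        if feat.pseudo:
            qualifiers["pseudo"] = [""]
        record.features.append(
            SeqFeature(
                _to_location(feat, genome.length),
                type=_WRITE_KEYS[feat.ftype],
                qualifiers=qualifiers,
            )
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write([record], str(path), "genbank")
    return path


def read_fasta_alignment(path: str | Path, name: str | None = None, mclass: str = "other") -> MarkerAlignment:
    """Read an aligned FASTA into a :class:`MarkerAlignment` (ragged -> error)."""
    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not rows:
        raise AlignmentError(f"{path}: no sequences")
    return MarkerAlignment(name or Path(path).stem, labels, rows, mclass)


def write_fasta_alignment(aln: MarkerAlignment, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for label, row in zip(aln.labels, aln.rows):
            fh.write(f">{label}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")
    return path
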