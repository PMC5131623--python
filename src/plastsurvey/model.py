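"""Core domain types: circular annotated genomes, partitions, alignments.

Coordinate convention
---------------------
All internal coordinates are 0-based, half-open ``[start, end)``.  Because
plastomes are circular, a feature may span the origin; such intervals are
stored *unwrapped* with ``end > length`` (so ``end - start`` is always the
true span) and normalized modulo ``length`` when positions are materialised.
Strand ``+1`` refers to the stored sequence; ``-1`` features are
reverse-complemented on extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlignmentError

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn-",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn-",
)

IUPAC = set("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = set("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware, gap-preserving."""
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize_seq(seq: str) -> str:
    """Upper-case ``seq``; replace residues outside the IUPAC set with N."""
    seq = seq.upper()
    bad = set(seq) - IUPAC
    if bad:
        log.warning("replacing %d non-IUPAC residue kinds %s with N", len(bad), sorted(bad))
        seq = seq.translate(str.maketrans({c: "N" for c in bad}))
    return seq


@dataclass(frozen=True)
class Feature:
    """A typed, stranded, possibly multi-part annotation on a circular genome.

    ``parts`` is an ordered list of ``(start, end, strand)`` with 0-based
    half-open intervals; ``end`` may exceed the genome length to encode an
    origin-spanning part.  Spliced genes carry one part per exon.
    """

    name: str
    ftype: str  # gene | CDS | tRNA | rRNA | intron | spacer | other
    parts: tuple[tuple[int, int, int], ...]
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError(f"feature {self.name!r} has no parts")
        for s, e, strand in self.parts:
            if e <= s:
                raise ValueError(f"feature {self.name!r}: degenerate part ({s}, {e})")
            if strand not in (+1, -1):
                raise ValueError(f"feature {self.name!r}: strand must be +-1, got {strand}")

    @property
    def strand(self) -> int:
        return self.parts[0][2]

    @property
    def start(self) -> int:
        return min(s for s, _, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e, _ in self.parts)

    def span(self) -> int:
        return sum(e - s for s, e, _ in self.parts)

    def positions(self, length: int) -> np.ndarray:
        """All genome positions covered, normalized modulo ``length``."""
        idx = [np.arange(s, e) % length for s, e, _ in self.parts]
        return np.concatenate(idx)


@dataclass
class CircularGenome:
    """A circular nucleotide sequence plus its typed features."""

    id: str
    seq: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = sanitize_seq(self.seq)
        if not self.seq:
            raise ValueError("empty genome sequence")
        n = len(self.seq)
        for f in self.features:
            for s, e, _ in f.parts:
                if not (0 <= s < n) or e - s > n:
                    raise ValueError(
                        f"feature {f.name!r} part ({s},{e}) outside genome of length {n}"
                    )

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Circular slice ``[start, end)``; ``end`` may exceed the length."""
        n = self.length
        start %= n
        end = start + (end - start)
        if end <= n:
            return self.seq[start:end]
        return self.seq[start:] + self.fetch(0, end - n)

    def extract(self, feat: Feature) -> str:
        """Feature sequence in transcript orientation (strand-aware).

        Multi-part minus-strand features are read part-by-part in reverse
        order, each part reverse-complemented, matching GenBank
        ``complement(join(...))`` semantics.
        """
        chunks = [self.fetch(s, e) for s, e, _ in feat.parts]
        if feat.strand == -1:
            return "".join(revcomp(c) for c in reversed(chunks))
        return "".join(chunks)

    def rotated(self, offset: int) -> "CircularGenome":
        """Same circle with the origin moved to ``offset`` (testing aid)."""
        n = self.length
        offset %= n
        seq = self.seq[offset:] + self.seq[:offset]
        feats = [
            replace(
                f,
                parts=tuple(
                    ((s - offset) % n, (s - offset) % n + (e - s), st) for s, e, st in f.parts
                ),
            )
            for f in self.features
        ]
        return CircularGenome(self.id, seq, feats)

    def features_of_type(self, *ftypes: str) -> list[Feature]:
        return [f for f in self.features if f.ftype in ftypes]


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC / IRa / SSC / IRb intervals tiling the circle, canonical order.

    Intervals are 0-based half-open and unwrapped (``end > start``; ``end``
    may exceed ``genome_length`` for the region crossing the origin).  The
    canonical orientation places regions in circular order
    LSC -> IRa -> SSC -> IRb with LSC the longer single-copy region.
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    genome_length: int

    @property
    def ir_length(self) -> int:
        return self.ira[1] - self.ira[0]

    def lengths(self) -> dict[str, int]:
        return {
            "lsc": self.lsc[1] - self.lsc[0],
            "ssc": self.ssc[1] - self.ssc[0],
            "ir": self.ir_length,
            "full": self.genome_length,
        }

    def __post_init__(self) -> None:
        L = self.lengths()
        if L["lsc"] + L["ssc"] + 2 * L["ir"] != L["full"]:
            raise ValueError("partition does not tile the circle")
        if (self.irb[1] - self.irb[0]) != self.ir_length:
            raise ValueError("IRa and IRb lengths differ")

    def region_items(self) -> list[tuple[str, tuple[int, int]]]:
        return [("LSC", self.lsc), ("IRa", self.ira), ("SSC", self.ssc), ("IRb", self.irb)]

    def junctions(self) -> list[tuple[str, int]]:
        """The four boundary positions (first base of the downstream region)."""
        n = self.genome_length
        return [
            ("LSC-IRa", self.ira[0] % n),
            ("IRa-SSC", self.ssc[0] % n),
            ("SSC-IRb", self.irb[0] % n),
            ("IRb-LSC", self.lsc[0] % n),
        ]


@dataclass
class MarkerAlignment:
    """A named multiple alignment: equal-length gapped rows, unique labels."""

    name: str
    labels: list[str]
    rows: list[str]
    mclass: str = "other"  # intron | spacer | cds | other

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise AlignmentError(f"{self.name}: {len(self.labels)} labels for {len(self.rows)} rows")
        if len(set(self.labels)) != len(self.labels):
            raise AlignmentError(f"{self.name}: duplicate taxon labels")
        if not self.rows:
            raise AlignmentError(f"{self.name}: empty alignment")
        self.rows = [r.upper() for r in self.rows]
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise AlignmentError(f"{self.name}: ragged rows")

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def matrix(self) -> np.ndarray:
        """(n_taxa, width) array of single-byte residues for vectorized ops."""
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            self.n_taxa, self.width
        )

    def subset_columns(self, keep: np.ndarray) -> "MarkerAlignment":
        mat = self.matrix()[:, keep]
        rows = [b"".join(row).decode() for row in mat]
        return MarkerAlignment(self.name, list(self.labels), rows, self.mclass)

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]


@dataclass(frozen=True)
class MarkerDefinition:
    """Identity of a survey marker: a name, its class, and anchor genes."""

    name: str
    mclass: str  # intron | spacer | cds
    anchors: tuple[str, ...] = ()
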