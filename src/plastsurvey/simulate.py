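"""Synthetic plastomes: known architecture, known tree, known rates.

The generator emulates the statistical structure the survey assumes: a
cohort of circular genomes sharing one gene architecture (genes with
introns, intergenic spacers, an exact inverted-repeat block), whose loci
evolved along a single phylogeny under K80 with locus-specific rate
multipliers.  Every downstream quantity — partition lengths, class
lengths, marker sequences, the generating tree, per-marker rates — is
therefore known exactly, and each pipeline stage can be tested against the
planted truth.

No indels are simulated by default, so a collated marker is already an
alignment and distances/site counts have exact expectations.  An optional
indel mode punches gap blocks into markers purely to exercise gap handling
and the alignment mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CircularGenome, Feature, MarkerAlignment, revcomp
from .trees import PhyloTree, TreeNode

_ALPHA = "AGCT"  # A<->G and C<->T are the transitions (code ^ 1)


# ---------------------------------------------------------------------------
# Tree simulation (Yule process, ultrametric, rescaled to a target depth)
# ---------------------------------------------------------------------------


def simulate_tree(
    n_taxa: int = 16,
    seed: int = 0,
    depth: float = 0.05,
    birth_rate: float = 1.0,
    min_internal_branch: float = 0.002,
) -> PhyloTree:
    """Ultrametric Yule tree with root-to-tip depth in substitutions/site.

    ``depth`` defaults to 0.05 expected substitutions per site root-to-tip,
    which yields pairwise distances up to ~0.1 — the range seen between
    congeneric-to-confamilial plastomes.  Draws are conditioned (by
    rejection) on every internal branch being at least
    ``min_internal_branch`` substitutions/site after rescaling: a pure
    Yule process occasionally produces near-simultaneous speciations whose
    topology no finite alignment can resolve, and the simulated study
    design assumes an identifiable tree.  Set it to 0 to disable.
    Reproducible given ``seed``.
    """
    if n_taxa < 4:
        raise ValueError("need >= 4 taxa")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    labels = [f"taxon{str(i + 1).zfill(width)}" for i in range(n_taxa)]

    for _attempt in range(1000):
        # lineage birth times; each tip lineage later extends to the present
        root = TreeNode()
        tips: list[tuple[TreeNode, float]] = [(TreeNode(), 0.0), (TreeNode(), 0.0)]
        root.children = [t for t, _ in tips]
        internal_spans: list[float] = []
        t_now = 0.0
        while len(tips) < n_taxa:
            k = len(tips)
            t_now += rng.exponential(1.0 / (birth_rate * k))
            idx = rng.integers(k)
            node, born = tips[idx]
            node.length = t_now - born
            internal_spans.append(node.length)
            kids = [(TreeNode(), t_now), (TreeNode(), t_now)]
            node.children = [t for t, _ in kids]
            tips[idx : idx + 1] = kids
        t_end = t_now + rng.exponential(1.0 / (birth_rate * n_taxa))
        scale = depth / t_end
        if internal_spans and min(internal_spans) * scale < min_internal_branch:
            continue  # unresolvable radiation; redraw
        order = rng.permutation(n_taxa)
        for (node, born), lab in zip(tips, (labels[i] for i in order)):
            node.length = t_end - born
            node.name = lab

        def rescale(node: TreeNode) -> None:
            if node.length is not None:
                node.length *= scale
            for c in node.children:
                rescale(c)

        rescale(root)
        return PhyloTree(root)
    raise RuntimeError("could not draw a tree satisfying the branch-length floor")


# ---------------------------------------------------------------------------
# Sequence evolution under K80
# ---------------------------------------------------------------------------


def _k80_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after branch length t."""
    e1 = np.exp(-4.0 * t / (kappa + 2.0))
    e2 = np.exp(-2.0 * t * (kappa + 1.0) / (kappa + 2.0))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_same), float(p_ti), float(p_tv)


def _evolve_branch(parent: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    p_same, p_ti, p_tv = _k80_probs(t, kappa)
    u = rng.random(parent.size)
    child = parent.copy()
    ti = (u >= p_same) & (u < p_same + p_ti)
    child[ti] ^= 1  # transition partner: A<->G, C<->T
    tv1 = (u >= p_same + p_ti) & (u < p_same + p_ti + p_tv)
    tv2 = u >= p_same + p_ti + p_tv
    other = (1 - parent // 2) * 2  # first base of the other purine/pyrimidine pair
    child[tv1] = other[tv1]
    child[tv2] = other[tv2] + 1
    return child


def evolve_marker(
    tree: PhyloTree,
    length: int,
    rate_multiplier: float = 1.0,
    kappa: float = 2.0,
    seed: int = 0,
    name: str = "marker",
    mclass: str = "other",
) -> MarkerAlignment:
    """Evolve one gap-free marker along ``tree`` under K80.

    The root sequence is i.i.d. uniform over A/C/G/T; each branch applies
    the K80 transition kernel with transition/transversion rate ratio
    ``kappa`` and branch length scaled by ``rate_multiplier``.  Columns are
    independent.  Expected pairwise distance between two tips equals the
    rate-scaled path length between them.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    rows: dict[str, np.ndarray] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        if node.length is not None:
            seq = _evolve_branch(seq, node.length * rate_multiplier, kappa, rng)
        if node.is_leaf:
            rows[node.name] = seq
        for child in node.children:
            walk(child, seq)

    walk(tree.root, rng.integers(0, 4, size=length))
    labels = sorted(rows)
    decoded = ["".join(_ALPHA[b] for b in rows[lab]) for lab in labels]
    return MarkerAlignment(name, labels, decoded, mclass)


# ---------------------------------------------------------------------------
# Genome architecture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchUnit:
    """One architectural unit: a (possibly spliced) gene or a spacer."""

    name: str
    ftype: str  # CDS | tRNA | rRNA | spacer
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...] = ()
    strand: int = 1

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != max(0, len(self.exon_lengths) - 1):
            raise ValueError(f"{self.name}: need one intron length per exon gap")
        if any(x <= 0 for x in self.exon_lengths + self.intron_lengths):
            raise ValueError(f"{self.name}: lengths must be positive")

    @property
    def total_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


@dataclass(frozen=True)
class Architecture:
    """Ordered units of the three unique regions; IRb is IRa mirrored."""

    lsc: tuple[ArchUnit, ...]
    ir: tuple[ArchUnit, ...]
    ssc: tuple[ArchUnit, ...]

    @property
    def ir_length(self) -> int:
        return sum(u.total_length for u in self.ir)

    @property
    def genome_length(self) -> int:
        sc = sum(u.total_length for u in self.lsc) + sum(u.total_length for u in self.ssc)
        return sc + 2 * self.ir_length

    def region_lengths(self) -> dict[str, int]:
        return {
            "lsc": sum(u.total_length for u in self.lsc),
            "ssc": sum(u.total_length for u in self.ssc),
            "ir": self.ir_length,
            "full": self.genome_length,
        }

    def gene_counts(self) -> dict[str, int]:
        """Genes per class, IR duplicates counted twice."""
        counts = {"protein_coding": 0, "tRNA": 0, "rRNA": 0}
        key = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}
        for region, mult in ((self.lsc, 1), (self.ir, 2), (self.ssc, 1)):
            for u in region:
                if u.ftype in key:
                    counts[key[u.ftype]] += mult
        return counts


def _pad(idx: int, length: int) -> ArchUnit:
    return ArchUnit(f"pad_{idx}", "spacer", (length,))


def default_architecture() -> Architecture:
    """Toy but structurally faithful plastome: ~60 kb, ~8 kb IR.

    About thirty genes (CDS, tRNA, rRNA), six spliced genes including a
    two-intron clpP analogue and an intron-bearing tRNA, and ten
    PCR-sized spacers (named after their flanks, as extraction will name
    them) among smaller anonymous pads.
    """
    lsc = (
        ArchUnit("trnH", "tRNA", (74,)),
        _pad(1, 210),
        ArchUnit("psbA", "CDS", (1062,), strand=-1),
        ArchUnit("psbA-matK spacer", "spacer", (620,)),
        ArchUnit("matK", "CDS", (1530,), strand=-1),
        _pad(2, 260),
        ArchUnit("rps16", "CDS", (240, 816), (870,), strand=-1),
        ArchUnit("rps16-trnQ spacer", "spacer", (700,)),
        ArchUnit("trnQ", "tRNA", (72,), strand=-1),
        _pad(3, 150),
        ArchUnit("psbK", "CDS", (186,)),
        ArchUnit("psbK-psbI spacer", "spacer", (480,)),
        ArchUnit("psbI", "CDS", (111,)),
        _pad(4, 250),
        ArchUnit("atpA", "CDS", (1524,), strand=-1),
        _pad(5, 90),
        ArchUnit("atpF", "CDS", (144, 411), (720,), strand=-1),
        _pad(6, 130),
        ArchUnit("atpH", "CDS", (246,), strand=-1),
        ArchUnit("atpH-atpI spacer", "spacer", (850,)),
        ArchUnit("atpI", "CDS", (744,), strand=-1),
        _pad(7, 180),
        ArchUnit("rpoC1", "CDS", (432, 1611), (756,), strand=-1),
        _pad(8, 100),
        ArchUnit("rpoB", "CDS", (3213,), strand=-1),
        ArchUnit("rpoB-trnC spacer", "spacer", (620,)),
        ArchUnit("trnC", "tRNA", (71,)),
        _pad(9, 140),
        ArchUnit("psbD", "CDS", (1062,)),
        _pad(10, 60),
        ArchUnit("psbC", "CDS", (1386,)),
        ArchUnit("psbC-trnS spacer", "spacer", (560,)),
        ArchUnit("trnS", "tRNA", (87,), strand=-1),
        ArchUnit("trnS-trnG spacer", "spacer", (740,)),
        ArchUnit("trnG", "tRNA", (23, 48), (690,)),
        _pad(11, 160),
        ArchUnit("rbcL", "CDS", (1428,)),
        ArchUnit("rbcL-accD spacer", "spacer", (780,)),
        ArchUnit("accD", "CDS", (1467,)),
        _pad(12, 110),
        ArchUnit("clpP", "CDS", (69, 291, 228), (800, 650), strand=-1),
        _pad(13, 170),
        ArchUnit("psbB", "CDS", (1527,)),
        _pad(14, 95),
        ArchUnit("rpoA", "CDS", (1014,), strand=-1),
        ArchUnit("rpoA-rps19 spacer", "spacer", (505,)),
        ArchUnit("rps19", "CDS", (279,), strand=-1),
        _pad(15, 85),
    )
    ir = (
        ArchUnit("rpl2", "CDS", (831,), strand=-1),
        _pad(16, 200),
        ArchUnit("rrn16", "rRNA", (1491,)),
        _pad(17, 280),
        ArchUnit("trnI", "tRNA", (74,)),
        _pad(18, 120),
        ArchUnit("trnA", "tRNA", (73,)),
        _pad(19, 150),
        ArchUnit("rrn23", "rRNA", (2810,)),
        _pad(20, 101),
        ArchUnit("rrn4.5", "rRNA", (103,)),
        _pad(21, 90),
        ArchUnit("rrn5", "rRNA", (121,)),
        _pad(22, 220),
        ArchUnit("ndhB", "CDS", (1533,), strand=-1),
        _pad(23, 300),
    )
    ssc = (
        ArchUnit("ndhF", "CDS", (2220,), strand=-1),
        ArchUnit("ndhF-rpl32 spacer", "spacer", (880,)),
        ArchUnit("rpl32", "CDS", (174,)),
        _pad(24, 240),
        ArchUnit("ccsA", "CDS", (966,)),
        _pad(25, 190),
        ArchUnit("ndhD", "CDS", (1503,), strand=-1),
        _pad(26, 130),
        ArchUnit("ndhA", "CDS", (540, 552), (1020,), strand=-1),
        _pad(27, 160),
        ArchUnit("ycf1", "CDS", (5400,)),
        _pad(28, 210),
    )
    return Architecture(lsc, ir, ssc)


def random_architecture(rng: np.random.Generator) -> Architecture:
    """Small random architecture for planted-IR property tests (~2-6 kb)."""

    def gene(i: int) -> ArchUnit:
        return ArchUnit(f"g{i}", "CDS", (3 * int(rng.integers(40, 200)),),
                        strand=int(rng.choice([1, -1])))

    units: list[ArchUnit] = []
    for i in range(int(rng.integers(3, 7))):
        units.append(gene(i))
        units.append(ArchUnit(f"s{i}", "spacer", (int(rng.integers(80, 400)),)))
    lsc = tuple(units)
    ir = (
        ArchUnit("rrnX", "rRNA", (int(rng.integers(120, 400)),)),
        ArchUnit("irpad", "spacer", (int(rng.integers(60, 200)),)),
    )
    ssc_len = int(rng.integers(300, 700))
    ssc = (
        ArchUnit("g_ssc", "CDS", (3 * (ssc_len // 3),), strand=int(rng.choice([1, -1]))),
        ArchUnit("s_ssc", "spacer", (int(rng.integers(80, 250)),)),
    )
    arch = Architecture(lsc, ir, ssc)
    L = arch.region_lengths()
    if L["lsc"] <= L["ssc"]:  # keep LSC the longer single-copy region
        lsc = lsc + (ArchUnit("s_extra", "spacer", (L["ssc"] - L["lsc"] + 101,)),)
        arch = Architecture(lsc, ir, ssc)
    return arch


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------


def _marker_names(unit: ArchUnit) -> list[str]:
    """Truth names of the segments a unit contributes: gene + its introns."""
    names = [unit.name]
    n_introns = len(unit.intron_lengths)
    for i in range(n_introns):
        names.append(f"{unit.name} intron" if n_introns == 1 else f"{unit.name} intron {i + 1}")
    return names


@dataclass
class SimulatedCohort:
    """Simulator output: genomes plus every piece of planted truth."""

    genomes: list[CircularGenome]
    tree: PhyloTree
    architecture: Architecture
    truth: pd.DataFrame  # marker, mclass, length, rate_multiplier
    marker_alignments: dict[str, MarkerAlignment] = field(default_factory=dict)


def assemble_genomes(
    tree: PhyloTree,
    architecture: Architecture | None = None,
    rate_multipliers: dict[str, float] | None = None,
    kappa: float = 2.0,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> SimulatedCohort:
    """Evolve every unit along ``tree`` and assemble annotated genomes.

    Each gene (spliced exon set), intron and spacer evolves as an
    independent K80 marker with its own rate multiplier (default 1.0).
    Per taxon, segments are concatenated LSC -> IRa -> SSC, and IRb is the
    exact reverse complement of IRa appended at the end, with mirrored
    annotations — so the planted quadripartite structure is exact.  The
    bases flanking the IR copies are adjusted, if needed, so that no copy
    extends the repeat by chance and the planted IR is also the maximal one.

    ``indel_rate`` > 0 punches aligned gap blocks into non-coding markers
    (geometric lengths) to exercise gap handling; coding markers stay
    gap-free so translations remain in frame.
    """
    arch = architecture or default_architecture()
    mult = dict(rate_multipliers or {})
    rng_master = np.random.default_rng(seed)

    taxa = sorted(tree.taxa)
    units = [("lsc", u) for u in arch.lsc] + [("ir", u) for u in arch.ir] + [
        ("ssc", u) for u in arch.ssc
    ]

    # -- evolve every segment -------------------------------------------
    evolved: dict[str, MarkerAlignment] = {}
    truth_rows = []
    for idx, (_, unit) in enumerate(units):
        names = _marker_names(unit)
        seg_lengths = [sum(unit.exon_lengths)] + list(unit.intron_lengths)
        mclasses = [
            {"CDS": "cds", "tRNA": "trna", "rRNA": "rrna", "spacer": "spacer"}[unit.ftype]
        ] + ["intron"] * len(unit.intron_lengths)
        for sub, (name, length, mclass) in enumerate(zip(names, seg_lengths, mclasses)):
            m = mult.get(name, 1.0)
            aln = evolve_marker(
                tree, length, rate_multiplier=m, kappa=kappa,
                seed=int(rng_master.integers(2**31)), name=name, mclass=mclass,
            )
            if indel_rate > 0 and mclass in ("spacer", "intron"):
                aln = _punch_gaps(aln, indel_rate, np.random.default_rng([seed, 7, idx, sub]))
            evolved[name] = aln
            truth_rows.append(
                {"marker": name, "mclass": mclass, "length": length, "rate_multiplier": m}
            )

    # -- assemble per taxon ---------------------------------------------
    genomes = []
    for taxon in taxa:
        segs: list[tuple[str, str]] = []  # (region, sequence) per unit, genomic orientation
        feats_per_unit: list[list[tuple[str, str, int, list[tuple[int, int]]]]] = []
        for region, unit in units:
            names = _marker_names(unit)
            gene_seq = evolved[names[0]].row(taxon).replace("-", "")
            introns = [evolved[nm].row(taxon).replace("-", "") for nm in names[1:]]
            # interleave exons and introns in transcript order
            exon_seqs, off = [], 0
            for el in unit.exon_lengths:
                exon_seqs.append(gene_seq[off : off + el])
                off += el
            transcript_parts = [exon_seqs[0]]
            for intr, ex in zip(introns, exon_seqs[1:]):
                transcript_parts += [intr, ex]
            t_seq = "".join(transcript_parts)
            # exon intervals within the unit, transcript coordinates
            t_iv, pos = [], 0
            for part, is_exon in zip(transcript_parts, [True] + [v for i in introns for v in (False, True)]):
                if is_exon:
                    t_iv.append((pos, pos + len(part)))
                pos += len(part)
            if unit.strand == -1:
                g_seq = revcomp(t_seq)
                total = len(t_seq)
                g_iv = sorted((total - e, total - s) for s, e in t_iv)
            else:
                g_seq, g_iv = t_seq, t_iv
            segs.append((region, g_seq))
            feats_per_unit.append([(unit.name, unit.ftype, unit.strand, g_iv)])

        lsc_seq = "".join(s for r, s in segs if r == "lsc")
        ira_seq = "".join(s for r, s in segs if r == "ir")
        ssc_seq = "".join(s for r, s in segs if r == "ssc")
        seq = list(lsc_seq + ira_seq + ssc_seq + revcomp(ira_seq))
        n = len(seq)
        a, L, b = len(lsc_seq), len(ira_seq), len(lsc_seq) + len(ira_seq) + len(ssc_seq)
        # guard against chance extension of the repeat beyond the planted IR
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if seq[a - 1] == comp[seq[(b + L) % n]]:
            seq[a - 1] = next(c for c in "ACGT" if c != comp[seq[(b + L) % n]] and c != seq[a - 1])
        if seq[a + L] == comp[seq[b - 1]]:
            seq[b - 1] = next(c for c in "ACGT" if comp[c] != seq[a + L] and c != seq[b - 1])
        seq = "".join(seq)

        # feature coordinates: walk units once for LSC+IRa+SSC, then mirror IRb
        features: list[Feature] = []
        offset = 0
        ir_feats: list[Feature] = []
        for (region, unit), flist, (_, g_seq) in zip(units, feats_per_unit, segs):
            for name, ftype, strand, g_iv in flist:
                if ftype != "spacer":
                    parts = tuple((offset + s, offset + e, strand) for s, e in g_iv)
                    feat = Feature(name=name, ftype=ftype, parts=parts)
                    features.append(feat)
                    if region == "ir":
                        ir_feats.append(feat)
            offset += len(g_seq)
        # IRb occupies [b, b+L): position p of IRa [a, a+L) mirrors to
        # b + (a + L - 1 - p), so an interval [s, e) maps to
        # [b + a + L - e, b + a + L - s) on the opposite strand.
        for feat in ir_feats:
            parts = tuple(
                sorted((b + a + L - e, b + a + L - s, -st) for s, e, st in feat.parts)
            )
            features.append(Feature(name=feat.name, ftype=feat.ftype, parts=parts))
        genomes.append(CircularGenome(id=taxon, seq=seq, features=features))

    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(genomes, tree, arch, truth, evolved)


def _punch_gaps(aln: MarkerAlignment, rate: float, rng: np.random.Generator) -> MarkerAlignment:
    """Insert aligned gap blocks (geometric length, mean 8) into rows."""
    rows = []
    for row in aln.rows:
        chars = list(row)
        k = rng.poisson(rate * len(chars))
        for _ in range(k):
            start = int(rng.integers(0, len(chars)))
            glen = int(rng.geometric(1 / 8.0))
            for p in range(start, min(start + glen, len(chars))):
                chars[p] = "-"
        rows.append("".join(chars))
    return MarkerAlignment(aln.name, list(aln.labels), rows, aln.mclass)


def simulate_cohort(
    n_taxa: int = 16,
    seed: int = 0,
    depth: float = 0.05,
    kappa: float = 2.0,
    architecture: Architecture | None = None,
    rate_multipliers: dict[str, float] | None = None,
    indel_rate: float = 0.0,
) -> SimulatedCohort:
    """Convenience wrapper: Yule tree + assembled cohort from one seed."""
    tree = simulate_tree(n_taxa=n_taxa, seed=seed, depth=depth)
    return assemble_genomes(
        tree,
        architecture=architecture,
        rate_multipliers=rate_multipliers,
        kappa=kappa,
        seed=seed + 1,
        indel_rate=indel_rate,
    )
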