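"""Unrooted trees: Newick I/O, neighbor-joining, bootstrap, Robinson-Foulds.

Trees are stored rooted-for-traversal (a trifurcating root for unrooted
semantics) but every comparison operates on unrooted bipartitions: each
internal edge splits the taxa into two sides, canonicalised as the side not
containing the lexicographically smallest taxon.  Robinson-Foulds distance
is the size of the symmetric difference of the two nontrivial bipartition
sets.  The built-in inference engine is neighbor joining over K80 distance
matrices with nonparametric (column-resampling) bootstrap; externally
computed Newick trees can be used anywhere a tree is expected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alnstats import k80_matrix
from .errors import TreeError
from .model import MarkerAlignment

log = logging.getLogger(__name__)


@dataclass
class TreeNode:
    name: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """An unrooted phylogeny with branch lengths and optional edge supports."""

    def __init__(self, root: TreeNode):
        self.root = root
        taxa = [n.name for n in self.leaves()]
        if len(set(taxa)) != len(taxa) or any(t is None for t in taxa):
            raise TreeError("leaf labels must be present and unique")

    # -- traversal ----------------------------------------------------------
    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves())

    # -- bipartitions -------------------------------------------------------
    def _clades(self) -> dict[int, frozenset[str]]:
        clades: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                clades[id(node)] = frozenset([node.name])
            else:
                clades[id(node)] = frozenset().union(*(clades[id(c)] for c in node.children))
        return clades

    def _canonical(self, clade: frozenset[str]) -> frozenset[str]:
        anchor = min(self.taxa)
        return self.taxa - clade if anchor in clade else clade

    def bipartitions(self) -> set[frozenset[str]]:
        """Canonical nontrivial bipartitions (one frozenset per edge)."""
        taxa, clades = self.taxa, self._clades()
        out = set()
        for node in self.postorder():
            if node is self.root:
                continue
            clade = clades[id(node)]
            if 1 < len(clade) < len(taxa) - 1:
                out.add(self._canonical(clade))
        return out

    def internal_edges(self) -> list[tuple[TreeNode, frozenset[str]]]:
        """(node, canonical bipartition) for every internal edge."""
        taxa, clades = self.taxa, self._clades()
        out = []
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            clade = clades[id(node)]
            if 1 < len(clade) < len(taxa) - 1:
                out.append((node, self._canonical(clade)))
        return out

    # -- Newick -------------------------------------------------------------
    def newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(render(c) for c in node.children)
                label = ""
                if node.support is not None:
                    label = format(node.support, ".10g")
                elif node.name:
                    label = node.name
                body = f"({inner}){label}"
            if node.length is not None:
                body += ":" + format(node.length, ".10g")
            return body

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self.taxa)} taxa)"


# ---------------------------------------------------------------------------
# Newick parsing
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (lengths, internal support labels, polytomies)."""
    s = text.strip()
    if not s.endswith(";"):
        raise TreeError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def error(msg: str):
        raise TreeError(f"Newick parse error at char {pos}: {msg}")

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    error("unexpected end inside group")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                error(f"unexpected {s[pos]!r}")
            label = parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            label = parse_label()
            if not label:
                error("empty leaf label")
            node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in "(),:;":
                pos += 1
            try:
                node.length = float(s[start:pos])
            except ValueError:
                error(f"bad branch length {s[start:pos]!r}")
        return node

    root = parse_node()
    if pos != len(s):
        raise TreeError(f"trailing characters after tree: {s[pos:]!r}")
    if root.is_leaf:
        raise TreeError("tree has a single node")
    return PhyloTree(root)


def read_newick(path) -> PhyloTree:
    from pathlib import Path

    return parse_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, path) -> None:
    from pathlib import Path

    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(labels: list[str], d: np.ndarray) -> PhyloTree:
    """Classical neighbor joining; deterministic, negative lengths clamped.

    ``d`` must be a symmetric matrix with zero diagonal over >= 4 taxa and
    no missing entries.  Ties in the Q criterion are broken by the
    lexicographic order of each cluster's smallest taxon label, so the
    result is independent of input order.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if n < 4:
        raise TreeError("neighbor joining needs >= 4 taxa (no internal edge below 4)")
    if d.shape != (n, n):
        raise TreeError("distance matrix shape does not match labels")
    if np.isnan(d).any():
        raise TreeError("distance matrix contains undefined (NaN) entries")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise TreeError("distance matrix must be symmetric with zero diagonal")

    nodes = [TreeNode(name=lab) for lab in labels]
    keys = list(labels)  # smallest taxon label per cluster, for tie-breaks
    D = d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        R = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - R[i] - R[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        li = 0.5 * D[i, j] + (R[i] - R[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        # grow matrix by one row/col for the new cluster
        new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].length = max(0.0, 0.5 * (D[i, j] + D[i, k] - D[j, k]))
    nodes[j].length = max(0.0, 0.5 * (D[i, j] + D[j, k] - D[i, k]))
    nodes[k].length = max(0.0, 0.5 * (D[i, k] + D[j, k] - D[i, j]))
    return PhyloTree(root)


def nj_from_alignment(aln: MarkerAlignment) -> PhyloTree:
    """K80 distance matrix -> NJ tree (the package's built-in engine)."""
    labels, d = k80_matrix(aln)
    if np.isnan(d).any():
        raise TreeError(f"{aln.name}: saturated/undefined pairwise distances")
    return nj_tree(labels, d)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


def bootstrap_support(
    aln: MarkerAlignment, replicates: int = 100, seed: int = 0
) -> PhyloTree:
    """NJ tree with nonparametric bootstrap supports on internal edges.

    Columns are resampled with replacement ``replicates`` times; each
    replicate's K80 + NJ tree votes for the bipartitions it contains, and
    each internal edge of the original-data tree receives the percentage of
    successful replicates containing its bipartition.  Replicates whose
    distance matrix is undefined (saturation) are dropped with a warning.
    Each replicate draws from an independent counter-derived RNG stream, so
    results depend only on ``(seed, replicate index)``.
    """
    if replicates < 10:
        raise ValueError("need >= 10 bootstrap replicates")
    tree = nj_from_alignment(aln)
    counts: dict[frozenset[str], int] = {}
    kept = 0
    for rep in range(replicates):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, aln.width, size=aln.width)
        resampled = aln.subset_columns(cols)
        try:
            rep_tree = nj_from_alignment(resampled)
        except TreeError as exc:
            log.warning("%s: bootstrap replicate %d dropped: %s", aln.name, rep, exc)
            continue
        kept += 1
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    if kept == 0:
        raise TreeError(f"{aln.name}: all bootstrap replicates failed")
    for node, bp in tree.internal_edges():
        node.support = 100.0 * counts.get(bp, 0) / kept
    return tree


def mean_support(tree: PhyloTree) -> float:
    """Arithmetic mean of internal-edge supports."""
    supports = [node.support for node, _ in tree.internal_edges() if node.support is not None]
    if not supports:
        raise TreeError("tree has no supported internal edges")
    return float(np.mean(supports))


# ---------------------------------------------------------------------------
# Robinson-Foulds
# ---------------------------------------------------------------------------


def pruned(tree: PhyloTree, keep: set[str]) -> PhyloTree:
    """Copy of ``tree`` restricted to the taxa in ``keep``.

    Unary internal nodes created by the pruning are collapsed, summing
    branch lengths, so the result is a proper unrooted tree on ``keep``.
    """
    missing = keep - tree.taxa
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")

    def copy(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.name in keep:
                return TreeNode(name=node.name, length=node.length)
            return None
        kids = [c for c in (copy(ch) for ch in node.children) if c is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if child.length is not None or node.length is not None:
                child.length = (child.length or 0.0) + (node.length or 0.0)
            return child
        return TreeNode(name=node.name, length=node.length, support=node.support, children=kids)

    root = copy(tree.root)
    if root is None or root.is_leaf:
        raise TreeError("pruning left fewer than two taxa")
    root.length = None
    return PhyloTree(root)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference count of nontrivial bipartitions (unnormalised).

    0 iff the unrooted topologies agree; at most ``2(n-3)`` for two binary
    trees on ``n`` taxa.  Raises :class:`TreeError` on taxon-set mismatch.
    """
    if t1.taxa != t2.taxa:
        raise TreeError("trees have different taxon sets")
    return len(t1.bipartitions() ^ t2.bipartitions())
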