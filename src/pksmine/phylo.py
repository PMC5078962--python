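"""16S identity, distance matrices, neighbor-joining and bootstrap supports.

The tree-building procedure mirrors the classical 16S workflow: align,
eliminate every column containing a gap in any sequence (complete
deletion), compute pairwise distances (p-distance or Jukes-Cantor,
JC being the default), build a Saitou-Nei neighbor-joining tree, and attach
bootstrap supports from column-resampled replicates, suppressing values at
or below 50% in rendered output.  The outgroup is used only for display
rooting; all computation is on the unrooted tree.

NJ is implemented here rather than delegated because the package fixes its
determinism contract: ties in the Q-criterion are broken by the lowest
index pair, and a negative branch length is clamped to zero with its length
moved to the sibling edge, so a given matrix always yields the same tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# pairwise identity (16S similarity reporting)

def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    # free end gaps (glocal): near-identical rRNA sequences of unequal trim
    aligner.end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def pairwise_identity(a: str, b: str) -> tuple[int, int, float]:
    """(matches, compared, percent) identity of two nucleotide sequences.

    Sequences are globally aligned with free end gaps; every column
    containing a gap is excluded from the comparison, matching the
    ``100 %, 1456/1456`` reporting convention for 16S genes.
    """
    if not a or not b:
        raise PhyloError("empty sequence")
    aln = next(iter(_nt_aligner().align(a.upper(), b.upper())))
    blocks_a, blocks_b = aln.aligned
    matches = compared = 0
    for (as_, ae), (bs, _be) in zip(blocks_a, blocks_b):
        for i in range(ae - as_):
            compared += 1
            if a[as_ + i].upper() == b[bs + i].upper():
                matches += 1
    pct = 100.0 * matches / compared if compared else 0.0
    return matches, compared, pct


# ---------------------------------------------------------------------------
# alignment container and distances

@dataclass
class MsaLite:
    """A positional alignment: taxa labels and equal-length rows."""

    taxa: list[str]
    rows: list[str]
    kept_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise PhyloError("taxa/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise PhyloError(f"rows of unequal length: {sorted(lengths)}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_array(self) -> np.ndarray:
        return np.array([list(r.upper()) for r in self.rows], dtype="U1")


def gap_eliminate(msa: MsaLite) -> MsaLite:
    """Complete deletion: drop every column gapped in any row."""
    arr = msa.to_array()
    gapped = (arr == "-") | (arr == ".")
    kept = np.where(~gapped.any(axis=0))[0]
    if kept.size == 0:
        raise PhyloError("gap elimination removed every column")
    sub = arr[:, kept]
    return MsaLite(
        taxa=list(msa.taxa),
        rows=["".join(row) for row in sub],
        kept_columns=[int(i) for i in kept],
    )


def distance(msa: MsaLite, model: str = "jukes_cantor") -> np.ndarray:
    """Pairwise distance matrix (substitutions/site) of a gapless MSA.

    ``p_distance`` is the mismatch fraction; ``jukes_cantor`` applies
    d = -(3/4) ln(1 - 4p/3), undefined (error) at p >= 0.75.
    """
    arr = msa.to_array()
    n = len(msa.taxa)
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p = float(np.mean(arr[i] != arr[j]))
        if model == "p_distance":
            d = p
        elif model == "jukes_cantor":
            if p >= 0.75:
                raise PhyloError(f"JC distance undefined at p={p:.3f} >= 0.75")
            d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
        else:
            raise PhyloError(f"unknown model {model!r}")
        dist[i, j] = dist[j, i] = d
    return dist


# ---------------------------------------------------------------------------
# trees

@dataclass
class Node:
    label: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True, support_min: float = 50.0) -> str:
        return self._nwk(with_support, support_min) + ";"

    def _nwk(self, ws: bool, smin: float) -> str:
        if self.is_leaf():
            return f"{self.label}:{self.length:.6f}"
        inner = ",".join(c._nwk(ws, smin) for c in self.children)
        lab = ""
        if ws and self.support is not None and self.support > smin:
            lab = f"{self.support:.0f}"
        return f"({inner}){lab}:{self.length:.6f}"


def nj_tree(dist: np.ndarray, taxa: Sequence[str]) -> Node:
    """Saitou-Nei neighbor joining; deterministic on its input.

    Q-criterion ties are broken by the lowest (i, j) index pair in the
    current node ordering; a negative branch length is clamped to zero with
    the deficit moved to its sibling edge.  The result is the unrooted tree
    represented with a trifurcating root.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(taxa)
    if n < 3:
        raise PhyloError("need at least 3 taxa")
    if dist.shape != (n, n):
        raise PhyloError("distance matrix shape mismatch")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise PhyloError("distance matrix is not symmetric")
    if np.any(np.diag(dist) != 0):
        raise PhyloError("distance matrix diagonal must be zero")

    nodes: list[Node] = [Node(label=t) for t in taxa]
    D = dist.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best: tuple[float, int, int] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = Node(children=[_with_length(nodes[i], li), _with_length(nodes[j], lj)])
        new_d = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = new_d[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    # final join of the last three nodes at a central (trifurcating) node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    l0, l1, l2 = (max(0.0, x) for x in (l0, l1, l2))
    return Node(children=[
        _with_length(nodes[0], l0),
        _with_length(nodes[1], l1),
        _with_length(nodes[2], l2),
    ])


def _with_length(node: Node, length: float) -> Node:
    node.length = max(0.0, float(length))
    return node


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(0.0, li), max(0.0, lj)


def bipartitions(tree: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is encoded as the canonical side not containing the
    lexicographically smallest taxon, so trees over the same taxa compare
    directly.
    """
    all_taxa = frozenset(tree.leaves())
    anchor = min(all_taxa)
    out: set[frozenset[str]] = set()

    def walk(node: Node) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c in node.children))
        if 1 < len(below) < len(all_taxa) - 1:
            side = all_taxa - below if anchor in below else below
            out.add(side)
        return below

    for child in tree.children:
        walk(child)
    return out


def same_topology(a: Node, b: Node) -> bool:
    if set(a.leaves()) != set(b.leaves()):
        return False
    return bipartitions(a) == bipartitions(b)


@dataclass
class PhyloResult:
    """Distance matrix, NJ tree and bootstrap supports for one alignment."""

    taxa: list[str]
    dist: np.ndarray
    tree: Node
    supports: dict[frozenset[str], float]
    model: str
    n_boot: int
    seed: int | None
    outgroup: str | None = None

    def newick(self, support_min: float = 50.0) -> str:
        tree = root_at(self.tree, self.outgroup) if self.outgroup else self.tree
        return tree.newick(with_support=True, support_min=support_min)


def bootstrap_consensus(
    msa: MsaLite,
    n: int = 1000,
    seed: int | None = None,
    model: str = "jukes_cantor",
) -> tuple[dict[frozenset[str], float], Node]:
    """Bootstrap supports for the full-data NJ tree.

    Columns are resampled with replacement ``n`` times; each replicate is
    re-distanced and re-joined, and bipartition frequencies (percent) are
    attached to the matching internal edges of the full-data tree.
    Rendering suppresses supports at or below 50%.
    """
    if n < 1:
        raise PhyloError("need at least 1 bootstrap replicate")
    full = nj_tree(distance(msa, model), msa.taxa)
    full_bips = bipartitions(full)
    counts: dict[frozenset[str], int] = {b: 0 for b in full_bips}

    rng = np.random.default_rng(seed)
    arr = msa.to_array()
    L = arr.shape[1]
    for _ in range(n):
        idx = rng.integers(0, L, size=L)
        rep = MsaLite(taxa=list(msa.taxa), rows=["".join(r) for r in arr[:, idx]])
        try:
            rep_tree = nj_tree(distance(rep, model), rep.taxa)
        except PhyloError:  # a replicate can exceed the JC domain
            continue
        for b in bipartitions(rep_tree):
            if b in counts:
                counts[b] += 1
    supports = {b: 100.0 * c / n for b, c in counts.items()}
    _attach_supports(full, supports)
    return supports, full


def _attach_supports(tree: Node, supports: dict[frozenset[str], float]) -> None:
    all_taxa = frozenset(tree.leaves())
    anchor = min(all_taxa)

    def walk(node: Node) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.label])
        below = frozenset().union(*(walk(c) for c in node.children))
        if 1 < len(below) < len(all_taxa) - 1:
            side = all_taxa - below if anchor in below else below
            if side in supports:
                node.support = supports[side]
        return below

    for child in tree.children:
        walk(child)


def root_at(tree: Node, outgroup: str) -> Node:
    """Display rooting on the edge leading to ``outgroup``.

    Purely presentational: the unrooted topology and all supports are
    unchanged; the outgroup becomes the first child of the new root.  The
    input tree is not modified.
    """
    import copy

    tree = copy.deepcopy(tree)
    parent: dict[int, Node] = {}

    def index(node: Node) -> None:
        for c in node.children:
            parent[id(c)] = node
            index(c)

    index(tree)

    def find(node: Node) -> Node | None:
        if node.is_leaf():
            return node if node.label == outgroup else None
        for c in node.children:
            got = find(c)
            if got is not None:
                return got
        return None

    leaf = find(tree)
    if leaf is None:
        raise PhyloError(f"outgroup {outgroup!r} not in tree")

    def flipped(node: Node, exclude: Node) -> Node:
        """The tree as seen from ``node``, looking away from ``exclude``."""
        kids = [c for c in node.children if c is not exclude]
        up = parent.get(id(node))
        if up is not None:
            up_node = flipped(up, node)
            # the edge node->parent is re-read as parent hanging below node
            up_node.length = node.length
            up_node.support = node.support
            kids.append(up_node)
        return Node(label="" if kids else node.label, children=kids)

    rest = flipped(parent[id(leaf)], leaf)
    return Node(children=[leaf, rest])


def run_phylogeny(
    msa: MsaLite,
    n_boot: int = 1000,
    seed: int | None = None,
    model: str = "jukes_cantor",
    outgroup: str | None = None,
) -> PhyloResult:
    """Gap-eliminate, distance, NJ, bootstrap: the full 16S tree recipe."""
    clean = gap_eliminate(msa)
    dist = distance(clean, model)
    supports, tree = bootstrap_consensus(clean, n=n_boot, seed=seed, model=model)
    return PhyloResult(
        taxa=list(msa.taxa), dist=dist, tree=tree, supports=supports,
        model=model, n_boot=n_boot, seed=seed, outgroup=outgroup,
    )
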