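"""Distance-based phylogenetics: Poisson-corrected distances with pairwise
deletion, neighbor-joining (Saitou-Nei) tree construction, column-resampling
bootstrap support, and nearest-reference subclass labeling.

Trees are unrooted, held as weighted graphs; negative NJ branch lengths are
clamped to zero (the convention of the common desktop packages). A small
center-star progressive aligner is included for pipelines that start from
unaligned domain regions; any external aligner producing the same
fixed-width matrix can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .homology import ScoringScheme, _protein_aligner
from .seqcore import ProteinRecord

GAP = "-"


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows over amino acids plus gap."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.ids) < 2:
            raise ValueError("an alignment needs at least two taxa")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("aligned rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def to_array(self) -> np.ndarray:
        return np.frombuffer("".join(self.rows).encode("ascii"),
                             dtype=np.uint8).reshape(len(self.rows), self.length)


class SaturatedDistance(ValueError):
    """Raised when p = 1 (Poisson correction undefined) or no sites remain."""


def poisson_distance(row_a: str, row_b: str) -> float:
    """Poisson-corrected distance d = -ln(1 - p) with pairwise deletion.

    Columns where either row has a gap are excluded; p is the proportion of
    differing retained sites.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows must have equal length")
    retained = mismatches = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            continue
        retained += 1
        if x != y:
            mismatches += 1
    if retained == 0:
        raise SaturatedDistance("no shared ungapped sites")
    p = mismatches / retained
    if p >= 1.0:
        raise SaturatedDistance("saturated pair (p = 1)")
    return -np.log1p(-p)


def distance_matrix(aln: MultipleAlignment, clamp: bool = False) -> np.ndarray:
    """All pairwise Poisson distances (vectorized).

    With ``clamp=True`` saturated pairs are capped just below p = 1 instead
    of raising (used inside bootstrap replicates, where resampling can
    saturate an otherwise fine pair).
    """
    arr = aln.to_array()
    return _distance_matrix_from_array(arr, clamp)


def _distance_matrix_from_array(arr: np.ndarray, clamp: bool) -> np.ndarray:
    gap = np.uint8(ord(GAP))
    n = arr.shape[0]
    valid = arr != gap
    D = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        retained = both.sum(axis=1).astype(float)
        mism = ((arr[i] != arr) & both).sum(axis=1)
        if np.any(retained == 0):
            if not clamp:
                raise SaturatedDistance("no shared ungapped sites for some pair")
            retained = np.maximum(retained, 1.0)
            mism = np.minimum(mism, retained - 0.0)
        p = mism / retained
        if np.any(p >= 1.0):
            if not clamp:
                raise SaturatedDistance("saturated pair (p = 1)")
            p = np.minimum(p, 1.0 - 1e-9)
        D[i] = -np.log1p(-p)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# Trees


class PhyloTree:
    """An unrooted tree: weighted graph over leaves and internal nodes."""

    def __init__(self, graph: nx.Graph, leaves: Sequence[str]):
        self.graph = graph
        self.leaves = list(leaves)
        self.supports: dict[frozenset, float] = {}

    def patristic(self, source: str) -> dict[str, float]:
        return nx.single_source_dijkstra_path_length(self.graph, source,
                                                     weight="length")

    def distance_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = list(order or self.leaves)
        D = np.zeros((len(order), len(order)))
        for i, a in enumerate(order):
            d = self.patristic(a)
            for j, b in enumerate(order):
                D[i, j] = d[b]
        return D

    def bipartitions(self) -> set[frozenset]:
        """Canonical non-trivial splits: for each edge, the leaf set on the
        side not containing the smallest leaf (computed in one traversal)."""
        leafset = set(self.leaves)
        anchor = min(self.leaves)
        internal = [n for n in self.graph.nodes if n not in leafset]
        root = internal[0] if internal else self.leaves[0]
        splits: set[frozenset] = set()
        stack = [(root, None, False)]
        below: dict = {}
        while stack:
            node, parent, done = stack.pop()
            if not done:
                stack.append((node, parent, True))
                for c in self.graph.neighbors(node):
                    if c != parent:
                        stack.append((c, node, False))
                continue
            kids = [c for c in self.graph.neighbors(node) if c != parent]
            s = set()
            for c in kids:
                s |= below.pop(c)
            if node in leafset:
                s.add(node)
            below[node] = s
            if parent is not None:
                side = s if anchor not in s else leafset - s
                if 1 < len(side) < len(leafset) - 1:
                    splits.add(frozenset(side))
        return splits

    def _side_leaves(self, u, v) -> set:
        g = self.graph.copy()
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, v)
        return {n for n in comp if n in set(self.leaves)}

    def newick(self) -> str:
        """Newick string rooted at an arbitrary internal node, with bootstrap
        supports (if any) as internal node labels."""
        internal = [n for n in self.graph.nodes if n not in set(self.leaves)]
        root = internal[0] if internal else self.leaves[0]
        leafset = set(self.leaves)

        def walk(node, parent) -> str:
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children and node in leafset:
                return node
            parts = []
            for c in children:
                length = self.graph.edges[node, c]["length"]
                sub = walk(c, node)
                parts.append(f"{sub}:{length:.6f}")
            label = ""
            if parent is not None:
                side = self._side_leaves(parent, node)
                if min(self.leaves) in side:
                    side = leafset - side
                key = frozenset(side)
                if key in self.supports:
                    label = f"{self.supports[key]:.0f}"
            return f"({','.join(parts)}){label}"

        return walk(root, None) + ";"


def nj_tree(D: np.ndarray, ids: Sequence[str]) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties on the Q criterion resolve to the smallest (i, j) index pair;
    negative branch lengths are clamped to zero. Two taxa yield the
    degenerate single-edge tree.
    """
    D = np.asarray(D, dtype=float)
    n = len(ids)
    if D.shape != (n, n):
        raise ValueError("distance matrix does not match taxa")
    g = nx.Graph()
    if n == 1:
        g.add_node(ids[0])
        return PhyloTree(g, ids)
    if n == 2:
        g.add_edge(ids[0], ids[1], length=max(D[0, 1], 0.0))
        return PhyloTree(g, ids)

    D = D.copy()
    nodes = list(ids)
    next_internal = 0
    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)  # row-major: smallest pair
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = f"_nj{next_internal}"
        next_internal += 1
        g.add_edge(nodes[i], new, length=li)
        g.add_edge(nodes[j], new, length=lj)
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_next = np.empty((m - 1, m - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = d_new[keep]
        D_next[:-1, -1] = d_new[keep]
        D_next[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [new]
        D = D_next
    g.add_edge(nodes[0], nodes[1], length=max(D[0, 1], 0.0))
    return PhyloTree(g, ids)


def nj_from_alignment(aln: MultipleAlignment, clamp: bool = False) -> PhyloTree:
    return nj_tree(distance_matrix(aln, clamp=clamp), aln.ids)


def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    tree: PhyloTree | None = None,
) -> PhyloTree:
    """Column-resampling bootstrap: support = percent of replicate NJ trees
    containing each bipartition of the full-alignment tree.

    With ``n_reps=0`` the tree is returned without supports. Replicate
    distance matrices clamp saturated pairs rather than failing.
    """
    tree = tree or nj_from_alignment(aln)
    if n_reps <= 0:
        return tree
    rng = np.random.default_rng(seed)
    arr = aln.to_array()
    targets = tree.bipartitions()
    hits = {split: 0 for split in targets}
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep_arr = arr[:, cols]
        D = _distance_matrix_from_array(rep_arr, clamp=True)
        rep = nj_tree(D, aln.ids)
        rep_splits = rep.bipartitions()
        for split in targets:
            if split in rep_splits:
                hits[split] += 1
    tree.supports = {s: 100.0 * h / n_reps for s, h in hits.items()}
    return tree


def label_subclasses(
    tree: PhyloTree, references: Mapping[str, str]
) -> dict[str, str]:
    """Assign each unlabeled leaf the subclass of its nearest labeled leaf by
    patristic distance (ties: smallest distance, then lexicographic id)."""
    refs = {t: references[t] for t in references if t in set(tree.leaves)}
    if not refs:
        raise ValueError("no labeled reference taxa present in the tree")
    out = {}
    for leaf in tree.leaves:
        if leaf in refs:
            continue
        d = tree.patristic(leaf)
        best = min(sorted(refs), key=lambda r: (d[r], r))
        out[leaf] = refs[best]
    return out


# ---------------------------------------------------------------------------
# Multiple alignment of unaligned domain regions


def align_mafft(records: Sequence[ProteinRecord]) -> MultipleAlignment:
    """Multiple alignment via the mafft executable (--auto, deterministic).

    Raises FileNotFoundError when mafft is not on PATH; callers may fall
    back to :func:`align_star`.
    """
    import subprocess
    import tempfile
    from Bio import SeqIO

    if len(records) < 2:
        raise ValueError("need at least two sequences")
    with tempfile.TemporaryDirectory() as tmp:
        infile = f"{tmp}/in.fa"
        with open(infile, "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n{rec.sequence}\n")
        proc = subprocess.run(
            ["mafft", "--auto", "--amino", "--quiet", infile],
            capture_output=True, text=True, check=True,
        )
    rows = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(_as_handle(proc.stdout), "fasta")}
    ids = [r.id for r in records]
    return MultipleAlignment(ids=ids, rows=[rows[i] for i in ids])


def _as_handle(text: str):
    from io import StringIO
    return StringIO(text)


def align_family(records: Sequence[ProteinRecord],
                 scheme: ScoringScheme | None = None) -> MultipleAlignment:
    """Best available aligner: mafft when installed, else center-star."""
    try:
        return align_mafft(records)
    except (FileNotFoundError, OSError):
        return align_star(records, scheme)


# ---------------------------------------------------------------------------
# Center-star progressive alignment (fallback for closely related sets)


def align_star(records: Sequence[ProteinRecord],
               scheme: ScoringScheme | None = None) -> MultipleAlignment:
    """Center-star multiple alignment: global pairwise alignments of every
    sequence against the center (the longest; ties by id), merged by
    projecting all insertions onto the center's coordinates.

    Adequate for closely related, indel-poor domain regions; not a
    general-purpose aligner.
    """
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    scheme = scheme or ScoringScheme(gap_open=10.0, gap_extend=0.5)
    center = min(records, key=lambda r: (-len(r), r.id))
    aligner = _protein_aligner(scheme.matrix, scheme.gap_open, scheme.gap_extend,
                               scheme.match, scheme.mismatch, mode="global")
    c_len = len(center)
    # per sequence: inserted residues before each center position (and after the end)
    pairwise = {}
    max_ins = np.zeros(c_len + 1, dtype=int)
    for rec in records:
        if rec.id == center.id:
            continue
        aln = aligner.align(center.sequence, rec.sequence)[0]
        cols_c, cols_r = _alignment_columns(aln)
        ins = np.zeros(c_len + 1, dtype=int)
        placed: list[tuple[int, int, str]] = []  # (center_pos, insert_rank, residue)
        c_pos = 0
        run = 0
        for cc, rc in zip(cols_c, cols_r):
            if cc == GAP:
                placed.append((c_pos, run, rc))
                run += 1
            else:
                ins[c_pos] = max(ins[c_pos], run)
                run = 0
                if rc != GAP:
                    placed.append((c_pos, -1, rc))
                c_pos += 1
        ins[c_pos] = max(ins[c_pos], run)
        max_ins = np.maximum(max_ins, ins)
        pairwise[rec.id] = placed

    # column offsets in the master alignment
    offsets = np.zeros(c_len + 1, dtype=int)
    total = 0
    for j in range(c_len + 1):
        offsets[j] = total + max_ins[j]
        total = offsets[j] + (1 if j < c_len else 0)
    width = int(offsets[c_len])

    rows = {}
    center_row = [GAP] * width
    for j, aa in enumerate(center.sequence):
        center_row[offsets[j]] = aa
    rows[center.id] = "".join(center_row)
    for rec in records:
        if rec.id == center.id:
            continue
        row = [GAP] * width
        for c_pos, rank, aa in pairwise[rec.id]:
            if rank < 0:
                col = offsets[c_pos]
            else:
                base = offsets[c_pos] - max_ins[c_pos]
                col = base + rank
            row[col] = aa
        rows[rec.id] = "".join(row)
    ids = [r.id for r in records]
    return MultipleAlignment(ids=ids, rows=[rows[i] for i in ids])


def _alignment_columns(aln) -> tuple[str, str]:
    """Aligned rows (with gaps) for a Biopython pairwise alignment."""
    return str(aln[0]), str(aln[1])
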