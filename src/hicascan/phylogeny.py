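"""Distance-based phylogeny of HicA domain sequences.

Pairwise global (Needleman-Wunsch, BLOSUM62, affine gaps) identities give
a distance matrix (d = 1 - identity); trees are built by Saitou-Nei
neighbor joining with deterministic tie-breaking, and class clustering is
quantified as nearest-neighbor purity. Trees are scikit-bio TreeNode
objects, so Newick round-trips and path-length queries come for free.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import TreeNode

PhyloTree = TreeNode


class PhylogenyError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise PhylogenyError(f"matrix shape {self.d.shape} != ({n},{n})")
        if len(set(self.ids)) != n:
            raise PhylogenyError("duplicate ids in distance matrix")
        if not np.all(np.isfinite(self.d)):
            raise PhylogenyError("non-finite distances")
        if np.abs(self.d - self.d.T).max() > 1e-12:
            raise PhylogenyError("matrix not symmetric")
        if np.abs(np.diag(self.d)).max() > 0:
            raise PhylogenyError("diagonal must be zero")


_aligner_cache: dict[tuple[float, float], Align.PairwiseAligner] = {}


def _nw_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    key = (gap_open, gap_extend)
    if key not in _aligner_cache:
        al = Align.PairwiseAligner()
        al.mode = "global"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -float(gap_open)
        al.extend_gap_score = -float(gap_extend)
        _aligner_cache[key] = al
    return _aligner_cache[key]


def global_align(
    a: str,
    b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    return_matches: bool = False,
):
    """Needleman-Wunsch with BLOSUM62 and affine gaps.

    Returns (alignment, fractional_identity); identity is matches over
    alignment columns excluding terminal gap columns. With
    ``return_matches=True`` returns (alignment, identity, n_matches).
    """
    if not a or not b:
        raise PhylogenyError("sequences must be non-empty")
    aligner = _nw_aligner(gap_open, gap_extend)
    aln = aligner.align(a.upper(), b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    # strip terminal gap columns
    start = 0
    end = len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    cols = end - start
    matches = sum(
        1 for i in range(start, end) if row_a[i] == row_b[i] and row_a[i] != "-"
    )
    identity = matches / cols if cols else 0.0
    if return_matches:
        return aln, identity, matches
    return aln, identity


def distance_matrix(
    seqs: Sequence[tuple[str, str]], gap_open: float = 11.0, gap_extend: float = 1.0
) -> DistanceMatrix:
    """Pairwise identity distances d = 1 - fractional_identity."""
    if len(seqs) < 3:
        raise PhylogenyError("need >= 3 sequences")
    ids = [s[0] for s in seqs]
    if len(set(ids)) != len(ids):
        raise PhylogenyError("duplicate sequence ids")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ident = global_align(seqs[i][1], seqs[j][1], gap_open, gap_extend)
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(ids, d)


def nj_tree(D: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining, deterministic.

    Q-criterion ties are broken by the lexicographically smallest pair of
    cluster representative ids. Negative branch-length estimates are
    clamped to zero with the deficit moved to the sister branch, so
    tip-to-tip path lengths on additive inputs are preserved.
    """
    n = len(D.ids)
    if n < 3:
        raise PhylogenyError("NJ needs >= 3 taxa")
    d = D.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=name) for name in D.ids]
    reps = list(D.ids)  # representative id per active cluster (for ties)

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj = max(0.0, lj + li)
            li = 0.0
        if lj < 0:
            li = max(0.0, li + lj)
            lj = 0.0
        return li, lj

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            (tuple(sorted((reps[i], reps[j]))), i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if q[i, j] <= qmin + 1e-12
        ]
        _, i, j = min(candidates)
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[: m - 2, : m - 2] = d[np.ix_(keep, keep)]
        new_d[m - 2, : m - 2] = new_d[: m - 2, m - 2] = dk[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # join the last three clusters at an (unrooted) trichotomy
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lengths = [max(0.0, v) for v in (la, lb, lc)]
    root = TreeNode(children=list(nodes))
    for node, length in zip(nodes, lengths):
        node.length = float(length)
    root.length = None
    return root


def write_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text))


def class_purity(
    D: DistanceMatrix, labels: dict[str, object]
) -> float:
    """Fraction of sequences whose nearest neighbor shares their class.

    Distance ties are broken by lexicographic id; members of singleton
    classes are excluded from the denominator (with a warning).
    """
    counts: dict[object, int] = {}
    for i in labels.values():
        counts[i] = counts.get(i, 0) + 1
    if sum(1 for v in counts.values() if v >= 2) < 2 and len(counts) < 2:
        raise PhylogenyError("need >= 2 classes")
    idx = {name: i for i, name in enumerate(D.ids)}
    total = 0
    agree = 0
    for name in D.ids:
        cls = labels[name]
        if counts[cls] < 2:
            warnings.warn(f"singleton class {cls!r}: {name} excluded from purity")
            continue
        i = idx[name]
        others = [(D.d[i, idx[o]], o) for o in D.ids if o != name]
        others.sort(key=lambda t: (t[0], t[1]))
        nearest = others[0][1]
        total += 1
        if labels[nearest] == cls:
            agree += 1
    if total == 0:
        raise PhylogenyError("no sequences in non-singleton classes")
    return agree / total
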