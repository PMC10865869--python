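"""Global alignment (vs path-enumeration oracle), NJ on additive matrices,
Newick round trips and class purity."""

import math
from functools import lru_cache

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from hicascan.phylogeny import (
    DistanceMatrix,
    PhylogenyError,
    class_purity,
    distance_matrix,
    global_align,
    nj_tree,
    read_newick,
    write_newick,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def oracle_global_score(a, b, gap_open, gap_extend):
    """Independent affine-gap Needleman-Wunsch (end gaps penalized)."""
    NEG = -math.inf

    @lru_cache(maxsize=None)
    def M(i, j):
        if i == 0 and j == 0:
            return 0.0
        if i == 0 or j == 0:
            return NEG
        return BLOSUM62[a[i - 1], b[j - 1]] + max(M(i - 1, j - 1), Ix(i - 1, j - 1), Iy(i - 1, j - 1))

    @lru_cache(maxsize=None)
    def Ix(i, j):
        if i == 0:
            return NEG
        return max(M(i - 1, j) - gap_open, Ix(i - 1, j) - gap_extend)

    @lru_cache(maxsize=None)
    def Iy(i, j):
        if j == 0:
            return NEG
        return max(M(i, j - 1) - gap_open, Iy(i, j - 1) - gap_extend)

    return max(M(len(a), len(b)), Ix(len(a), len(b)), Iy(len(a), len(b)))


def test_identity_trivials():
    _, ident = global_align("M" + "ACDEFGHIKL" * 5, "M" + "ACDEFGHIKL" * 5)
    assert ident == 1.0
    _, ident2 = global_align("AAAA", "CCCC")
    assert ident2 == 0.0


def test_global_score_matches_enumeration_oracle():
    """NW scores equal the independent recursion on sequences <= 12 aa."""
    rng = np.random.default_rng(0)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(30):
        a = "".join(rng.choice(aas, int(rng.integers(4, 13))))
        b = "".join(rng.choice(aas, int(rng.integers(4, 13))))
        aln, _ = global_align(a, b)
        assert aln.score == pytest.approx(oracle_global_score(a, b, 11.0, 1.0))


def test_distance_matrix_properties():
    seqs = [("a", "MKRLAV" * 8), ("b", "MKRLAV" * 8), ("c", "MWWWAV" * 8),
            ("d", "MKRLGV" * 8), ("e", "MARLAV" * 8)]
    dm = distance_matrix(seqs)
    assert np.allclose(dm.d, dm.d.T)
    assert np.allclose(np.diag(dm.d), 0)
    assert dm.d[0, 1] == 0.0  # identical pair
    assert dm.d.min() >= 0 and dm.d.max() <= 1
    # per-pair recomputation
    _, ident = global_align(seqs[0][1], seqs[2][1])
    assert dm.d[0, 2] == pytest.approx(1 - ident)
    # order invariance up to permutation
    dm2 = distance_matrix(seqs[::-1])
    idx = [dm2.ids.index(i) for i in dm.ids]
    assert np.allclose(dm2.d[np.ix_(idx, idx)], dm.d)


def test_distance_matrix_errors():
    with pytest.raises(PhylogenyError):
        distance_matrix([("a", "MKR"), ("b", "MKR")])
    with pytest.raises(PhylogenyError, match="duplicate"):
        distance_matrix([("a", "MKR"), ("a", "MKW"), ("c", "MRR")])


def _tip_distances(tree):
    dm = tree.tip_tip_distances()
    return dm


def test_nj_recovers_known_four_taxon_tree():
    """Additive matrix from ((A:1,B:2):1,C:3,D:5) -> exact recovery."""
    ids = ["A", "B", "C", "D"]
    # path lengths: AB=3, AC=5, AD=7, BC=6, BD=8, CD=8
    d = np.array(
        [[0, 3, 5, 7], [3, 0, 6, 8], [5, 6, 0, 8], [7, 8, 8, 0]], dtype=float
    )
    # verify additivity (four-point condition) before trusting it
    sums = sorted([d[0, 1] + d[2, 3], d[0, 2] + d[1, 3], d[0, 3] + d[1, 2]])
    assert sums[1] == sums[2] and sums[0] <= sums[1]
    tree = nj_tree(DistanceMatrix(ids, d))
    tips = _tip_distances(tree)
    for i, x in enumerate(ids):
        for y in ids[i + 1 :]:
            assert tips[x, y] == pytest.approx(d[ids.index(x), ids.index(y)], abs=1e-9)
    # topology: A,B form a cherry
    a = tree.find("A")
    assert {t.name for t in a.parent.tips()} == {"A", "B"}
    assert a.length == pytest.approx(1.0)
    assert tree.find("B").length == pytest.approx(2.0)


def _random_additive(rng, n):
    """Random tree -> (ids, path-length matrix). Guaranteed additive."""
    nodes = [(f"t{i}",) for i in range(n)]
    children: dict = {}
    lengths: dict = {}
    idx = 0
    items = [f"t{i}" for i in range(n)]
    parent_of = {}
    blen = {}
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        a, b = items[i], items[j]
        new = f"n{idx}"; idx += 1
        parent_of[a] = new
        parent_of[b] = new
        blen[a] = float(rng.uniform(0.1, 2.0))
        blen[b] = float(rng.uniform(0.1, 2.0))
        items = [x for x in items if x not in (a, b)] + [new]
    root = items[0]

    def depth_path(leaf):
        path = []
        x = leaf
        while x != root:
            path.append(x)
            x = parent_of[x]
        return path

    ids = [f"t{i}" for i in range(n)]
    d = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            px = depth_path(ids[x])
            py = depth_path(ids[y])
            shared = set(px) & set(py)
            dist = sum(blen[e] for e in px if e not in shared)
            dist += sum(blen[e] for e in py if e not in shared)
            d[x, y] = d[y, x] = dist
    return ids, d


def test_nj_exact_on_random_additive_matrices():
    """Topology and branch lengths are recovered exactly (path metric
    equality) on 100 random additive matrices with n <= 8."""
    rng = np.random.default_rng(1)
    for trial in range(100):
        n = int(rng.integers(4, 9))
        ids, d = _random_additive(rng, n)
        tree = nj_tree(DistanceMatrix(ids, d))
        tips = _tip_distances(tree)
        for i in range(n):
            for j in range(i + 1, n):
                assert tips[ids[i], ids[j]] == pytest.approx(d[i, j], abs=1e-9), trial


def test_nj_agrees_with_skbio_reference():
    """Cross-check the tip-path metric against scikit-bio's NJ."""
    import skbio

    rng = np.random.default_rng(2)
    ids, d = _random_additive(rng, 7)
    ours = _tip_distances(nj_tree(DistanceMatrix(ids, d)))
    ref_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
    ref = ref_tree.tip_tip_distances()
    for i in range(7):
        for j in range(i + 1, 7):
            assert ours[ids[i], ids[j]] == pytest.approx(ref[ids[i], ids[j]], abs=1e-9)


def test_nj_star_matrix_zero_internal_branches():
    ids = list("ABCDE")
    d = np.full((5, 5), 2.0)
    np.fill_diagonal(d, 0.0)
    tree = nj_tree(DistanceMatrix(ids, d))
    for node in tree.non_tips():
        if node.length is not None:
            assert node.length == pytest.approx(0.0, abs=1e-12)


def test_nj_permutation_invariant_topology():
    rng = np.random.default_rng(3)
    ids, d = _random_additive(rng, 6)
    t1 = _tip_distances(nj_tree(DistanceMatrix(ids, d)))
    perm = list(rng.permutation(6))
    ids2 = [ids[p] for p in perm]
    d2 = d[np.ix_(perm, perm)]
    t2 = _tip_distances(nj_tree(DistanceMatrix(ids2, d2)))
    for i in range(6):
        for j in range(i + 1, 6):
            assert t1[ids[i], ids[j]] == pytest.approx(t2[ids[i], ids[j]], abs=1e-9)


def test_nj_input_validation():
    with pytest.raises(PhylogenyError):
        nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
    with pytest.raises(PhylogenyError, match="finite"):
        DistanceMatrix(["a", "b", "c"], np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]]))


# --- newick ---------------------------------------------------------------


def test_newick_roundtrip_small():
    tree = nj_tree(DistanceMatrix(list("ABC"), np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0.0]])))
    text = write_newick(tree)
    assert text.endswith(";")
    back = read_newick(text)
    assert {t.name for t in back.tips()} == {"A", "B", "C"}
    for t in back.tips():
        assert t.length == pytest.approx(1.0)


def test_newick_quotes_labels_with_spaces():
    rng = np.random.default_rng(4)
    ids = ["seq one", "seq two", "seq three"]
    d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.5], [0.6, 0.5, 0.0]])
    text = write_newick(nj_tree(DistanceMatrix(ids, d)))
    back = read_newick(text)
    assert {t.name for t in back.tips()} == set(ids)


def test_newick_roundtrip_path_lengths_50_leaves():
    rng = np.random.default_rng(5)
    ids, d = _random_additive(rng, 50)
    tree = nj_tree(DistanceMatrix(ids, d))
    back = read_newick(write_newick(tree))
    t1 = _tip_distances(tree)
    t2 = back.tip_tip_distances()
    for i in range(0, 50, 7):
        for j in range(i + 1, 50, 11):
            assert t1[ids[i], ids[j]] == pytest.approx(t2[ids[i], ids[j]], abs=1e-9)


# --- class purity ---------------------------------------------------------


def test_purity_separated_classes():
    """Within-class 10%, between-class 60% -> purity 1.0."""
    ids = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    labels = {i: i[0] for i in ids}
    d = np.full((10, 10), 0.6)
    d[:5, :5] = 0.1
    d[5:, 5:] = 0.1
    np.fill_diagonal(d, 0.0)
    assert class_purity(DistanceMatrix(ids, d), labels) == 1.0


def test_purity_random_labels_near_half():
    """Uniformly random balanced labels over n=100: purity ~ 0.5."""
    rng = np.random.default_rng(6)
    n = 100
    ids = [f"s{i:03d}" for i in range(n)]
    m = rng.uniform(0.2, 0.9, size=(n, n))
    d = (m + m.T) / 2
    np.fill_diagonal(d, 0.0)
    labels_list = ["x"] * 50 + ["y"] * 50
    rng.shuffle(labels_list)
    labels = dict(zip(ids, labels_list))
    p = class_purity(DistanceMatrix(ids, d), labels)
    assert abs(p - 0.5) <= 0.15


def test_purity_singleton_excluded():
    ids = ["a1", "a2", "a3", "lone"]
    labels = {"a1": "a", "a2": "a", "a3": "a", "lone": "z"}
    d = np.array(
        [[0, 0.1, 0.1, 0.9], [0.1, 0, 0.1, 0.9], [0.1, 0.1, 0, 0.9], [0.9, 0.9, 0.9, 0.0]]
    )
    with pytest.warns(UserWarning, match="singleton"):
        p = class_purity(DistanceMatrix(ids, d), labels)
    assert p == 1.0
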