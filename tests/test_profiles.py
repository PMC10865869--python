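"""Profile construction, local scanning (vs brute-force DP), calibration,
architecture assignment and HMMER table ingestion."""

import itertools
import math
from functools import lru_cache

import numpy as np
import pytest

from hicascan.profiles import (
    AMINO_ACIDS,
    DomainHit,
    ProfileError,
    SeedProfile,
    assign_architecture,
    build_profile,
    calibrate_threshold,
    has_coiled_coil,
    ingest_domtblout,
    scan_protein,
)

AA = AMINO_ACIDS
AAI = {a: i for i, a in enumerate(AA)}


def oracle_local_score(protein, columns, gap_open, gap_extend):
    """Independent affine-gap Smith-Waterman by plain recursion.

    The first gapped position costs gap_open, each further one gap_extend;
    an optimal local alignment neither starts nor ends in a gap.
    """
    n, m = len(protein), len(columns)
    NEG = -math.inf

    @lru_cache(maxsize=None)
    def M(i, j):
        if i < 0 or j < 0:
            return NEG
        best_prev = max(0.0, M(i - 1, j - 1), Ix(i - 1, j - 1), Iy(i - 1, j - 1))
        return columns[j][AAI[protein[i]]] + best_prev

    @lru_cache(maxsize=None)
    def Ix(i, j):  # protein residue i against a gap
        if i < 1 or j < 0:
            return NEG
        return max(M(i - 1, j) - gap_open, Ix(i - 1, j) - gap_extend)

    @lru_cache(maxsize=None)
    def Iy(i, j):  # profile column j against a gap
        if i < 0 or j < 1:
            return NEG
        return max(M(i, j - 1) - gap_open, Iy(i, j - 1) - gap_extend)

    best = 0.0
    for i in range(n):
        for j in range(m):
            best = max(best, M(i, j))
    return best


def random_profile(rng, length):
    cols = rng.normal(0.0, 2.0, size=(length, 20))
    return SeedProfile("HicA_dsRBD", cols)


# --- build_profile --------------------------------------------------------


def test_build_profile_log_odds_hand_computed():
    """Per-column scores equal explicit recomputation of the smoothing
    formula on a 5-sequence toy alignment."""
    seqs = ["ACDEF" + "G" * 7, "ACDEF" + "G" * 7, "ACDFF" + "G" * 7,
            "ACD-F" + "G" * 7, "PCDEF" + "G" * 7]
    prof = build_profile(seqs, "HicA_dsRBD", pseudocount=0.5)
    assert prof.length == 12
    # column 0: A x4, P x1 (N=5)
    bg = 1 / 20
    expected_a = math.log2(((4 + 0.5 * bg) / (5 + 0.5)) / bg)
    expected_p = math.log2(((1 + 0.5 * bg) / (5 + 0.5)) / bg)
    expected_absent = math.log2(((0 + 0.5 * bg) / (5 + 0.5)) / bg)
    assert prof.columns[0][AAI["A"]] == pytest.approx(expected_a)
    assert prof.columns[0][AAI["P"]] == pytest.approx(expected_p)
    assert prof.columns[0][AAI["W"]] == pytest.approx(expected_absent)
    # column 3 has one gap: N=4
    expected_e = math.log2(((3 + 0.5 * bg) / (4 + 0.5)) / bg)
    assert prof.columns[3][AAI["E"]] == pytest.approx(expected_e)


def test_build_profile_occupancy_threshold():
    """>= 50% non-gap columns kept, below dropped."""
    seqs = ["AC-" + "G" * 9, "A--" + "G" * 9, "AC-" + "G" * 9, "A--" + "G" * 9]
    prof = build_profile(seqs, "HicA_dsRBD")
    # col0 100%, col1 50% kept; col2 0% dropped
    assert prof.length == 11


def test_build_profile_identical_copies_consensus():
    seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
    prof = build_profile([seq] * 4, "HicA_dsRBD")
    assert prof.consensus == seq
    for j, aa in enumerate(seq):
        assert prof.columns[j].argmax() == AAI[aa]


def test_build_profile_errors():
    with pytest.raises(ProfileError, match="2 aligned"):
        build_profile(["ACDEFGHIKL"], "HicA_dsRBD")
    with pytest.raises(ProfileError):
        build_profile(["-" * 12, "-" * 12], "HicA_dsRBD")


# --- scan_protein ---------------------------------------------------------


def test_scan_consensus_self_hit_score():
    """The consensus aligns over the full profile with score equal to the
    sum of per-column maxima."""
    rng = np.random.default_rng(0)
    seed = "".join(rng.choice(list(AA), 30))
    prof = build_profile([seed] * 4, "HicA_dsRBD")
    prof.score_threshold = 1.0
    (hit,) = scan_protein(prof.consensus, prof)
    assert (hit.start, hit.end) == (0, 30)
    assert hit.score == pytest.approx(prof.self_score)


def test_scan_matches_bruteforce_oracle_small_instances():
    """Best local score equals the recursive oracle on proteins <= 12 aa
    vs profiles of 10 columns, across gap-penalty settings."""
    rng = np.random.default_rng(1)
    for trial in range(25):
        prof = random_profile(rng, 10)
        protein = "".join(rng.choice(list(AA), int(rng.integers(5, 13))))
        go, ge = float(rng.choice([11.0, 5.0, 3.0])), float(rng.choice([1.0, 0.5]))
        hits = scan_protein(protein, prof, go, ge, min_score=1e-6)
        got = hits[0].score if hits else 0.0
        expected = oracle_local_score(protein, prof.columns, go, ge)
        assert got == pytest.approx(expected, abs=1e-9), f"trial {trial}"


def test_scan_multiple_nonoverlapping_hits():
    rng = np.random.default_rng(2)
    seed = "".join(rng.choice(list(AA), 20))
    prof = build_profile([seed] * 4, "HicA_dsRBD")
    calibrate_threshold(prof, 100, rng_seed=0)
    spacer = "".join(rng.choice(list(AA), 15))
    protein = seed + spacer + seed
    hits = scan_protein(protein, prof)
    assert len(hits) == 2
    spans = sorted((h.start, h.end) for h in hits)
    assert spans == [(0, 20), (35, 55)]


def test_scan_empty_protein_error():
    prof = random_profile(np.random.default_rng(0), 12)
    prof.score_threshold = 0.0
    with pytest.raises(ProfileError):
        scan_protein("", prof)


# --- calibrate_threshold --------------------------------------------------


def test_calibration_deterministic_and_separating():
    rng = np.random.default_rng(3)
    seed = "".join(rng.choice(list(AA), 40))
    seqs = [seed] * 3 + ["".join(rng.choice(list(AA), 40))]
    prof = build_profile(seqs, "HicA_dsRBD")
    t1 = calibrate_threshold(prof, 100, rng_seed=42)
    t2 = calibrate_threshold(prof, 100, rng_seed=42)
    assert t1 == t2
    assert t1 < prof.self_score
    with pytest.raises(ProfileError):
        calibrate_threshold(prof, 50, rng_seed=0)


def test_calibration_agrees_with_independent_null():
    """mean + 5 SD of the shuffle null, recomputed independently with the
    brute-force scorer at n=1000, within 10%."""
    rng = np.random.default_rng(4)
    seed = "".join(rng.choice(list(AA), 12))
    prof = build_profile([seed] * 4, "HicA_dsRBD")
    t_pkg = calibrate_threshold(prof, 1000, rng_seed=5)
    consensus = list(prof.consensus)
    rng2 = np.random.default_rng(99)
    scores = []
    for _ in range(1000):
        perm = [consensus[i] for i in rng2.permutation(len(consensus))]
        scores.append(oracle_local_score("".join(perm), prof.columns, 11.0, 1.0))
    t_oracle = float(np.mean(scores) + 5 * np.std(scores))
    assert t_pkg == pytest.approx(t_oracle, rel=0.10)


# --- detection round trip -------------------------------------------------


def test_detection_sensitivity_and_specificity(ancestors):
    """Mutated copies at 30% divergence are detected with the right label
    >= 95% of the time; shuffled decoys give < 5% false labels."""
    from hicascan.simulate import mutate

    entry = ancestors["HicA_dsRBD"]
    prof = entry.profile
    rng = np.random.default_rng(6)
    n = 60
    detected = 0
    false = 0
    for _ in range(n):
        variant = mutate(entry.ancestor, 0.30, rng)
        if scan_protein(variant, prof):
            detected += 1
        shuffled = "".join(
            np.array(list(entry.ancestor))[rng.permutation(len(entry.ancestor))]
        )
        if scan_protein(shuffled, prof):
            false += 1
    assert detected / n >= 0.95
    assert false / n < 0.05


# --- assign_architecture --------------------------------------------------


def test_architecture_disjoint_hits_kept_in_order():
    hits = [
        DomainHit("p", "HicB_pRNaseH", 60, 120, 35.0),
        DomainHit("p", "HicA_dsRBD", 0, 55, 40.0),
    ]
    arch = assign_architecture("p", hits)
    assert arch.labels() == ["HicA_dsRBD", "HicB_pRNaseH"]


def test_architecture_overlap_resolved_by_score():
    hits = [
        DomainHit("p", "DBD_HTH", 80, 130, 30.0),
        DomainHit("p", "DBD_RHH", 85, 125, 20.0),
    ]
    arch = assign_architecture("p", hits)
    assert arch.labels() == ["DBD_HTH"]


def test_architecture_matches_exhaustive_oracle_on_overlap_cluster():
    """On 6 mutually-overlapping hits the exhaustive max-score compatible
    subset is a single hit, and greedy selection finds exactly it."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        hits = [
            DomainHit(
                "p", "DBD_HTH", int(s), int(s) + 50, float(rng.integers(10, 60))
            )
            for s in rng.integers(0, 20, size=6)
        ]
        greedy = assign_architecture("p", hits)
        best = 0.0
        for r in range(7):
            for combo in itertools.combinations(hits, r):
                if all(
                    a.overlap(b) <= 10 for a, b in itertools.combinations(combo, 2)
                ):
                    best = max(best, sum(h.score for h in combo))
        assert sum(h.score for h in greedy.hits) == pytest.approx(best)


def test_architecture_greedy_is_compatible_and_maximal():
    """On arbitrary instances the greedy selection is pairwise compatible
    and no rejected hit could still be added."""
    rng = np.random.default_rng(1)
    for _ in range(20):
        hits = []
        for _k in range(6):
            s = int(rng.integers(0, 120))
            hits.append(
                DomainHit("p", "DBD_HTH", s, s + int(rng.integers(15, 60)),
                          float(rng.integers(10, 60)))
            )
        arch = assign_architecture("p", hits)
        kept = arch.hits
        assert all(
            a.overlap(b) <= 10 for a, b in itertools.combinations(kept, 2)
        )
        for h in hits:
            if h not in kept:
                assert any(h.overlap(k) > 10 for k in kept)


def test_architecture_order_independent():
    rng = np.random.default_rng(7)
    hits = [
        DomainHit("p", l, int(s), int(s) + 40, float(sc))
        for l, s, sc in zip(
            ["DBD_HTH", "DBD_RHH", "HicA_dsRBD", "SMC"],
            rng.integers(0, 100, 4),
            rng.integers(10, 50, 4),
        )
    ]
    a1 = assign_architecture("p", hits)
    a2 = assign_architecture("p", hits[::-1])
    assert [(h.domain_label, h.start) for h in a1.hits] == [
        (h.domain_label, h.start) for h in a2.hits
    ]


# --- domtblout ingestion --------------------------------------------------

DOMTBL_LINE = (
    "{target} - 200 {query} - 55 1.2e-30 105.3 0.1 1 1 "
    "2e-30 {ieval} {score} 0.1 3 55 4 58 {envf} {envt} 0.95 -\n"
)


def test_domtblout_coordinates_and_filtering(tmp_path):
    path = tmp_path / "hits.domtbl"
    path.write_text(
        "# comment line\n"
        + DOMTBL_LINE.format(target="protA", query="hica_hmm", ieval="1e-20",
                             score="80.0", envf=5, envt=60)
        + DOMTBL_LINE.format(target="protB", query="unknown_hmm", ieval="1e-20",
                             score="70.0", envf=1, envt=50)
        + DOMTBL_LINE.format(target="protC", query="hica_hmm", ieval="0.5",
                             score="10.0", envf=1, envt=50)
    )
    with pytest.warns(UserWarning, match="unknown_hmm"):
        hits = ingest_domtblout(path, {"hica_hmm": "HicA_dsRBD"})
    assert len(hits) == 1  # unmapped skipped, weak i-Evalue filtered
    (h,) = hits
    assert (h.protein_id, h.domain_label, h.start, h.end) == ("protA", "HicA_dsRBD", 4, 60)


def test_domtblout_empty_and_malformed(tmp_path):
    empty = tmp_path / "empty.domtbl"
    empty.write_text("# only comments\n#\n")
    assert ingest_domtblout(empty, {}) == []
    bad = tmp_path / "bad.domtbl"
    bad.write_text("too few fields\n")
    with pytest.raises(ProfileError, match="line 1"):
        ingest_domtblout(bad, {})


def test_coiled_coil_proxy():
    heptad = ("LAALAAD" * 20)  # hydrophobic at a and d positions
    assert has_coiled_coil(heptad)
    rng = np.random.default_rng(8)
    random_prot = "".join(rng.choice(list(AA), 300))
    assert not has_coiled_coil(random_prot)
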