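"""Domain detection by position-specific scoring profiles.

A :class:`SeedProfile` is a per-domain log-odds matrix (bits, uniform
background) built from a small seed alignment. Proteins are scanned by
Smith-Waterman local alignment against the profile columns with affine
gaps; the dynamic programming runs on Biopython's PairwiseAligner by giving
every profile column its own symbol in a custom substitution matrix.
Score thresholds are calibrated per profile from a shuffle null
(mean + 5 SD of the best local score of shuffled consensus sequences).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

DOMAIN_LABELS = (
    "HicA_dsRBD",
    "HicB_pRNaseH",
    "DBD_HTH",
    "DBD_RHH",
    "DBD_PhdYefM",
    "SharedDomain",
    "pVip",
    "SMC",
    "RelE",
    "DUF1902",
    "NERD",
)

DBD_LABELS = ("DBD_HTH", "DBD_RHH", "DBD_PhdYefM")

#: score assigned to masked or non-standard residues; blocks alignment through
_BLOCK = -1e4


class ProfileError(ValueError):
    pass


@dataclass
class DomainHit:
    """A retained local-alignment hit of a profile on one protein."""

    protein_id: str
    domain_label: str
    start: int  # 0-based half-open protein coords
    end: int
    score: float

    def overlap(self, other: "DomainHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class DomainArchitecture:
    """Ordered (N->C), non-overlapping domain hits on one protein."""

    protein_id: str
    hits: list[DomainHit] = field(default_factory=list)

    def labels(self) -> list[str]:
        return [h.domain_label for h in self.hits]

    def has(self, label: str) -> bool:
        return any(h.domain_label == label for h in self.hits)

    def first(self, label: str) -> Optional[DomainHit]:
        for h in self.hits:
            if h.domain_label == label:
                return h
        return None

    def has_dbd(self) -> bool:
        return any(h.domain_label in DBD_LABELS for h in self.hits)


@dataclass
class SeedProfile:
    """Per-domain position-specific scoring matrix (log-odds, bits)."""

    domain_label: str
    columns: np.ndarray  # (length, 20) log2-odds vs uniform background
    score_threshold: Optional[float] = None
    _aligner: Optional[Align.PairwiseAligner] = field(
        default=None, repr=False, compare=False
    )
    _aligner_key: Optional[tuple] = field(default=None, repr=False, compare=False)
    _symbols: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 20:
            raise ProfileError("profile columns must be (length, 20)")
        if self.length < 10:
            raise ProfileError(
                f"{self.domain_label}: profile length {self.length} < 10"
            )

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[j] for j in np.argmax(self.columns, axis=1))

    @property
    def self_score(self) -> float:
        return float(np.max(self.columns, axis=1).sum())

    def aligner(self, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
        """Local aligner whose substitution matrix encodes the profile."""
        key = (gap_open, gap_extend)
        if self._aligner is not None and self._aligner_key == key:
            return self._aligner
        w = self.length
        cols = tuple(f"c{j}" for j in range(w))
        alphabet = tuple(AMINO_ACIDS) + ("X",) + cols
        n = len(alphabet)
        mat = np.full((n, n), _BLOCK)
        # aa rows vs column symbols; everything else is never aligned
        mat[:20, 21:] = self.columns.T
        mat[21:, :20] = self.columns
        arr = substitution_matrices.Array(alphabet=alphabet, dims=2, data=mat)
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = arr
        al.open_gap_score = -float(gap_open)
        al.extend_gap_score = -float(gap_extend)
        self._aligner_key = key
        self._aligner = al
        self._symbols = cols
        return al


def _read_alignment(aligned_fasta: str | Path | Sequence[str]) -> list[str]:
    if isinstance(aligned_fasta, (str, Path)) and Path(str(aligned_fasta)).exists():
        seqs = [str(r.seq).upper() for r in SeqIO.parse(str(aligned_fasta), "fasta")]
    else:
        seqs = [str(s).upper() for s in aligned_fasta]  # type: ignore[union-attr]
    if len(seqs) < 2:
        raise ProfileError(
            "profile needs >= 2 aligned sequences (duplicating one sequence "
            "adds no information)"
        )
    if len({len(s) for s in seqs}) != 1:
        raise ProfileError("aligned sequences must have equal length")
    return seqs


def build_profile(
    aligned_fasta: str | Path | Sequence[str],
    domain_label: str,
    pseudocount: float = 0.5,
) -> SeedProfile:
    """Build a log-odds profile from an aligned FASTA (or aligned strings).

    Columns with >= 50% non-gap occupancy are retained. Per retained column,
    ``log2(((count + pc/20) / (N + pc)) / (1/20))`` with uniform background
    and N the column's non-gap count.
    """
    seqs = _read_alignment(aligned_fasta)
    ncols = len(seqs[0])
    nseq = len(seqs)
    bg = 1.0 / 20.0
    out_cols = []
    for j in range(ncols):
        residues = [s[j] for s in seqs if s[j] in _AA_INDEX]
        if len(residues) * 2 < nseq:  # < 50% occupancy
            continue
        counts = np.zeros(20)
        for r in residues:
            counts[_AA_INDEX[r]] += 1
        n = len(residues)
        freqs = (counts + pseudocount * bg) / (n + pseudocount)
        out_cols.append(np.log2(freqs / bg))
    if not out_cols:
        raise ProfileError("alignment has no columns with >= 50% occupancy")
    return SeedProfile(domain_label, np.array(out_cols))


def _encode(protein: str) -> list[str]:
    return [c if c in _AA_INDEX else "X" for c in protein.upper()]


def _best_local(
    protein_syms: list[str],
    profile: SeedProfile,
    gap_open: float,
    gap_extend: float,
):
    """Best local alignment of (possibly masked) protein vs the profile.

    Returns (score, start, end) in protein coordinates; (0, None, None)
    when nothing aligns.
    """
    al = profile.aligner(gap_open, gap_extend)
    cols = list(profile._symbols)  # type: ignore[arg-type]
    alns = al.align(protein_syms, cols)
    if alns.score <= 0:
        return 0.0, None, None
    best = alns[0]
    blocks = best.aligned[0]
    return float(alns.score), int(blocks[0][0]), int(blocks[-1][1])


def scan_protein(
    protein: str,
    profile: SeedProfile,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    *,
    protein_id: str = "query",
    min_score: Optional[float] = None,
) -> list[DomainHit]:
    """All non-overlapping local hits of a profile on one protein.

    Hits are found best-first: after each hit the matched residues are
    masked and the protein rescanned; the scan stops below the profile's
    calibrated threshold (or an explicit ``min_score``).
    """
    if not protein:
        raise ProfileError("protein must be non-empty")
    threshold = min_score if min_score is not None else profile.score_threshold
    if threshold is None:
        raise ProfileError(
            f"profile {profile.domain_label} is uncalibrated; run "
            "calibrate_threshold or pass min_score"
        )
    syms = _encode(protein)
    hits: list[DomainHit] = []
    for _ in range(64):
        score, start, end = _best_local(syms, profile, gap_open, gap_extend)
        if start is None or score < threshold:
            break
        hits.append(DomainHit(protein_id, profile.domain_label, start, end, score))
        for i in range(start, end):
            syms[i] = "X"
    return hits


def calibrate_threshold(
    profile: SeedProfile,
    n_shuffles: int = 100,
    rng_seed: int = 0,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Set the profile threshold to mean + 5 SD of a shuffle null.

    The null is the best local score of the profile against shuffled
    copies of its own consensus sequence.
    """
    if n_shuffles < 100:
        raise ProfileError("n_shuffles must be >= 100")
    rng = np.random.default_rng(rng_seed)
    consensus = list(profile.consensus)
    scores = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = [consensus[j] for j in rng.permutation(len(consensus))]
        scores[i], _, _ = _best_local(shuffled, profile, gap_open, gap_extend)
    threshold = float(scores.mean() + 5.0 * scores.std())
    profile.score_threshold = threshold
    return threshold


def assign_architecture(protein_id: str, hits: Iterable[DomainHit]) -> DomainArchitecture:
    """Greedy maximal-score selection of mutually compatible hits.

    Hits are taken by (score desc, start asc, label asc); a hit is kept if
    it overlaps every previously kept hit by <= 10 residues. Kept hits are
    returned N->C.
    """
    ordered = sorted(hits, key=lambda h: (-h.score, h.start, h.domain_label))
    kept: list[DomainHit] = []
    for h in ordered:
        if h.protein_id != protein_id:
            raise ProfileError("all hits must belong to the same protein")
        if all(h.overlap(k) <= 10 for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end, h.domain_label))
    return DomainArchitecture(protein_id, kept)


def ingest_domtblout(
    path: str | Path,
    label_map: dict[str, str],
    max_i_evalue: float = 1e-5,
) -> list[DomainHit]:
    """Read HMMER3 --domtblout hits, mapping profile names to domain labels.

    Envelope coordinates (1-based inclusive) become 0-based half-open.
    Unmapped profile names are skipped with a warning; malformed lines
    raise with the offending line number.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 23:
                raise ProfileError(f"{path}: malformed domtblout line {lineno}")
            try:
                target, query = parts[0], parts[3]
                i_evalue = float(parts[12])
                bitscore = float(parts[13])
                env_from, env_to = int(parts[19]), int(parts[20])
            except ValueError as exc:
                raise ProfileError(
                    f"{path}: malformed domtblout line {lineno}: {exc}"
                ) from exc
            if query not in label_map:
                warnings.warn(f"domtblout profile name {query!r} not mapped; skipped")
                continue
            if i_evalue > max_i_evalue:
                continue
            hits.append(
                DomainHit(target, label_map[query], env_from - 1, env_to, bitscore)
            )
    return hits


def write_hits_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tdomain_label\tstart\tend\tscore\n")
        for h in hits:
            fh.write(f"{h.protein_id}\t{h.domain_label}\t{h.start}\t{h.end}\t{h.score:.3f}\n")


# ---------------------------------------------------------------------------
# coiled-coil proxy (used by the Class 14 SMC sanity rule)

_HYDROPHOBIC = set("AVLIMFWY")


def has_coiled_coil(protein: str, window: int = 100, min_ad_fraction: float = 0.85) -> bool:
    """Heptad-periodicity proxy: some 100-aa window has a heptad frame whose
    a/d positions are >= 85% hydrophobic. Random-composition proteins
    essentially never satisfy this."""
    n = len(protein)
    if n < window:
        return False
    hydro = np.fromiter((c in _HYDROPHOBIC for c in protein), dtype=float, count=n)
    for frame in range(7):
        idx = np.arange(n)
        ad = ((idx - frame) % 7 == 0) | ((idx - frame) % 7 == 3)
        for s in range(0, n - window + 1, 7):
            sel = ad[s : s + window]
            if sel.sum() and hydro[s : s + window][sel].mean() >= min_ad_fraction:
                return True
    return False
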