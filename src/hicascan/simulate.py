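"""Synthetic annotated genomes with ground-truth HicA locus labels.

The generator emulates the fourteen genetic contexts in which HicA toxin
domains occur: bicistronic hicAB/hicBA operons with small, DBD-bearing or
long HicB antitoxins (classes 1-8), hicA genes adjacent to prokaryotic
Viperin genes (9-10), fused monocistronic HicA-HicB architectures (11-13)
and the SMC-HicA fusion (14) -- plus the confounders that complicate real
genomes: pseudogenized antitoxins, solitary hicB genes, neighboring TA
modules, transposases and RelE-pVip pairs.

Every domain is a mutated copy of a randomly drawn ancestor protein;
profiles are built from 8 seed copies at 15% divergence of the same
ancestor, so detection sensitivity can be studied as a function of the
per-site substitution rate (``divergence``). Genes are back-translated
with uniform synonymous codons (table 11) and embedded in random DNA;
negative intergenic gaps are realized by sharing nucleotides between the
two reading frames, as in translationally coupled operons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .annotations import (
    GeneFeature,
    GenomeRecord,
    write_genbank,
    write_gff_fasta,
)
from .profiles import AMINO_ACIDS, SeedProfile, build_profile, calibrate_threshold

STOP_CODONS = ("TAA", "TAG", "TGA")

#: ancestor lengths (aa) per domain; HicA/HicB/DBD/SharedDomain sizes follow
#: the sizes typical of each family, pVip and SMC are large multi-domain
#: proteins, SMC large enough that fusions exceed the 600-aa SMC floor.
ANCESTOR_LENGTHS = {
    "HicA_dsRBD": 55,
    "HicB_pRNaseH": 50,
    "DBD_HTH": 45,
    "DBD_RHH": 45,
    "DBD_PhdYefM": 45,
    "SharedDomain": 55,
    "pVip": 280,
    "SMC": 700,
    "RelE": 90,
    "DUF1902": 55,
    "NERD": 80,
}

DECOY_KINDS = (
    "pseudogene_hicb",
    "solitary_hicb",
    "neighbor_vapBC",
    "neighbor_relBE",
    "transposase",
    "relE_pvip_pair",
)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# primitives


def mutate(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each site to a uniformly random different residue with
    probability ``divergence``; no indels."""
    out = list(protein)
    for i, aa in enumerate(out):
        if rng.random() < divergence:
            choices = [a for a in AMINO_ACIDS if a != aa]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


_fwd = CodonTable.unambiguous_dna_by_id[11].forward_table
_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_fwd.items()):
    _CODONS.setdefault(aa, []).append(codon)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous back-translation; an initiator M is always ATG."""
    codons = []
    for i, aa in enumerate(protein):
        if i == 0 and aa == "M":
            codons.append("ATG")
        else:
            opts = _CODONS[aa]
            codons.append(opts[rng.integers(len(opts))])
    return "".join(codons)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=n))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def _assemble(
    rng: np.random.Generator,
    parts: Sequence[str],
    total: int,
    anchor: str = "none",  # 'none' | 'cterm' | 'nterm'
) -> str:
    """'M' + domains + random padding, total length ``total``.

    ``cterm`` flushes the last part to the C terminus; ``nterm`` flushes
    the first part to position 1.
    """
    core = sum(len(p) for p in parts)
    spare = total - 1 - core
    if spare < 0:
        raise SimulationError(f"domains ({core} aa) exceed requested length {total}")
    if anchor == "cterm":
        pads = [spare] + [0] * len(parts)
    elif anchor == "nterm":
        pads = [0] * len(parts) + [spare]
    else:
        front = int(min(spare, 4))
        pads = [front] + [0] * (len(parts) - 1) + [spare - front]
    pieces = ["M"]
    for pad, part in zip(pads, parts):
        pieces.append(_random_protein(rng, pad))
        pieces.append(part)
    pieces.append(_random_protein(rng, pads[-1]) if len(pads) > len(parts) else "")
    return "".join(pieces)


# ---------------------------------------------------------------------------
# ancestors


@dataclass
class AncestorEntry:
    ancestor: str
    profile: SeedProfile
    seed_copies: list[str]


def make_ancestors(rng_seed: int, calibration_shuffles: int = 100) -> dict[str, AncestorEntry]:
    """One random ancestor protein + calibrated profile per domain label.

    Profiles are built from 8 copies of the ancestor at 15% divergence,
    and thresholds calibrated against a shuffle null (deterministic in
    ``rng_seed``).
    """
    rng = np.random.default_rng(rng_seed)
    out: dict[str, AncestorEntry] = {}
    for i, (label, length) in enumerate(sorted(ANCESTOR_LENGTHS.items())):
        ancestor = _random_protein(rng, length)
        seeds = [mutate(ancestor, 0.15, rng) for _ in range(8)]
        profile = build_profile(seeds, label)
        calibrate_threshold(
            profile, calibration_shuffles, rng_seed=(rng_seed * 131 + i) % (2**31)
        )
        out[label] = AncestorEntry(ancestor, profile, seeds)
    return out


def write_seed_alignments(ancestors: dict[str, AncestorEntry], directory: str | Path) -> None:
    """Write each profile's seed copies as an aligned FASTA (<label>.afa)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for label, entry in sorted(ancestors.items()):
        with open(directory / f"{label}.afa", "w") as fh:
            for i, s in enumerate(entry.seed_copies):
                fh.write(f">{label}_seed{i}\n{s}\n")


# ---------------------------------------------------------------------------
# locus specification


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic HicA locus (one of the 14 contexts)."""

    class_id: int
    rng_seed: int = 0
    divergence: float = 0.1
    hica_len: Optional[int] = None
    hicb_len: Optional[int] = None
    gap_nt: Optional[int] = None
    strand: str = "+"
    decoys: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 1 <= self.class_id <= 14:
            raise SimulationError(f"class_id must be 1..14, got {self.class_id}")
        if not 0 <= self.divergence < 0.5:
            raise SimulationError("divergence must be in [0, 0.5)")
        unknown = set(self.decoys) - set(DECOY_KINDS)
        if unknown:
            raise SimulationError(f"unknown decoys: {sorted(unknown)}")


#: (hica_len, hicb_len, gap_nt) defaults per class, within the documented
#: size ranges of each class; fused classes use hica_len for the full CDS.
CLASS_DEFAULTS: dict[int, tuple[int, Optional[int], Optional[int]]] = {
    1: (70, 80, 2),
    2: (72, 85, -4),
    3: (70, 115, 8),
    4: (68, 110, 6),
    5: (70, 105, 0),
    6: (128, 105, -1),
    7: (70, 225, 5),
    8: (95, 345, 4),
    9: (70, None, 50),
    10: (70, None, 40),
    11: (165, None, None),
    12: (140, None, None),
    13: (380, None, None),
    14: (765, None, None),
}


# ---------------------------------------------------------------------------
# DNA assembly of gene pairs (with frame-compatible overlaps)


def _feasible_overlap(k: int) -> bool:
    # k%3==0 puts the upstream stop in the downstream frame; 2 and 5 admit
    # no stop codon consistent with the downstream ATG.
    return 1 <= k <= 20 and k != 2 and k != 5 and (k < 3 or k % 3 != 0)


def _nearest_feasible_gap(gap: int) -> int:
    for delta in range(1, 25):
        for cand in (gap + delta, gap - delta):
            if cand >= 0 or _feasible_overlap(-cand):
                return cand
    return 0


def _overlap_region(k: int, rng: np.random.Generator) -> str:
    """Shared nucleotides for an overlap of k: starts the downstream ATG
    and ends with the upstream gene's stop codon."""
    for _ in range(500):
        s: list[Optional[str]] = [None] * k
        s[0:3] = list("ATG")
        stop = STOP_CODONS[rng.integers(3)]
        ok = True
        for i, c in enumerate(stop):
            j = k - 3 + i
            if s[j] is None:
                s[j] = c
            elif s[j] != c:
                ok = False
        if not ok:
            continue
        for j in range(k):
            if s[j] is None:
                s[j] = "ACGT"[rng.integers(4)]
        region = "".join(s)  # frame checks happen on the full genes
        return region
    raise SimulationError(f"could not construct overlap region of {k} nt")


def _translate_dna(dna: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(dna).translate(table=11))


def _clean_cds(dna: str) -> Optional[str]:
    """Protein if dna is one clean ORF (single terminal stop), else None."""
    if len(dna) % 3:
        return None
    prot = _translate_dna(dna)
    if not prot.endswith("*") or "*" in prot[:-1]:
        return None
    return "M" + prot[1:-1]


def _pair_dna(
    prot_a: str, prot_b: str, gap: int, rng: np.random.Generator
) -> tuple[str, tuple[int, int], tuple[int, int], str, str]:
    """DNA for two co-oriented genes A then B separated by ``gap`` nt.

    Returns (dna, a_span, b_span, protein_a, protein_b); for negative gaps
    the realized proteins may differ from the requested ones in a few
    junction residues.
    """
    if gap >= 0:
        dna_a = back_translate(prot_a, rng) + STOP_CODONS[rng.integers(3)]
        dna_b = back_translate(prot_b, rng) + STOP_CODONS[rng.integers(3)]
        dna = dna_a + _random_dna(rng, gap) + dna_b
        a_span = (0, len(dna_a))
        b_span = (len(dna_a) + gap, len(dna))
        return dna, a_span, b_span, prot_a, prot_b
    k = -gap
    if not _feasible_overlap(k):
        raise SimulationError(
            f"overlap of {k} nt is not frame-constructible; nearest feasible "
            f"gap is {_nearest_feasible_gap(gap)}"
        )
    for _ in range(200):
        if k == 1:
            dna_a = back_translate(prot_a, rng) + "TAA"
            dna_b = back_translate(prot_b, rng) + STOP_CODONS[rng.integers(3)]
            a2, b2 = prot_a, prot_b
        else:
            region = _overlap_region(k, rng)
            # upstream gene: keep the first c designed residues; the codon
            # spanning the junction is chosen to fit the shared region (its
            # residue may differ from the requested protein)
            j = (-k) % 3  # body nt in the junction codon
            c = (3 * (len(prot_a) + 1) - k - j) // 3
            body_a = back_translate(prot_a[:c], rng)
            if j:
                suffix = region[: 3 - j]
                cands_a = [
                    cod
                    for codons in _CODONS.values()
                    for cod in codons
                    if cod.endswith(suffix)
                ]
                junction = cands_a[rng.integers(len(cands_a))][:j]
            else:
                junction = ""
            dna_a = body_a + junction + region
            # downstream gene: complete the codon the shared region cuts into
            n_full, r = divmod(k, 3)
            if r:
                prefix = region[3 * n_full :]
                cands = [
                    c
                    for codons in _CODONS.values()
                    for c in codons
                    if c.startswith(prefix)
                ]
                codon = cands[rng.integers(len(cands))]
                tail = back_translate(prot_b[n_full + 1 :], rng)
                dna_b = region + codon[r:] + tail + STOP_CODONS[rng.integers(3)]
            else:
                dna_b = region + back_translate(prot_b[n_full:], rng) + STOP_CODONS[
                    rng.integers(3)
                ]
            a2 = _clean_cds(dna_a)
            b2 = _clean_cds(dna_b)
            if a2 is None or b2 is None:
                continue
        dna = dna_a[:-k] + dna_b
        a_span = (0, len(dna_a))
        b_span = (len(dna_a) - k, len(dna))
        return dna, a_span, b_span, a2, b2
    raise SimulationError(f"failed to realize overlap of {k} nt after 200 tries")


# ---------------------------------------------------------------------------
# locus construction


@dataclass
class _Gene:
    role: str  # 'hicA', 'hicB', 'fused', 'pVip', or decoy roles
    start: int
    end: int
    strand: str
    protein: str
    kind: str = "CDS"


@dataclass
class LocusFragment:
    sequence: str
    genes: list[_Gene]
    truth: dict


def _domain(entry: AncestorEntry, divergence: float, rng: np.random.Generator) -> str:
    return mutate(entry.ancestor, divergence, rng)


def build_locus(
    spec: SyntheticSpec, ancestors: dict[str, AncestorEntry]
) -> LocusFragment:
    """One synthetic locus on the forward strand of its own fragment
    (reverse-strand specs flip the whole fragment)."""
    rng = np.random.default_rng(spec.rng_seed)
    cid = spec.class_id
    d_a, d_b, d_g = CLASS_DEFAULTS[cid]
    la = spec.hica_len if spec.hica_len is not None else d_a
    lb = spec.hicb_len if spec.hicb_len is not None else d_b
    gap = spec.gap_nt if spec.gap_nt is not None else d_g
    div = spec.divergence
    A = ancestors

    def dom(label: str) -> str:
        return _domain(A[label], div, rng)

    hica = _assemble(rng, [dom("HicA_dsRBD")], la) if cid not in (6, 8) else None
    genes: list[_Gene] = []
    seq = ""
    truth: dict = {
        "class_id": cid,
        "is_decoy": "pseudogene_hicb" in spec.decoys,
        "gap_nt": gap,
        "hica_len": la,
        "hicb_len": lb,
        "strand": spec.strand,
        "seed": spec.rng_seed,
        "decoys": ",".join(sorted(spec.decoys)),
    }

    def pair(first_role, first_prot, second_role, second_prot):
        nonlocal seq
        dna, sp1, sp2, p1, p2 = _pair_dna(first_prot, second_prot, gap, rng)
        seq = dna
        genes.append(_Gene(first_role, sp1[0], sp1[1], "+", p1))
        genes.append(_Gene(second_role, sp2[0], sp2[1], "+", p2))

    if "pseudogene_hicb" in spec.decoys:
        _build_pseudogene_locus(spec, ancestors, rng, genes, truth)
        seq = truth.pop("_seq")
    elif cid in (1, 3, 4):
        if cid == 1:
            hicb = _assemble(rng, [dom("HicB_pRNaseH")], lb)
        else:
            dbd = "DBD_HTH" if cid == 3 else "DBD_RHH"
            hicb = _assemble(rng, [dom("HicB_pRNaseH"), dom(dbd)], lb, anchor="cterm")
        pair("hicA", hica, "hicB", hicb)
    elif cid == 2:
        hicb = _assemble(rng, [dom("HicB_pRNaseH")], lb)
        pair("hicB", hicb, "hicA", hica)
    elif cid in (5, 6):
        hicb = _assemble(rng, [dom("DBD_PhdYefM"), dom("HicB_pRNaseH")], lb, anchor="nterm")
        if cid == 6:
            hica = _assemble(rng, [dom("HicA_dsRBD"), dom("SharedDomain")], la, anchor="cterm")
        pair("hicB", hicb, "hicA", hica)
    elif cid == 7:
        hicb = _assemble(rng, [dom("DUF1902"), dom("DUF1902")], lb)
        pair("hicB", hicb, "hicA", hica)
    elif cid == 8:
        hica = _assemble(rng, [dom("HicA_dsRBD")], la)
        hicb = _assemble(rng, [dom("HicB_pRNaseH")], lb, anchor="cterm")
        pair("hicB", hicb, "hicA", hica)
    elif cid in (9, 10):
        pvip = _assemble(rng, [dom("pVip")], len(A["pVip"].ancestor) + 12)
        if cid == 9:
            pair("hicA", hica, "pVip", pvip)
        else:
            pair("pVip", pvip, "hicA", hica)
    elif cid in (11, 12, 13, 14):
        if cid == 11:
            dbd = "DBD_HTH" if rng.random() < 0.5 else "DBD_RHH"
            fused = _assemble(
                rng, [dom("HicA_dsRBD"), dom("HicB_pRNaseH"), dom(dbd)], la, anchor="cterm"
            )
        elif cid == 12:
            fused = _assemble(rng, [dom("HicB_pRNaseH"), dom("HicA_dsRBD")], la, anchor="cterm")
        elif cid == 13:
            fused = _assemble(rng, [dom("HicB_pRNaseH"), dom("HicA_dsRBD")], la, anchor="cterm")
        else:
            parts = [dom("SMC"), dom("HicA_dsRBD")]
            if rng.random() < 0.5:
                truth["decoys"] += (";nerd" if truth["decoys"] else "nerd")
            fused = _assemble(rng, parts, la, anchor="cterm")
        dna = back_translate(fused, rng) + STOP_CODONS[rng.integers(3)]
        seq = dna
        genes.append(_Gene("fused", 0, len(dna), "+", fused))
        truth["gap_nt"] = None

    seq, genes2 = _add_decoys(spec, ancestors, rng, seq, genes)
    frag = LocusFragment(seq, genes2, truth)
    if spec.strand == "-":
        frag = _flip_fragment(frag)
    return frag


def _build_pseudogene_locus(spec, ancestors, rng, genes, truth):
    """Class-3-like locus whose hicB carries an engineered stop before the
    HTH: annotated as a short DBD-less HicB, with the DBD still encoded in
    frame downstream of the stop (read-through reveals it)."""
    div = spec.divergence
    la = spec.hica_len if spec.hica_len is not None else 70
    gap = spec.gap_nt if spec.gap_nt is not None else 4
    hica = _assemble(rng, [_domain(ancestors["HicA_dsRBD"], div, rng)], la)
    core = _assemble(rng, [_domain(ancestors["HicB_pRNaseH"], div, rng)], 75)
    dbd = _domain(ancestors["DBD_HTH"], div, rng)
    dna_a = back_translate(hica, rng) + STOP_CODONS[rng.integers(3)]
    # truncated hicB ORF, then the DBD continues in the same frame
    dna_b = back_translate(core, rng) + "TAA" + back_translate(dbd, rng) + "TAA"
    spacer = _random_dna(rng, max(gap, 0))
    seq = dna_a + spacer + dna_b
    b0 = len(dna_a) + len(spacer)
    genes.append(_Gene("hicA", 0, len(dna_a), "+", hica))
    genes.append(_Gene("hicB", b0, b0 + 3 * (len(core) + 1), "+", core))
    truth.update({"class_id": 1, "is_decoy": True, "gap_nt": gap, "hicb_len": len(core)})
    truth["_seq"] = seq


def _add_decoys(spec, ancestors, rng, seq, genes):
    div = spec.divergence
    out = list(genes)

    def append_gene(role, protein, gap=60, kind="CDS"):
        nonlocal seq
        dna = back_translate(protein, rng) + STOP_CODONS[rng.integers(3)]
        start = len(seq) + gap
        seq = seq + _random_dna(rng, gap) + dna
        out.append(_Gene(role, start, start + len(dna), "+", protein, kind))

    for decoy in sorted(spec.decoys):
        if decoy == "pseudogene_hicb":
            continue  # handled in locus construction
        if decoy == "solitary_hicb":
            append_gene("decoy_hicB", _assemble(rng, [_domain(ancestors["HicB_pRNaseH"], div, rng)], 82))
        elif decoy == "neighbor_vapBC":
            append_gene("decoy_vapB", "M" + _random_protein(rng, 75))
            append_gene("decoy_vapC", "M" + _random_protein(rng, 130), gap=5)
        elif decoy == "neighbor_relBE":
            append_gene("decoy_relB", "M" + _random_protein(rng, 85))
            append_gene("decoy_relE", _assemble(rng, [_domain(ancestors["RelE"], div, rng)], 100), gap=3)
        elif decoy == "transposase":
            append_gene("decoy_transposase", "M" + _random_protein(rng, 300))
        elif decoy == "relE_pvip_pair":
            append_gene("decoy_relE", _assemble(rng, [_domain(ancestors["RelE"], div, rng)], 100))
            append_gene("decoy_pVip", _assemble(rng, [_domain(ancestors["pVip"], div, rng)], 292), gap=40)
    return seq, out


def _flip_fragment(frag: LocusFragment) -> LocusFragment:
    from Bio.Seq import Seq

    n = len(frag.sequence)
    seq = str(Seq(frag.sequence).reverse_complement())
    genes = [
        _Gene(g.role, n - g.end, n - g.start, "-" if g.strand == "+" else "+", g.protein, g.kind)
        for g in frag.genes
    ]
    genes.sort(key=lambda g: g.start)
    return LocusFragment(seq, genes, frag.truth)


# ---------------------------------------------------------------------------
# genome assembly


def build_genome(
    specs: Sequence[SyntheticSpec],
    island: bool = False,
    rng_seed: int = 0,
    contig_id: str = "synctg1",
    ancestors: Optional[dict[str, AncestorEntry]] = None,
) -> tuple[GenomeRecord, pd.DataFrame]:
    """Concatenate loci into one contig with random spacers.

    Default spacers are >= 500 nt; with ``island=True`` loci are packed
    with short spacers, emulating defense islands where many TA loci
    cluster within a few kilobases.
    """
    rng = np.random.default_rng(rng_seed)
    if ancestors is None:
        ancestors = _ANCESTOR_CACHE.get_or_make(rng_seed)
    seq_parts: list[str] = []
    features: list[GeneFeature] = []
    rows = []
    pos = 0
    lead = 50 if island else 300
    seq_parts.append(_random_dna(rng, lead))
    pos += lead
    for i, spec in enumerate(specs, 1):
        frag = build_locus(spec, ancestors=ancestors)
        locus_id = f"L{i:03d}"
        for j, g in enumerate(frag.genes):
            features.append(
                GeneFeature(
                    gene_id=f"{locus_id}_{g.role}" + (f"_{j}" if _dup(frag.genes, g) else ""),
                    start=pos + g.start,
                    end=pos + g.end,
                    strand=g.strand,
                    kind=g.kind,
                    protein=g.protein,
                    product="hypothetical protein",
                )
            )
        seq_parts.append(frag.sequence)
        pos += len(frag.sequence)
        row = {"locus_id": locus_id, **frag.truth}
        rows.append(row)
        spacer = int(rng.integers(40, 90)) if island else int(rng.integers(500, 700))
        seq_parts.append(_random_dna(rng, spacer))
        pos += spacer
    record = GenomeRecord(contig_id, "".join(seq_parts), features)
    truth = pd.DataFrame(rows)
    return record, truth


def _dup(genes, g) -> bool:
    return sum(1 for other in genes if other.role == g.role) > 1


class _AncestorCache:
    """Ancestor worlds keyed by seed (profile calibration is the slow step)."""

    def __init__(self) -> None:
        self._cache: dict[int, dict[str, AncestorEntry]] = {}

    def get_or_make(self, seed: int) -> dict[str, AncestorEntry]:
        if seed not in self._cache:
            self._cache[seed] = make_ancestors(seed)
        return self._cache[seed]


_ANCESTOR_CACHE = _AncestorCache()


def exemplar_specs(
    rng_seed: int,
    per_class: int = 1,
    divergence: float = 0.1,
    classes: Sequence[int] = tuple(range(1, 15)),
) -> list[SyntheticSpec]:
    """One (or more) spec per class with per-locus derived seeds."""
    specs = []
    for c in classes:
        for r in range(per_class):
            specs.append(
                SyntheticSpec(
                    class_id=c,
                    rng_seed=(rng_seed * 1009 + c * 101 + r) % (2**31),
                    divergence=divergence,
                )
            )
    return specs


def hica_class_benchmark(
    rng_seed: int,
    n_classes: int = 10,
    n_per_class: int = 10,
    max_divergence: float = 0.25,
    class_ancestor_divergence: float = 0.45,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """HicA domain sequences emulating class-wise sequence clusters.

    Each class gets its own sub-ancestor (``class_ancestor_divergence``
    from the family ancestor); members diverge from their sub-ancestor by
    a per-site rate drawn uniformly from [0.05, max_divergence]. Returns
    (sequences, labels) for phylogenetic class-clustering analyses.
    """
    rng = np.random.default_rng(rng_seed)
    family = _random_protein(rng, ANCESTOR_LENGTHS["HicA_dsRBD"])
    seqs: list[tuple[str, str]] = []
    labels: dict[str, int] = {}
    for c in range(1, n_classes + 1):
        sub = mutate(family, class_ancestor_divergence, rng)
        for m in range(n_per_class):
            d = float(rng.uniform(0.05, max_divergence))
            name = f"c{c}_s{m}"
            seqs.append((name, mutate(sub, d, rng)))
            labels[name] = c
    return seqs, labels


def emit_bundle(
    record: GenomeRecord,
    truth: pd.DataFrame,
    out_dir: str | Path,
    ancestors: Optional[dict[str, AncestorEntry]] = None,
) -> None:
    """Write GenBank + GFF3 + FASTA + truth TSV (+ seed alignments)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genbank([record], out / "genome.gbk")
    write_gff_fasta([record], out / "genome.gff3", out / "genome.fna")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    if ancestors is not None:
        write_seed_alignments(ancestors, out / "seeds")
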