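"""The 14-class genetic-context classifier for HicA-domain loci.

Each focal HicA-bearing gene is assigned exactly one class (or left
unclassified) by rules evaluated in fixed precedence: fusions (14, 11, 12,
13) outrank pVip adjacency (9, 10), which outranks DBD-bearing bicistronic
operons (6, 5, 3, 4), long DBD-less HicBs (7, 8) and finally the
permissive small-HicB rules (1, 2). Every satisfied predicate is recorded
as evidence, so an assignment can be replayed and audited.

Class semantics (gene order is biological, relative to the hicA strand):
1/2 hicAB / hicBA with a small DBD-less HicB; 3/4 hicAB with a C-terminal
HTH / RHH DBD on HicB; 5/6 hicBA with an N-terminal Phd/YefM DBD on HicB
(6 when HicA carries the C-terminal Shared Domain); 7/8 hicBA with long
DBD-less HicBs; 9/10 hicA immediately upstream / downstream of a
prokaryotic Viperin gene; 11-13 fused monocistronic HicA-HicB
architectures; 14 the SMC-HicA fusion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Optional

import pandas as pd

from .annotations import GeneFeature, GenomeRecord, translate_cds
from .neighborhood import (
    LocusContext,
    build_context,
    coupling_flag,
    find_hica_loci,
)
from .profiles import (
    DBD_LABELS,
    DomainArchitecture,
    SeedProfile,
    assign_architecture,
    has_coiled_coil,
    scan_protein,
)


@dataclass
class ClassRuleConfig:
    """Tunable thresholds of the class rules (lengths in aa, gaps in nt).

    Length ranges are closed (endpoints included). The Class 1 and Class 8
    HicB ranges default to the union of the two ranges reported for those
    classes in the literature; all fields are configurable.
    """

    small_hicb_range_c1: tuple[int, int] = (60, 97)
    small_hicb_range_c2: tuple[int, int] = (63, 103)
    hicb_range_c7: tuple[int, int] = (216, 233)
    hicb_range_c8: tuple[int, int] = (331, 356)
    shared_domain_len: tuple[int, int] = (45, 70)
    fused_c12_max: int = 250
    fused_c13_range: tuple[int, int] = (340, 440)
    smc_min_len: int = 600
    pvip_max_gap: int = 300
    closely_linked_max_gap: int = 10

    def __post_init__(self) -> None:
        for name in (
            "small_hicb_range_c1",
            "small_hicb_range_c2",
            "hicb_range_c7",
            "hicb_range_c8",
            "shared_domain_len",
            "fused_c13_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lo {lo} > hi {hi}")

    @classmethod
    def from_toml(cls, path: str | Path) -> "ClassRuleConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        section = data.get("class_rules", data)
        kwargs = {}
        for key, value in section.items():
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


@dataclass
class ClassAssignment:
    """One classified locus with its evidence trail."""

    locus_id: str
    contig_id: str
    class_id: Optional[int]  # None = unclassified
    evidence: list[tuple[str, str]] = field(default_factory=list)
    flags: dict = field(default_factory=dict)
    focal_len: Optional[int] = None
    partner_id: Optional[str] = None
    partner_len: Optional[int] = None
    gap_nt: Optional[int] = None


def _in_range(x: int, rng: tuple[int, int]) -> bool:
    return rng[0] <= x <= rng[1]


def _coherent_partner(ctx: LocusContext, side: str):
    nb = ctx.partner(side)
    if nb is None or nb.feature.kind != "CDS":
        return None
    if nb.feature.strand != ctx.focal.strand:
        return None
    return nb


# --- predicates -----------------------------------------------------------
# Each predicate maps (ctx, config) -> (bool, observation). Evidence stores
# the predicate name + observation; replaying the named predicates against
# the context reproduces the class (see replay_evidence).

def _p_smc_fusion(ctx, cfg):
    arch = ctx.focal_architecture
    smc, hica = arch.first("SMC"), arch.first("HicA_dsRBD")
    plen = len(ctx.focal.protein or "")
    if smc is None or hica is None:
        return False, "no SMC+HicA architecture"
    big = plen >= cfg.smc_min_len or has_coiled_coil(ctx.focal.protein)
    ok = big and hica.start >= smc.end - 10
    return ok, f"SMC@{smc.start}-{smc.end};HicA@{hica.start}-{hica.end};len={plen}"


def _p_fusion_11(ctx, cfg):
    arch = ctx.focal_architecture
    hica, hicb = arch.first("HicA_dsRBD"), arch.first("HicB_pRNaseH")
    dbd = arch.first("DBD_HTH") or arch.first("DBD_RHH")
    if not (hica and hicb and dbd):
        return False, "missing HicA/HicB/DBD hit"
    ok = hica.start < hicb.start < dbd.start
    return ok, (
        f"HicA@{hica.start};HicB@{hicb.start};{dbd.domain_label}@{dbd.start}"
    )


def _p_fusion_12(ctx, cfg):
    arch = ctx.focal_architecture
    hica, hicb = arch.first("HicA_dsRBD"), arch.first("HicB_pRNaseH")
    plen = len(ctx.focal.protein or "")
    if not (hica and hicb):
        return False, "missing HicA/HicB hit"
    ok = hicb.start < hica.start and plen <= cfg.fused_c12_max
    return ok, f"HicB@{hicb.start};HicA@{hica.start};len={plen}"


def _p_fusion_13(ctx, cfg):
    arch = ctx.focal_architecture
    hica = arch.first("HicA_dsRBD")
    plen = len(ctx.focal.protein or "")
    if hica is None:
        return False, "no HicA hit"
    ok = _in_range(plen, cfg.fused_c13_range) and hica.end >= plen - 20
    return ok, f"len={plen};HicA@{hica.start}-{hica.end}"


def _pvip_adjacent(ctx, cfg, side):
    nb = _coherent_partner(ctx, side)
    if nb is None or nb.architecture is None:
        return False, f"no co-oriented {side} neighbor"
    ok = nb.architecture.has("pVip") and nb.gap_nt <= cfg.pvip_max_gap
    return ok, f"{side}={nb.feature.gene_id};gap={nb.gap_nt}"


def _p_pvip_down(ctx, cfg):
    return _pvip_adjacent(ctx, cfg, "downstream")


def _p_pvip_up(ctx, cfg):
    return _pvip_adjacent(ctx, cfg, "upstream")


def _p_upstream_phd_hicb(ctx, cfg):
    nb = _coherent_partner(ctx, "upstream")
    if nb is None or nb.architecture is None:
        return False, "no co-oriented upstream neighbor"
    hicb = nb.architecture.first("HicB_pRNaseH")
    phd = nb.architecture.first("DBD_PhdYefM")
    if not (hicb and phd):
        return False, f"{nb.feature.gene_id}: no HicB+Phd/YefM"
    ok = phd.start < hicb.start  # DBD N-terminal
    return ok, f"{nb.feature.gene_id}:Phd@{phd.start};HicB@{hicb.start};gap={nb.gap_nt}"


def _p_shared_domain(ctx, cfg):
    arch = ctx.focal_architecture
    hica, sd = arch.first("HicA_dsRBD"), arch.first("SharedDomain")
    if not (hica and sd):
        return False, "no SharedDomain hit"
    ok = sd.start >= hica.end - 10  # C-terminal to the dsRBD
    return ok, f"HicA@{hica.start}-{hica.end};Shared@{sd.start}-{sd.end}"


def _downstream_dbd_hicb(ctx, cfg, dbd_label):
    nb = _coherent_partner(ctx, "downstream")
    if nb is None or nb.architecture is None:
        return False, "no co-oriented downstream neighbor"
    hicb = nb.architecture.first("HicB_pRNaseH")
    dbd = nb.architecture.first(dbd_label)
    if not (hicb and dbd):
        return False, f"{nb.feature.gene_id}: no HicB+{dbd_label}"
    ok = dbd.start > hicb.start  # DBD C-terminal
    return ok, f"{nb.feature.gene_id}:HicB@{hicb.start};{dbd_label}@{dbd.start};gap={nb.gap_nt}"


def _p_down_hth(ctx, cfg):
    return _downstream_dbd_hicb(ctx, cfg, "DBD_HTH")


def _p_down_rhh(ctx, cfg):
    return _downstream_dbd_hicb(ctx, cfg, "DBD_RHH")


def _dbdless_partner(ctx, cfg, side, length_range, require_hicb_core=False):
    nb = _coherent_partner(ctx, side)
    if nb is None or not nb.feature.protein:
        return False, f"no co-oriented {side} neighbor"
    if nb.architecture is not None and nb.architecture.has_dbd():
        return False, f"{nb.feature.gene_id} has a DBD"
    if nb.architecture is not None and nb.architecture.has("HicA_dsRBD"):
        return False, f"{nb.feature.gene_id} is itself a HicA gene"
    if require_hicb_core and (
        nb.architecture is None or not nb.architecture.has("HicB_pRNaseH")
    ):
        return False, f"{nb.feature.gene_id}: no HicB core hit"
    n = len(nb.feature.protein)
    ok = _in_range(n, length_range)
    core = ";HicB_core" if require_hicb_core else ""
    return ok, f"{nb.feature.gene_id}:len={n};gap={nb.gap_nt}{core}"


def _p_c7_hicb(ctx, cfg):
    return _dbdless_partner(ctx, cfg, "upstream", cfg.hicb_range_c7)


def _p_c8_hicb(ctx, cfg):
    return _dbdless_partner(ctx, cfg, "upstream", cfg.hicb_range_c8)


def _p_c1_hicb_core(ctx, cfg):
    return _dbdless_partner(ctx, cfg, "downstream", cfg.small_hicb_range_c1, True)


def _p_c2_hicb_core(ctx, cfg):
    return _dbdless_partner(ctx, cfg, "upstream", cfg.small_hicb_range_c2, True)


def _p_c1_hicb(ctx, cfg):
    return _dbdless_partner(ctx, cfg, "downstream", cfg.small_hicb_range_c1)


def _p_c2_hicb(ctx, cfg):
    return _dbdless_partner(ctx, cfg, "upstream", cfg.small_hicb_range_c2)


_PREDICATES: dict[str, Callable] = {
    "focal_smc_hica_fusion": _p_smc_fusion,
    "focal_hica_hicb_dbd_fusion": _p_fusion_11,
    "focal_hicb_hica_fusion_small": _p_fusion_12,
    "focal_cterm_hica_large_fusion": _p_fusion_13,
    "pvip_adjacent_downstream": _p_pvip_down,
    "pvip_adjacent_upstream": _p_pvip_up,
    "upstream_hicb_with_nterm_phdyefm": _p_upstream_phd_hicb,
    "focal_cterm_shared_domain": _p_shared_domain,
    "downstream_hicb_with_cterm_hth": _p_down_hth,
    "downstream_hicb_with_cterm_rhh": _p_down_rhh,
    "upstream_long_dbdless_hicb_c7": _p_c7_hicb,
    "upstream_long_dbdless_hicb_c8": _p_c8_hicb,
    "downstream_small_hicb_with_core": _p_c1_hicb_core,
    "upstream_small_hicb_with_core": _p_c2_hicb_core,
    "downstream_small_dbdless_hicb": _p_c1_hicb,
    "upstream_small_dbdless_hicb": _p_c2_hicb,
}

#: fixed precedence: (class_id, [predicate names that must all hold])
RULE_PRECEDENCE: list[tuple[int, list[str]]] = [
    (14, ["focal_smc_hica_fusion"]),
    (11, ["focal_hica_hicb_dbd_fusion"]),
    (12, ["focal_hicb_hica_fusion_small"]),
    (13, ["focal_cterm_hica_large_fusion"]),
    (9, ["pvip_adjacent_downstream"]),
    (10, ["pvip_adjacent_upstream"]),
    (6, ["upstream_hicb_with_nterm_phdyefm", "focal_cterm_shared_domain"]),
    (5, ["upstream_hicb_with_nterm_phdyefm"]),
    (3, ["downstream_hicb_with_cterm_hth"]),
    (4, ["downstream_hicb_with_cterm_rhh"]),
    (7, ["upstream_long_dbdless_hicb_c7"]),
    (8, ["upstream_long_dbdless_hicb_c8"]),
    # a partner with a detectable HicB core outranks a size-only match,
    # so an unrelated small neighbor cannot shadow the true antitoxin
    (1, ["downstream_small_hicb_with_core"]),
    (2, ["upstream_small_hicb_with_core"]),
    (1, ["downstream_small_dbdless_hicb"]),
    (2, ["upstream_small_dbdless_hicb"]),
]

#: the partner side each bicistronic class reads its HicB/pVip from
_PARTNER_SIDE = {
    1: "downstream", 2: "upstream", 3: "downstream", 4: "downstream",
    5: "upstream", 6: "upstream", 7: "upstream", 8: "upstream",
    9: "downstream", 10: "upstream",
}


def classify_locus(ctx: LocusContext, config: Optional[ClassRuleConfig] = None) -> ClassAssignment:
    """Assign the first rule (in precedence order) whose predicates all
    hold; record every satisfied predicate as evidence."""
    cfg = config or ClassRuleConfig()
    assignment = ClassAssignment(
        locus_id=ctx.focal.gene_id,
        contig_id=ctx.contig_id,
        class_id=None,
        focal_len=len(ctx.focal.protein) if ctx.focal.protein else None,
    )
    for class_id, pred_names in RULE_PRECEDENCE:
        results = [(name, _PREDICATES[name](ctx, cfg)) for name in pred_names]
        if all(ok for _, (ok, _) in results):
            assignment.class_id = class_id
            assignment.evidence = [(name, obs) for name, (ok, obs) in results]
            break
    side = _PARTNER_SIDE.get(assignment.class_id) if assignment.class_id else None
    flags = {"closely_linked": False, "overlapping": False, "pseudogene_candidate": False}
    if side is not None:
        nb = _coherent_partner(ctx, side)
        if nb is not None:
            assignment.partner_id = nb.feature.gene_id
            assignment.partner_len = len(nb.feature.protein) if nb.feature.protein else None
            assignment.gap_nt = nb.gap_nt
            state = coupling_flag(nb.gap_nt, cfg.closely_linked_max_gap)
            flags["closely_linked"] = state == "closely_linked"
            flags["overlapping"] = state == "overlapping"
    assignment.flags = flags
    return assignment


def replay_evidence(
    assignment: ClassAssignment, ctx: LocusContext, config: Optional[ClassRuleConfig] = None
) -> Optional[int]:
    """Re-evaluate the recorded predicates; returns the class they entail.

    Raises if any recorded predicate no longer holds (audit failure).
    """
    cfg = config or ClassRuleConfig()
    for name, _ in assignment.evidence:
        ok, obs = _PREDICATES[name](ctx, cfg)
        if not ok:
            raise AssertionError(f"evidence predicate {name} does not hold: {obs}")
    names = [name for name, _ in assignment.evidence]
    for class_id, pred_names in RULE_PRECEDENCE:
        if pred_names == names:
            return class_id
    return None


# ---------------------------------------------------------------------------
# pseudogene screen


def pseudogene_screen(
    record: GenomeRecord,
    hicb: GeneFeature,
    profiles: dict[str, SeedProfile],
    reference_hicbs: Optional[list[tuple[str, bool]]] = None,
    readthrough_nt: int = 300,
) -> bool:
    """Is a candidate Class 1/2 HicB a degraded DBD-bearing HicB?

    True if (a) in-frame read-through translation past the stop codon
    (up to ``readthrough_nt`` nt) scores above threshold against an HTH or
    RHH profile, or (b) a supplied reference HicB known to carry a DBD
    matches the candidate at >= 95% identity over its full length.
    """
    # (a) read-through
    if hicb.strand == "+":
        lo = hicb.end
        hi = min(len(record.sequence), hicb.end + readthrough_nt)
        ext = record.sequence[lo : lo + (hi - lo) // 3 * 3]
    else:
        hi = hicb.start
        lo = max(0, hicb.start - readthrough_nt)
        span = (hi - lo) // 3 * 3
        ext = record.sequence[hi - span : hi]
    if len(ext) < 30:
        warnings.warn(
            f"{hicb.gene_id}: read-through region truncated at contig end; "
            "screen (a) skipped"
        )
    else:
        from Bio.Seq import Seq

        seq = Seq(ext)
        if hicb.strand == "-":
            seq = seq.reverse_complement()
        readthrough = str(seq.translate(table=11))
        for label in ("DBD_HTH", "DBD_RHH"):
            prof = profiles.get(label)
            if prof is None:
                continue
            if scan_protein(readthrough, prof, protein_id=hicb.gene_id):
                return True
    # (b) reference identity
    if reference_hicbs and hicb.protein:
        from .phylogeny import global_align

        for ref_protein, has_dbd in reference_hicbs:
            if not has_dbd:
                continue
            _, _, matches = global_align(hicb.protein, ref_protein, return_matches=True)
            if matches / len(hicb.protein) >= 0.95:
                return True
    return False


# ---------------------------------------------------------------------------
# genome-level driver


def compute_architectures(
    record: GenomeRecord,
    profiles: dict[str, SeedProfile],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> dict[str, DomainArchitecture]:
    """Scan every CDS protein against every profile and resolve overlaps."""
    out: dict[str, DomainArchitecture] = {}
    for f in record.features:
        if not f.protein:
            continue
        hits = []
        for prof in profiles.values():
            hits.extend(
                scan_protein(f.protein, prof, gap_open, gap_extend, protein_id=f.gene_id)
            )
        out[f.gene_id] = assign_architecture(f.gene_id, hits)
    return out


def _rele_pvip_gene_ids(
    record: GenomeRecord, architectures: dict[str, DomainArchitecture], max_gap: int
) -> set[str]:
    """Gene ids participating in an adjacent co-oriented RelE-pVip pair."""
    out: set[str] = set()
    feats = [f for f in record.features if f.kind == "CDS"]
    for a, b in zip(feats, feats[1:]):
        if a.strand != b.strand or b.start - a.end > max_gap:
            continue
        la = architectures.get(a.gene_id)
        lb = architectures.get(b.gene_id)
        if la is None or lb is None:
            continue
        if (la.has("RelE") and lb.has("pVip")) or (la.has("pVip") and lb.has("RelE")):
            out.update((a.gene_id, b.gene_id))
    return out


def classify_genome(
    records: Iterable[GenomeRecord],
    profiles: dict[str, SeedProfile],
    config: Optional[ClassRuleConfig] = None,
    window_genes: int = 5,
    reference_hicbs: Optional[list[tuple[str, bool]]] = None,
    run_pseudogene_screen: bool = True,
) -> tuple[pd.DataFrame, list[ClassAssignment], list[LocusContext]]:
    """Classify every HicA-domain locus in a set of contigs.

    Returns (table, assignments, contexts); the table has one row per
    focal gene, never silently dropping unclassified loci. Candidate
    Class 1/2 loci are screened for pseudogenized DBD-bearing HicBs and
    flagged (not dropped). The auxiliary ``rele_pvip_nearby`` column marks
    loci whose context window contains an adjacent co-oriented
    RelE-pVip gene pair (an association, not a class).
    """
    cfg = config or ClassRuleConfig()
    rows = []
    assignments: list[ClassAssignment] = []
    contexts: list[LocusContext] = []
    for record in records:
        arch = compute_architectures(record, profiles)
        pair_ids = _rele_pvip_gene_ids(record, arch, cfg.pvip_max_gap)
        for focal in find_hica_loci(record, arch):
            ctx = build_context(record, focal, arch, window_genes)
            window_ids = {
                nb.feature.gene_id for nb in ctx.upstream + ctx.downstream
            } | {focal.gene_id}
            rele_pvip = bool(pair_ids & window_ids)
            assignment = classify_locus(ctx, cfg)
            if (
                run_pseudogene_screen
                and assignment.class_id in (1, 2)
                and assignment.partner_id is not None
            ):
                partner_feat = next(
                    f for f in record.features if f.gene_id == assignment.partner_id
                )
                if pseudogene_screen(record, partner_feat, profiles, reference_hicbs):
                    assignment.flags["pseudogene_candidate"] = True
            assignments.append(assignment)
            contexts.append(ctx)
            rows.append(
                {
                    "locus_id": assignment.locus_id,
                    "contig": assignment.contig_id,
                    "class_id": assignment.class_id if assignment.class_id else "unclassified",
                    "focal_len": assignment.focal_len,
                    "partner_id": assignment.partner_id,
                    "partner_len": assignment.partner_len,
                    "gap_nt": assignment.gap_nt,
                    "closely_linked": assignment.flags["closely_linked"],
                    "overlapping": assignment.flags["overlapping"],
                    "pseudogene_candidate": assignment.flags["pseudogene_candidate"],
                    "rele_pvip_nearby": rele_pvip,
                    "evidence": ";".join(f"{n}[{o}]" for n, o in assignment.evidence),
                }
            )
    columns = [
        "locus_id", "contig", "class_id", "focal_len", "partner_id", "partner_len",
        "gap_nt", "closely_linked", "overlapping", "pseudogene_candidate",
        "rele_pvip_nearby", "evidence",
    ]
    return pd.DataFrame(rows, columns=columns), assignments, contexts


def write_evidence_json(assignments: Iterable[ClassAssignment], path: str | Path) -> None:
    payload = [asdict(a) for a in assignments]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
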