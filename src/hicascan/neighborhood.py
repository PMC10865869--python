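"""Gene-neighborhood extraction around HicA-domain loci.

Upstream/downstream are biological: relative to the focal gene's strand,
so classification is invariant under reverse-complementing a contig.
Neighbor gaps are chain gaps — each neighbor's ``gap_nt`` is the
intergenic distance to the next gene toward the focal gene (rank 1 is the
gap to the focal gene itself); negative gaps are overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .annotations import GeneFeature, GenomeRecord
from .profiles import DomainArchitecture


class NeighborhoodError(ValueError):
    pass


@dataclass
class Neighbor:
    feature: GeneFeature
    architecture: Optional[DomainArchitecture]
    gap_nt: int
    rank: int  # 1 = adjacent to focal

    @property
    def length_aa(self) -> Optional[int]:
        return len(self.feature.protein) if self.feature.protein else None


@dataclass
class LocusContext:
    """A focal HicA-bearing gene plus its flanking genes."""

    contig_id: str
    focal: GeneFeature
    focal_architecture: DomainArchitecture
    upstream: list[Neighbor] = field(default_factory=list)
    downstream: list[Neighbor] = field(default_factory=list)
    window_genes: int = 5

    def partner(self, side: str) -> Optional[Neighbor]:
        """Rank-1 neighbor on a side ('upstream'/'downstream'), if any."""
        lst = self.upstream if side == "upstream" else self.downstream
        return lst[0] if lst else None


def intergenic_gap(
    a: GeneFeature,
    b: GeneFeature,
    contig_a: Optional[str] = None,
    contig_b: Optional[str] = None,
) -> int:
    """Nucleotides between two genes with ``a.start <= b.start``.

    Negative values are overlap lengths; 0 means abutting.
    """
    if contig_a is not None and contig_b is not None and contig_a != contig_b:
        raise NeighborhoodError(
            f"genes on different contigs: {contig_a!r} vs {contig_b!r}"
        )
    if a.start > b.start:
        raise NeighborhoodError("intergenic_gap requires a.start <= b.start")
    return b.start - a.end


def coupling_flag(gap: int, max_gap: int = 10) -> str:
    """Partition a gap into overlapping / closely_linked / distal.

    ``closely_linked`` is inclusive at both ends: 0 <= gap <= max_gap.
    """
    if gap < 0:
        return "overlapping"
    if gap <= max_gap:
        return "closely_linked"
    return "distal"


def find_hica_loci(
    record: GenomeRecord, architectures: dict[str, DomainArchitecture]
) -> list[GeneFeature]:
    """Every intact CDS whose architecture has a HicA_dsRBD hit, in contig
    order. Pseudogene features are never focal."""
    out = []
    for f in record.features:
        if f.kind != "CDS":
            continue
        arch = architectures.get(f.gene_id)
        if arch is not None and arch.has("HicA_dsRBD"):
            out.append(f)
    return out


def build_context(
    record: GenomeRecord,
    focal: GeneFeature,
    architectures: dict[str, DomainArchitecture],
    window_genes: int = 5,
) -> LocusContext:
    """Collect up to ``window_genes`` neighbors per side with chain gaps."""
    feats = record.features
    try:
        idx = next(i for i, f in enumerate(feats) if f is focal or f.gene_id == focal.gene_id)
    except StopIteration:
        raise NeighborhoodError(f"focal {focal.gene_id} not in record {record.contig_id}")

    def chain(indices: list[int]) -> list[Neighbor]:
        out = []
        prev = feats[idx]
        for rank, i in enumerate(indices, 1):
            nb = feats[i]
            left, right = (prev, nb) if prev.start <= nb.start else (nb, prev)
            gap = intergenic_gap(left, right)
            out.append(Neighbor(nb, architectures.get(nb.gene_id), gap, rank))
            prev = nb
        return out

    left = list(range(idx - 1, max(-1, idx - 1 - window_genes), -1))
    right = list(range(idx + 1, min(len(feats), idx + 1 + window_genes)))
    if focal.strand == "+":
        upstream, downstream = chain(left), chain(right)
    else:
        upstream, downstream = chain(right), chain(left)
    return LocusContext(
        record.contig_id, focal, architectures[focal.gene_id], upstream, downstream, window_genes
    )


def write_neighborhood_tsv(contexts: Iterable[LocusContext], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tfocal_id\tneighbor_id\tside\trank\tgap_nt\tstrand\tlabels\n")
        for ctx in contexts:
            for side, lst in (("upstream", ctx.upstream), ("downstream", ctx.downstream)):
                for nb in lst:
                    labels = ",".join(nb.architecture.labels()) if nb.architecture else ""
                    fh.write(
                        f"{ctx.contig_id}\t{ctx.focal.gene_id}\t{nb.feature.gene_id}\t"
                        f"{side}\t{nb.rank}\t{nb.gap_nt}\t{nb.feature.strand}\t{labels}\n"
                    )
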