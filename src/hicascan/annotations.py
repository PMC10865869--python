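"""Genome annotation I/O with a single internal coordinate convention.

All in-memory intervals are 0-based half-open ``[start, end)``; GenBank and
GFF3 use 1-based inclusive coordinates and are converted at the boundary.
Stored protein sequences exclude the terminal stop codon, so an intact CDS
satisfies ``end - start == 3 * (len(protein) + 1)``.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

TRANSLATION_TABLE = 11
_START_CODONS = {"ATG", "GTG", "TTG"}


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class GeneFeature:
    """One gene on a contig, in internal 0-based half-open coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str = "CDS"  # 'CDS', 'pseudo' or 'other'
    protein: Optional[str] = None
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"feature {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"feature {self.gene_id}: strand must be '+' or '-'")

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A contig: DNA sequence plus ordered, stranded gene features."""

    contig_id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise AnnotationError("contig_id must be non-empty")
        self.features.sort(key=lambda f: (f.start, f.end, f.gene_id))
        for f in self.features:
            if f.start < 0 or f.end > len(self.sequence):
                raise AnnotationError(
                    f"feature {f.gene_id} [{f.start},{f.end}) outside contig "
                    f"{self.contig_id} of length {len(self.sequence)}"
                )

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]


def translate_cds(record: GenomeRecord, feature: GeneFeature, *, partial: bool = False) -> str:
    """Translate a CDS with table 11 (strand-aware).

    The terminal stop codon is stripped; internal stops render as ``'*'``
    so read-through screens can see them. ATG/GTG/TTG starts all yield M at
    position 1. With ``partial=True`` a trailing sub-codon remainder is
    ignored instead of raising.
    """
    nt = record.sequence[feature.start : feature.end]
    seq = Seq(nt)
    if feature.strand == "-":
        seq = seq.reverse_complement()
    rem = len(seq) % 3
    if rem:
        if not partial:
            raise AnnotationError(
                f"CDS {feature.gene_id} length {len(seq)} not divisible by 3 "
                "(pass partial=True to truncate)"
            )
        seq = seq[: len(seq) - rem]
    prot = str(seq.translate(table=TRANSLATION_TABLE))
    if prot.endswith("*"):
        prot = prot[:-1]
    first = str(seq[:3]).upper()
    if prot and first in _START_CODONS:
        prot = "M" + prot[1:]
    return prot


# ---------------------------------------------------------------------------
# GenBank


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Read a GenBank flat file into GenomeRecords.

    CDS features with a /translation qualifier keep it verbatim; CDS
    without one are translated from the (spliced, strand-corrected) DNA.
    Features flagged /pseudo are retained with kind='pseudo'.
    """
    records: list[GenomeRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise AnnotationError(f"malformed GenBank file {path}: {exc}") from exc
    for rec in parsed:
        feats: list[GeneFeature] = []
        for i, sf in enumerate(rec.features):
            if sf.type not in ("CDS", "gene"):
                continue
            if sf.type == "gene" and any(
                other.type == "CDS"
                and int(other.location.start) == int(sf.location.start)
                and int(other.location.end) == int(sf.location.end)
                for other in rec.features
            ):
                continue  # gene/CDS twins: keep the CDS
            start, end = int(sf.location.start), int(sf.location.end)
            if start < 0 or end > len(rec.seq):
                raise AnnotationError(
                    f"{rec.id}: feature at {start}..{end} outside sequence"
                )
            strand = "-" if sf.location.strand == -1 else "+"
            pseudo = "pseudo" in sf.qualifiers or "pseudogene" in sf.qualifiers
            kind = "pseudo" if pseudo else ("CDS" if sf.type == "CDS" else "other")
            gene_id = (
                sf.qualifiers.get("locus_tag", [None])[0]
                or sf.qualifiers.get("gene", [None])[0]
                or sf.qualifiers.get("protein_id", [None])[0]
                or f"{rec.id}_f{i}"
            )
            protein = None
            if kind == "CDS":
                if "translation" in sf.qualifiers:
                    protein = sf.qualifiers["translation"][0]
                else:
                    spliced = sf.location.extract(rec.seq)
                    rem = len(spliced) % 3
                    if rem:
                        spliced = spliced[: len(spliced) - rem]
                    prot = str(spliced.translate(table=TRANSLATION_TABLE))
                    if prot.endswith("*"):
                        prot = prot[:-1]
                    if prot and str(spliced[:3]).upper() in _START_CODONS:
                        prot = "M" + prot[1:]
                    protein = prot
            feats.append(
                GeneFeature(
                    gene_id=gene_id,
                    start=start,
                    end=end,
                    strand=strand,
                    kind=kind,
                    protein=protein,
                    product=sf.qualifiers.get("product", [None])[0],
                )
            )
        records.append(GenomeRecord(rec.id, str(rec.seq).upper(), feats))
    return records


def write_genbank(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write GenomeRecords as a GenBank flat file (deterministic output)."""
    seqrecs = []
    for rec in records:
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.contig_id,
            name=rec.contig_id[:16],
            description="synthetic contig",
        )
        sr.annotations["molecule_type"] = "DNA"
        sr.annotations["topology"] = "linear"
        for f in rec.features:
            quals: dict[str, list[str]] = {"locus_tag": [f.gene_id]}
            if f.product:
                quals["product"] = [f.product]
            if f.kind == "pseudo":
                quals["pseudo"] = [""]
            if f.protein is not None:
                quals["translation"] = [f.protein]
            sf = SeqFeature(
                SimpleLocation(f.start, f.end, strand=-1 if f.strand == "-" else 1),
                type="CDS" if f.kind in ("CDS", "pseudo") else "misc_feature",
                qualifiers=quals,
            )
            sr.features.append(sf)
        seqrecs.append(sr)
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "genbank")


# ---------------------------------------------------------------------------
# GFF3 + FASTA


def write_gff_fasta(
    records: Iterable[GenomeRecord], gff_path: str | Path, fasta_path: str | Path
) -> None:
    """Emit GFF3 (1-based inclusive) plus the contig FASTA.

    Each CDS line carries ID=, kind=, and translation_length= attributes
    (and product= when set) so the feature table round-trips exactly.
    """
    records = list(records)
    with open(gff_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for rec in records:
            gff.write(f"##sequence-region {rec.contig_id} 1 {len(rec.sequence)}\n")
            for f in rec.features:
                attrs = [f"ID={f.gene_id}", f"kind={f.kind}"]
                if f.product:
                    attrs.append(f"product={f.product}")
                if f.protein is not None:
                    attrs.append(f"translation_length={len(f.protein)}")
                gff.write(
                    "\t".join(
                        [
                            rec.contig_id,
                            "hicascan",
                            "CDS" if f.kind in ("CDS", "pseudo") else "region",
                            str(f.start + 1),
                            str(f.end),
                            ".",
                            f.strand,
                            "0",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
    with open(fasta_path, "w") as fa:
        for rec in records:
            fa.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fa.write(rec.sequence[i : i + 70] + "\n")


def read_gff_fasta(gff: str | Path, fasta: str | Path) -> list[GenomeRecord]:
    """Read a GFF3 + FASTA pair.

    CDS features without an explicit protein are translated with table 11.
    A GFF seqid missing from the FASTA is an error listing the missing ids.
    """
    seqs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta), "fasta")}
    try:
        db = gffutils.create_db(
            str(gff), dbfn=":memory:", from_string=False, force=True,
            keep_order=True, merge_strategy="create_unique",
        )
        all_features = list(db.all_features())
    except gffutils.exceptions.EmptyInputError:
        all_features = []
    by_contig: dict[str, list[GeneFeature]] = {}
    missing = set()
    for gf in all_features:
        if gf.featuretype not in ("CDS", "region"):
            continue
        if gf.seqid not in seqs:
            missing.add(gf.seqid)
            continue
        kind = gf.attributes.get("kind", ["CDS" if gf.featuretype == "CDS" else "other"])[0]
        feat = GeneFeature(
            gene_id=gf.attributes.get("ID", [gf.id])[0],
            start=gf.start - 1,
            end=gf.end,
            strand="-" if gf.strand == "-" else "+",
            kind=kind,
            product=gf.attributes.get("product", [None])[0],
        )
        by_contig.setdefault(gf.seqid, []).append(feat)
    if missing:
        raise AnnotationError(
            "GFF seqids absent from FASTA: " + ", ".join(sorted(missing))
        )
    out = []
    for cid, seq in seqs.items():
        rec = GenomeRecord(cid, seq, by_contig.get(cid, []))
        for f in rec.features:
            if f.kind == "CDS" and f.protein is None:
                f.protein = translate_cds(rec, f, partial=True)
        out.append(rec)
    return out


def write_protein_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Export every CDS protein as FASTA (ids are gene ids)."""
    with open(path, "w") as fh:
        for rec in records:
            for f in rec.cds_features():
                if f.protein:
                    fh.write(f">{f.gene_id} {rec.contig_id}\n{f.protein}\n")
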