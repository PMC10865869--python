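"""Per-class summary statistics of classified HicA loci.

Counts, protein-length ranges and linkage fractions per class, with an
optional redundancy filter that keeps only loci whose HicA domain protein
is < 95% identical to any already-kept HicA (greedy, by locus id).
Pseudogene-flagged loci are discarded from class counts and tallied
separately.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .classify import ClassAssignment


@dataclass
class ClassSummary:
    class_id: object  # 1..14 or 'unclassified'
    n_loci: int = 0
    hica_len_min: Optional[int] = None
    hica_len_max: Optional[int] = None
    hicb_len_min: Optional[int] = None
    hicb_len_max: Optional[int] = None
    n_closely_linked: int = 0
    n_overlapping: int = 0
    pct_closely_linked: float = 0.0
    n_pseudogene_discarded: int = 0

    @property
    def pct_display(self) -> int:
        """Rounded integer percentage (reports print '31%'-style values)."""
        return round(self.pct_closely_linked)


def _identity_over_shorter(a: str, b: str) -> float:
    from .phylogeny import global_align

    _, _, matches = global_align(a, b, return_matches=True)
    return matches / min(len(a), len(b))


def redundancy_filter(
    hica_seqs: dict[str, str], threshold: float = 0.95
) -> set[str]:
    """Greedy non-redundant locus set: visit loci by id, keep a locus iff
    its HicA is < threshold identical to every kept HicA."""
    kept: list[str] = []
    for locus_id in sorted(hica_seqs):
        seq = hica_seqs[locus_id]
        if all(_identity_over_shorter(seq, hica_seqs[k]) < threshold for k in kept):
            kept.append(locus_id)
    return set(kept)


def summarize(
    assignments: Iterable[ClassAssignment],
    hica_seqs: Optional[dict[str, str]] = None,
    redundancy: bool = False,
) -> dict[object, ClassSummary]:
    """Per-class counts, length ranges and linkage fractions.

    ``pct_closely_linked`` is 100 * n_closely_linked / n_loci at full
    precision (display rounds it). With ``redundancy=True`` (requires
    ``hica_seqs`` keyed by locus id), near-identical HicAs are collapsed
    before counting.
    """
    assignments = list(assignments)
    keep: Optional[set[str]] = None
    if redundancy:
        if hica_seqs is None:
            raise ValueError("redundancy=True requires hica_seqs")
        keep = redundancy_filter(hica_seqs)
    out: dict[object, ClassSummary] = {}
    for a in assignments:
        key = a.class_id if a.class_id is not None else "unclassified"
        s = out.setdefault(key, ClassSummary(class_id=key))
        if a.flags.get("pseudogene_candidate"):
            s.n_pseudogene_discarded += 1
            continue
        if keep is not None and a.locus_id not in keep:
            continue
        s.n_loci += 1
        if a.focal_len is not None:
            s.hica_len_min = min(s.hica_len_min or a.focal_len, a.focal_len)
            s.hica_len_max = max(s.hica_len_max or a.focal_len, a.focal_len)
        if a.partner_len is not None:
            s.hicb_len_min = min(s.hicb_len_min or a.partner_len, a.partner_len)
            s.hicb_len_max = max(s.hicb_len_max or a.partner_len, a.partner_len)
        if a.flags.get("closely_linked"):
            s.n_closely_linked += 1
        if a.flags.get("overlapping"):
            s.n_overlapping += 1
    for s in out.values():
        if s.n_loci:
            s.pct_closely_linked = 100.0 * s.n_closely_linked / s.n_loci
    return out


def write_summary_tsv(summaries: dict[object, ClassSummary], path: str | Path) -> None:
    rows = [asdict(s) | {"pct_display": s.pct_display} for s in summaries.values()]
    df = pd.DataFrame(rows).sort_values("class_id", key=lambda c: c.astype(str))
    df.to_csv(path, sep="\t", index=False)


def write_summary_json(summaries: dict[object, ClassSummary], path: str | Path) -> None:
    payload = {str(k): asdict(s) for k, s in sorted(summaries.items(), key=lambda kv: str(kv[0]))}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_class_sheets(
    table: pd.DataFrame, out_dir: str | Path, prefix: str = "class"
) -> None:
    """One TSV per class (sheet-per-class layout: locus, lengths, gap, flags)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for class_id, group in table.groupby("class_id"):
        group.to_csv(out / f"{prefix}_{class_id}.tsv", sep="\t", index=False)
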