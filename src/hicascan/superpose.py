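"""Rigid-body superposition of CA coordinate sets with pair pruning.

Least-squares superposition (Kabsch, reflections excluded) of two
index-paired coordinate sets, optionally iterating: re-fit on the kept
pairs and drop pairs whose residual distance exceeds a cutoff until
convergence. The RMSD over the kept ("pruned") pairs is the quantity
structure-comparison figures typically report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np


class SuperpositionError(ValueError):
    pass


@dataclass
class CoordinateSet:
    """CA coordinates (Angstrom) with residue labels."""

    labels: list[str]
    coords: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise SuperpositionError("coords must be (n, 3)")
        if len(self.labels) != len(self.coords):
            raise SuperpositionError("labels/coords length mismatch")
        if len(self.coords) < 3:
            raise SuperpositionError("need >= 3 coordinates")
        if not np.all(np.isfinite(self.coords)):
            raise SuperpositionError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3,3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float
    kept_pairs: int
    pruned_labels: list[str] = field(default_factory=list)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(X: CoordinateSet, Y: CoordinateSet) -> SuperpositionResult:
    """Least-squares rotation+translation of X onto Y (paired by index).

    Reflections are excluded (det(R) = +1); degenerate (e.g. collinear)
    inputs warn but still return the best proper rotation.
    """
    if len(X) != len(Y):
        raise SuperpositionError("coordinate sets must have equal size")
    x = X.coords
    y = Y.coords
    cx, cy = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - cx, y - cy
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    if s[1] < 1e-10 * max(s[0], 1.0):
        warnings.warn("degenerate (collinear or coincident) coordinates")
    corr = np.diag([1.0, 1.0, sign])
    rotation = vt.T @ corr @ u.T
    translation = cy - rotation @ cx
    diff = (x @ rotation.T + translation) - y
    rmsd = float(np.sqrt((diff**2).sum() / len(x)))
    return SuperpositionResult(rotation, translation, rmsd, kept_pairs=len(x))


def prune_superpose(
    X: CoordinateSet,
    Y: CoordinateSet,
    cutoff: float = 2.0,
    max_iter: int = 50,
) -> SuperpositionResult:
    """Iterative superposition with pair pruning.

    Repeats {fit on kept pairs; drop pairs with residual > cutoff} until
    no pair is dropped or ``max_iter``; never prunes below 3 pairs
    (stops with a warning instead). RMSD is over the kept pairs.
    """
    if len(X) != len(Y):
        raise SuperpositionError("coordinate sets must have equal size")
    if len(X) < 4:
        raise SuperpositionError("pruning needs >= 4 pairs")
    keep = np.ones(len(X), dtype=bool)
    result: Optional[SuperpositionResult] = None
    for _ in range(max_iter):
        xs = CoordinateSet([X.labels[i] for i in np.flatnonzero(keep)], X.coords[keep])
        ys = CoordinateSet([Y.labels[i] for i in np.flatnonzero(keep)], Y.coords[keep])
        result = kabsch(xs, ys)
        dist = np.linalg.norm(result.transform(X.coords) - Y.coords, axis=1)
        drop = keep & (dist > cutoff)
        if not drop.any():
            break
        if keep.sum() - drop.sum() < 3:
            # drop worst pairs only down to the 3-pair floor
            droppable = int(keep.sum()) - 3
            if droppable <= 0:
                warnings.warn("pruning stopped: would leave < 3 pairs")
                break
            order = np.argsort(-dist * keep)
            drop = np.zeros_like(keep)
            drop[order[:droppable]] = True
            warnings.warn("pruning floored at 3 kept pairs")
        keep &= ~drop
    assert result is not None
    result.kept_pairs = int(keep.sum())
    result.pruned_labels = [X.labels[i] for i in np.flatnonzero(~keep)]
    # final rmsd over kept pairs
    dist = np.linalg.norm(result.transform(X.coords) - Y.coords, axis=1)
    result.rmsd = float(np.sqrt((dist[keep] ** 2).mean()))
    return result


def read_ca_coords(pdb: str | Path, chain: str) -> CoordinateSet:
    """CA atoms of one chain from a PDB file, in residue order.

    Altloc 'A' (or blank) is preferred; insertion codes are kept in the
    labels ("<resseq><icode>").
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if chain not in chains:
        raise SuperpositionError(
            f"chain {chain!r} not found; available: {sorted(chains)}"
        )
    labels = []
    coords = []
    for residue in chains[chain].get_residues():
        ca = None
        for atom in residue.get_atoms():
            if atom.get_name() != "CA":
                continue
            alt = atom.get_altloc()
            if ca is None or alt in (" ", "A"):
                ca = atom
            if alt in (" ", "A"):
                break
        if ca is None:
            continue
        _, resseq, icode = residue.get_id()
        labels.append(f"{resseq}{icode.strip()}")
        coords.append(ca.get_coord())
    if len(coords) < 3:
        raise SuperpositionError(f"chain {chain!r} has < 3 CA atoms")
    return CoordinateSet(labels, np.array(coords, dtype=float))


def write_ca_pdb(cs: CoordinateSet, path: str | Path, chain: str = "A") -> None:
    """Minimal CA-only PDB writer (fixture/export helper)."""
    with open(path, "w") as fh:
        for i, (label, xyz) in enumerate(zip(cs.labels, cs.coords), 1):
            resseq = "".join(c for c in label if c.isdigit() or c == "-") or str(i)
            fh.write(
                f"ATOM  {i:>5}  CA  GLY {chain}{int(resseq):>4}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def write_report_json(result: SuperpositionResult, path: str | Path) -> None:
    payload = {
        "rotation": result.rotation.tolist(),
        "translation": result.translation.tolist(),
        "rmsd": result.rmsd,
        "kept_pairs": result.kept_pairs,
        "pruned_labels": result.pruned_labels,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
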