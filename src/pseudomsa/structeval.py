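"""Cα-based structure comparison: common-atom RMSD and ensemble ssRMSD.

Predicted and reference chains are compared over the set of Cα atoms
common to both (matched by residue number + insertion code, never by
sequence alignment), superposed by least-squares (Kabsch, reflections
excluded) and scored by RMSD.  For an ensemble of models against one
reference, per-model RMSDs are squared and summed (ssRMSD), which
penalizes both inaccuracy and spread: a low ssRMSD means every model in
the ensemble converged near the native fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CaTrace",
    "SuperpositionResult",
    "EnsembleReport",
    "match_common_ca",
    "kabsch_superpose_rmsd",
    "ensemble_ssrmsd",
    "ComparisonError",
]

ResidueId = Tuple[int, str]  # (sequence number, insertion code; ' ' if none)


class ComparisonError(ValueError):
    """No comparable atoms, or a degenerate superposition request."""


@dataclass(frozen=True)
class CaTrace:
    """Ordered Cα coordinates for one chain, keyed by residue identifier."""

    chain_id: str
    residue_ids: Tuple[ResidueId, ...]
    coords: np.ndarray  # (n, 3) in Angstrom

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.shape != (len(self.residue_ids), 3):
            raise ComparisonError("one coordinate triple per residue required")
        if not np.isfinite(coords).all():
            raise ComparisonError("non-finite coordinates")
        if len(set(self.residue_ids)) != len(self.residue_ids):
            raise ComparisonError("duplicate residue identifiers")

    def __len__(self) -> int:
        return len(self.residue_ids)

    def subrange(self, start: int, end: int) -> "CaTrace":
        """Restrict to residues with start <= number <= end (author numbering)."""
        keep = [i for i, (num, _) in enumerate(self.residue_ids) if start <= num <= end]
        if not keep:
            raise ComparisonError(f"no residues in range {start}-{end}")
        return CaTrace(
            chain_id=self.chain_id,
            residue_ids=tuple(self.residue_ids[i] for i in keep),
            coords=self.coords[keep],
        )

    @classmethod
    def from_pdb(
        cls, path, chain_id: Optional[str] = None, model_index: int = 0
    ) -> "CaTrace":
        """Extract the Cα trace of one chain from a PDB (or mmCIF) file.

        Only standard-residue Cα atoms are taken; for alternate locations
        the parser's highest-occupancy conformer is used (ties: first
        listed).  If ``chain_id`` is None the first chain is used.
        """
        from Bio.PDB import MMCIFParser, PDBParser

        path = Path(path)
        parser = (
            MMCIFParser(QUIET=True)
            if path.suffix.lower() in (".cif", ".mmcif")
            else PDBParser(QUIET=True)
        )
        structure = parser.get_structure(path.stem, str(path))
        model = list(structure)[model_index]
        chains = {c.id: c for c in model}
        if chain_id is None:
            chain = next(iter(chains.values()))
        elif chain_id in chains:
            chain = chains[chain_id]
        else:
            raise ComparisonError(f"chain {chain_id!r} not in {sorted(chains)}")
        ids: List[ResidueId] = []
        xyz: List[np.ndarray] = []
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag != " " or "CA" not in res:
                continue
            ids.append((resseq, icode))
            xyz.append(res["CA"].get_coord())
        if not ids:
            raise ComparisonError(f"chain {chain.id!r} has no Cα atoms")
        return cls(chain_id=chain.id, residue_ids=tuple(ids), coords=np.array(xyz))


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit of one coordinate set onto another."""

    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int
    degenerate: bool = False  # collinear/planar input: rotation not unique


@dataclass(frozen=True)
class EnsembleReport:
    """Per-model RMSDs and the summed squared RMSD of an ensemble."""

    rmsds: Tuple[float, ...]
    ssrmsd: float  # Angstrom^2; NaN when every model failed
    n_models: int
    n_failed: int


def match_common_ca(
    pred: CaTrace, ref: CaTrace
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Pair Cα coordinates by residue identifier present in both traces.

    Order follows the reference.  Returns (pred_coords, ref_coords, count).
    """
    if len(pred) == 0 or len(ref) == 0:
        raise ComparisonError("empty trace")
    pred_index = {rid: i for i, rid in enumerate(pred.residue_ids)}
    pairs = [(pred_index[rid], j) for j, rid in enumerate(ref.residue_ids) if rid in pred_index]
    if not pairs:
        raise ComparisonError("no Cα atoms common to both traces")
    pi, ri = zip(*pairs)
    return pred.coords[list(pi)], ref.coords[list(ri)], len(pairs)


def kabsch_superpose_rmsd(
    mobile: np.ndarray, target: np.ndarray
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Solves the constrained Procrustes problem by SVD with the determinant
    correction that excludes reflections; RMSD is over the transformed
    pairs.  Requires >= 3 pairs; collinear inputs are fitted but flagged as
    degenerate (the rotation about the common axis is arbitrary).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ComparisonError("paired (n, 3) coordinate arrays required")
    n = P.shape[0]
    if n < 3:
        raise ComparisonError("at least 3 atom pairs required for superposition")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = (R @ P.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    # rank < 2 of the centered coordinates => direction(s) unconstrained
    degenerate = bool(np.linalg.matrix_rank(P0, tol=1e-8) < 2)
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd, n_atoms=n, degenerate=degenerate
    )


def common_ca_rmsd(
    pred: CaTrace,
    ref: CaTrace,
    residue_range: Optional[Tuple[int, int]] = None,
) -> SuperpositionResult:
    """Common-Cα RMSD of a prediction against a reference structure.

    ``residue_range`` restricts both traces to an author-numbered residue
    window (e.g. a CDRH3 loop) before matching and superposition.
    """
    if residue_range is not None:
        pred = pred.subrange(*residue_range)
        ref = ref.subrange(*residue_range)
    p, q, _ = match_common_ca(pred, ref)
    return kabsch_superpose_rmsd(p, q)


def ensemble_ssrmsd(
    models: Sequence[CaTrace],
    ref: CaTrace,
    residue_range: Optional[Tuple[int, int]] = None,
) -> EnsembleReport:
    """Sum of squared per-model common-Cα RMSDs over an ensemble.

    Models with no comparable atoms are counted as failures and excluded
    from the sum; a report with every model failed carries ssrmsd = NaN.
    """
    if not models:
        raise ComparisonError("at least one model required")
    rmsds: List[float] = []
    failed = 0
    for m in models:
        try:
            rmsds.append(common_ca_rmsd(m, ref, residue_range).rmsd)
        except ComparisonError:
            failed += 1
    ss = float(sum(r * r for r in rmsds)) if rmsds else float("nan")
    return EnsembleReport(
        rmsds=tuple(rmsds), ssrmsd=ss, n_models=len(models), n_failed=failed
    )
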