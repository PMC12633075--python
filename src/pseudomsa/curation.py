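"""Curation of single-domain antibody (VHH/nanobody) chains from PDB files.

Candidate chains are audited with two gates chosen to isolate intact,
fully resolved VHH domains: a length gate (80 <= L <= 140 standard
residues, the empirical size range of VHH domains) and a contiguity gate
(consecutive integer residue numbering across all adjacent standard
residues — any numbering gap or insertion code indicates unresolved or
non-canonically numbered backbone and fails the chain).  Passing chains
are emitted as single-chain PDB files plus one compiled multi-FASTA whose
sequences are read from the Cα-bearing residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

__all__ = [
    "CurationRecord",
    "extract_standard_residues",
    "apply_curation_gates",
    "curate_structure",
    "curate_directory",
    "write_curated_outputs",
]

MIN_LENGTH = 80
MAX_LENGTH = 140


@dataclass(frozen=True)
class CurationRecord:
    """Per-chain audit of the curation gates."""

    entry_id: str
    chain_id: str
    length: int
    contiguous: bool
    passed: bool
    fail_reasons: Tuple[str, ...] = ()
    sequence: str = ""
    residue_numbers: Tuple[int, ...] = field(default=(), repr=False)

    @property
    def label(self) -> str:
        return f"{self.entry_id}_{self.chain_id}"


def _three_to_one(resname: str) -> str:
    from Bio.Data.PDBData import protein_letters_3to1

    return protein_letters_3to1.get(resname.upper(), "X")


def extract_standard_residues(chain) -> Tuple[List[Tuple[int, str]], str]:
    """Standard amino-acid residues of a Bio.PDB chain, in file order.

    Heteroatoms and solvent are excluded (hetero-flagged residues are
    skipped even if they are modified amino acids); the sequence is read
    from residues bearing a Cα atom.  Returns (identifiers, sequence) where
    each identifier is (residue number, insertion code).
    """
    from Bio.PDB.Polypeptide import is_aa

    ids: List[Tuple[int, str]] = []
    seq: List[str] = []
    for res in chain:
        hetflag, resseq, icode = res.id
        if hetflag != " " or not is_aa(res, standard=True):
            continue
        if "CA" not in res:
            continue
        ids.append((resseq, icode))
        seq.append(_three_to_one(res.get_resname()))
    return ids, "".join(seq)


def apply_curation_gates(
    entry_id: str,
    chain_id: str,
    residue_ids: Sequence[Tuple[int, str]],
    sequence: str,
    min_length: int = MIN_LENGTH,
    max_length: int = MAX_LENGTH,
) -> CurationRecord:
    """Evaluate the length and contiguity gates for one chain.

    Length gate: inclusive on both bounds.  Contiguity gate: every adjacent
    pair of standard residues must differ by exactly 1 in sequence number;
    any insertion code breaks integer-consecutive numbering and is recorded
    as its own fail reason.  Both gates are always evaluated so the record
    carries every applicable reason.
    """
    L = len(residue_ids)
    reasons: List[str] = []
    if not (min_length <= L <= max_length):
        reasons.append(f"length {L} outside [{min_length}, {max_length}]")
    has_icode = any(icode.strip() for _, icode in residue_ids)
    numbers = [num for num, _ in residue_ids]
    gaps = [
        (numbers[j], numbers[j + 1])
        for j in range(len(numbers) - 1)
        if numbers[j + 1] - numbers[j] != 1
    ]
    contiguous = not gaps and not has_icode and L > 0
    if has_icode:
        reasons.append("insertion codes present")
    if gaps:
        reasons.append(f"numbering gap(s): {gaps[:3]}")
    if L == 0:
        contiguous = False
        if "length 0" not in " ".join(reasons):
            reasons.append("no standard residues")
    return CurationRecord(
        entry_id=entry_id,
        chain_id=chain_id,
        length=L,
        contiguous=contiguous,
        passed=(min_length <= L <= max_length) and contiguous,
        fail_reasons=tuple(reasons),
        sequence=sequence,
        residue_numbers=tuple(numbers),
    )


def curate_structure(
    path, min_length: int = MIN_LENGTH, max_length: int = MAX_LENGTH
) -> List[CurationRecord]:
    """Audit every chain of one structure file."""
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    records: List[CurationRecord] = []
    model = next(iter(structure))
    for chain in model:
        ids, seq = extract_standard_residues(chain)
        records.append(
            apply_curation_gates(path.stem, chain.id, ids, seq, min_length, max_length)
        )
    return records


def curate_directory(
    in_dir, min_length: int = MIN_LENGTH, max_length: int = MAX_LENGTH
) -> List[CurationRecord]:
    """Audit every chain of every .pdb file under ``in_dir`` (sorted order)."""
    in_dir = Path(in_dir)
    records: List[CurationRecord] = []
    for path in sorted(in_dir.glob("*.pdb")):
        records.extend(curate_structure(path, min_length, max_length))
    return records


class _ChainSelect:
    """Bio.PDB Select restricting output to one chain's standard residues."""

    def __init__(self, chain_id: str) -> None:
        self.chain_id = chain_id

    def accept_model(self, model) -> int:
        return 1 if model.id == 0 or model.serial_num in (0, 1) else 0

    def accept_chain(self, chain) -> int:
        return 1 if chain.id == self.chain_id else 0

    def accept_residue(self, residue) -> int:
        return 1 if residue.id[0] == " " else 0

    def accept_atom(self, atom) -> int:
        return 1


def write_curated_outputs(
    records: Sequence[CurationRecord],
    structure_paths: Dict[str, Path],
    out_dir,
) -> Tuple[List[Path], Path]:
    """Emit one single-chain PDB per passing chain plus a compiled multi-FASTA.

    ``structure_paths`` maps entry id -> source structure file.  FASTA
    record ids are "<entry>_<chain>" and sequences are the Cα-derived
    sequences from the audit.  Returns (structure files, fasta path).
    """
    from Bio.PDB import PDBIO, PDBParser

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    passing = [r for r in records if r.passed]
    if not passing:
        warnings.warn("no chains passed curation; writing an empty FASTA")
    parser = PDBParser(QUIET=True)
    io = PDBIO()
    written: List[Path] = []
    fasta_path = out_dir / "curated.fasta"
    with open(fasta_path, "w") as fh:
        for rec in passing:
            src = structure_paths[rec.entry_id]
            structure = parser.get_structure(rec.entry_id, str(src))
            io.set_structure(structure)
            out_path = out_dir / f"{rec.label}.pdb"
            io.save(str(out_path), select=_ChainSelect(rec.chain_id))
            written.append(out_path)
            fh.write(f">{rec.label}\n{rec.sequence}\n")
    return written, fasta_path
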