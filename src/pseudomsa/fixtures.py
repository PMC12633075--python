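"""Deterministic synthetic fixtures for desk-scale runs and tests.

Everything the pipeline consumes can be fabricated here with known ground
truth: random queries over the amino alphabet, toy Cα traces with the
~3.8 Å consecutive spacing of real backbones, alignments with one planted
covarying column pair, and a 10-chain structure set engineered to exercise
every curation gate.  Regeneration under the same seed is byte-identical,
and a JSON manifest records every planted property so tests never guess.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._seeding import substream
from .alphabets import AA_ALPHABET, AminoSequence
from .assembly import PseudoMSA
from .structeval import CaTrace

__all__ = [
    "FixtureSpec",
    "random_query",
    "toy_ca_trace",
    "jittered_trace",
    "write_ca_pdb",
    "planted_covariation_alignment",
    "curation_chain_plan",
    "generate_fixture_set",
]

_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: Mean consecutive Cα-Cα distance of a trans peptide backbone (Å).
CA_SPACING = 3.8


@dataclass(frozen=True)
class FixtureSpec:
    """Counts, lengths and planted properties of one fixture set."""

    n_queries: int = 3
    query_length: int = 60
    trace_length: int = 50
    n_models: int = 5
    model_noise_A: float = 0.5
    n_alignment_rows: int = 200
    alignment_length: int = 40
    coupled_pair: Tuple[int, int] = (7, 23)
    coupling_strength: float = 1.0
    identity_band: Tuple[float, float] = (0.3, 0.5)


def random_query(length: int, rng: np.random.Generator, id: str = "query") -> AminoSequence:
    """A uniform random sequence over the 20 amino acids."""
    residues = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, size=length))
    return AminoSequence(residues, id=id)


def toy_ca_trace(
    n_residues: int,
    rng: np.random.Generator,
    chain_id: str = "A",
    start_number: int = 1,
) -> CaTrace:
    """A self-avoiding-ish random walk with consecutive spacing 3.8 ± 0.1 Å."""
    coords = np.zeros((n_residues, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, n_residues):
        # small random turn keeps the walk chain-like rather than a blob
        turn = rng.normal(scale=0.6, size=3)
        direction = direction + turn
        direction /= np.linalg.norm(direction)
        step = CA_SPACING + rng.uniform(-0.1, 0.1)
        coords[i] = coords[i - 1] + step * direction
    ids = tuple((start_number + i, " ") for i in range(n_residues))
    return CaTrace(chain_id=chain_id, residue_ids=ids, coords=coords)


def jittered_trace(
    ref: CaTrace, rng: np.random.Generator, noise_A: float = 0.5
) -> CaTrace:
    """A copy of ``ref`` with isotropic Gaussian coordinate noise, then a
    random rigid motion — a stand-in for an ensemble model of known
    deviation scale."""
    noisy = ref.coords + rng.normal(scale=noise_A, size=ref.coords.shape)
    R = _random_rotation(rng)
    t = rng.uniform(-20, 20, size=3)
    return CaTrace(
        chain_id=ref.chain_id, residue_ids=ref.residue_ids, coords=(R @ noisy.T).T + t
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(int(rng.integers(2**31)))).as_matrix()


def write_ca_pdb(
    path,
    traces: Sequence[CaTrace],
    sequences: Optional[Dict[str, str]] = None,
    insertion_at: Optional[Dict[str, int]] = None,
    n_waters: int = 0,
) -> Path:
    """Write Cα-only chains as a minimal PDB file.

    ``sequences`` optionally maps chain id -> one-letter sequence (defaults
    to poly-alanine); ``insertion_at`` maps chain id -> ordinal position
    whose residue receives insertion code 'A' (duplicating the previous
    number), used to fabricate contiguity-gate failures.  ``n_waters``
    appends HETATM water oxygens.
    """
    path = Path(path)
    lines: List[str] = []
    serial = 1
    for trace in traces:
        seq = sequences.get(trace.chain_id) if sequences else None
        ins_pos = insertion_at.get(trace.chain_id) if insertion_at else None
        for i, ((num, icode), xyz) in enumerate(zip(trace.residue_ids, trace.coords)):
            resname = _ONE_TO_THREE[seq[i]] if seq else "ALA"
            if ins_pos is not None and i == ins_pos and i > 0:
                num = trace.residue_ids[i - 1][0]
                icode = "A"
            lines.append(
                f"ATOM  {serial:5d}  CA  {resname:>3s} {trace.chain_id}"
                f"{num:4d}{icode if icode.strip() else ' '}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
            )
            serial += 1
        lines.append("TER")
    # waters share the first chain so hetero exclusion is what removes them
    water_chain = traces[0].chain_id if traces else "A"
    water_start = (traces[0].residue_ids[-1][0] + 100) if traces else 1
    for w in range(n_waters):
        lines.append(
            f"HETATM{serial:5d}  O   HOH {water_chain}{water_start + w:4d}    "
            f"{50.0 + w:8.3f}{50.0:8.3f}{50.0:8.3f}  1.00  0.00           O"
        )
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def planted_covariation_alignment(
    n_rows: int,
    length: int,
    coupled_pair: Tuple[int, int],
    rng: np.random.Generator,
    coupling_strength: float = 1.0,
) -> PseudoMSA:
    """An alignment of iid-uniform columns with one covarying column pair.

    Column k is a fixed random permutation image of column j in a fraction
    ``coupling_strength`` of rows (1.0 = perfect covariation); all other
    columns are independent uniform noise, so (j, k) is the unique
    mutual-information signal.
    """
    j, k = coupled_pair
    if not (0 <= j < length and 0 <= k < length and j != k):
        raise ValueError("coupled pair must be two distinct in-range columns")
    perm = rng.permutation(20)
    arr = rng.integers(0, 20, size=(n_rows + 1, length))
    coupled = rng.random(n_rows + 1) < coupling_strength
    arr[coupled, k] = perm[arr[coupled, j]]
    rows = ["".join(AA_ALPHABET[c] for c in r) for r in arr]
    query = AminoSequence(rows[0], id="planted")
    return PseudoMSA(query_row=query, rows=tuple(rows[1:]))


def curation_chain_plan() -> List[dict]:
    """The 10-chain toy curation set with engineered gate outcomes."""
    return [
        {"entry": "toy00", "length": 79, "expect_pass": False, "why": "below length gate"},
        {"entry": "toy01", "length": 80, "expect_pass": True, "why": "lower boundary"},
        {"entry": "toy02", "length": 140, "expect_pass": True, "why": "upper boundary"},
        {"entry": "toy03", "length": 141, "expect_pass": False, "why": "above length gate"},
        {"entry": "toy04", "length": 120, "expect_pass": True, "why": "mid-range contiguous"},
        {"entry": "toy05", "length": 120, "gap_after": 50, "expect_pass": False, "why": "numbering gap"},
        {"entry": "toy06", "length": 120, "insertion_at": 60, "expect_pass": False, "why": "insertion code"},
        {"entry": "toy07", "length": 100, "expect_pass": True, "why": "mid-range"},
        {"entry": "toy08", "length": 90, "n_waters": 30, "expect_pass": True, "why": "waters excluded from count"},
        {"entry": "toy09", "length": 60, "expect_pass": False, "why": "far below length gate"},
    ]


def _plan_trace(plan: dict, rng: np.random.Generator) -> CaTrace:
    trace = toy_ca_trace(plan["length"], rng, chain_id="A")
    gap_after = plan.get("gap_after")
    if gap_after is not None:
        ids = list(trace.residue_ids)
        ids = [
            (num + (5 if i > gap_after else 0), icode)
            for i, (num, icode) in enumerate(ids)
        ]
        trace = CaTrace(chain_id="A", residue_ids=tuple(ids), coords=trace.coords)
    return trace


def generate_fixture_set(seed: int, spec: FixtureSpec, out_dir) -> dict:
    """Materialize a full fixture set under ``out_dir`` and return the manifest.

    Writes query FASTA, toy structure PDBs (curation set + an ensemble of
    jittered models around a reference), a planted-covariation alignment,
    and ``manifest.json`` recording every ground-truth property.
    """
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "spec": spec.__dict__.copy()}
    manifest["spec"]["coupled_pair"] = list(spec.coupled_pair)
    manifest["spec"]["identity_band"] = list(spec.identity_band)

    # queries
    qrng = substream(seed, "fixtures", "queries")
    queries = [
        random_query(spec.query_length, qrng, id=f"q{i:02d}")
        for i in range(spec.n_queries)
    ]
    qpath = out_dir / "queries.fasta"
    with open(qpath, "w") as fh:
        for q in queries:
            fh.write(f">{q.id}\n{q.residues}\n")
    manifest["queries"] = {q.id: q.residues for q in queries}

    # curation toy set
    crng = substream(seed, "fixtures", "curation")
    plan = curation_chain_plan()
    for entry in plan:
        trace = _plan_trace(entry, crng)
        write_ca_pdb(
            out_dir / "structures" / f"{entry['entry']}.pdb",
            [trace],
            insertion_at={"A": entry["insertion_at"]} if "insertion_at" in entry else None,
            n_waters=entry.get("n_waters", 0),
        )
    manifest["curation"] = {
        "plan": plan,
        "expected_pass": sorted(
            f"{e['entry']}_A" for e in plan if e["expect_pass"]
        ),
    }

    # ensemble: reference + jittered models
    erng = substream(seed, "fixtures", "ensemble")
    ref = toy_ca_trace(spec.trace_length, erng)
    write_ca_pdb(out_dir / "structures" / "reference.pdb", [ref])
    model_files = []
    for i in range(spec.n_models):
        m = jittered_trace(ref, erng, noise_A=spec.model_noise_A)
        p = write_ca_pdb(out_dir / "structures" / f"model{i}.pdb", [m])
        model_files.append(p.name)
    manifest["ensemble"] = {
        "reference": "reference.pdb",
        "models": model_files,
        "noise_A": spec.model_noise_A,
    }

    # planted-covariation alignment
    arng = substream(seed, "fixtures", "covariation")
    msa = planted_covariation_alignment(
        spec.n_alignment_rows,
        spec.alignment_length,
        spec.coupled_pair,
        arng,
        spec.coupling_strength,
    )
    from .assembly import write_msa

    write_msa(msa, out_dir / "planted.a3m")
    manifest["covariation"] = {
        "file": "planted.a3m",
        "coupled_pair": list(spec.coupled_pair),
        "strength": spec.coupling_strength,
        "n_rows": spec.n_alignment_rows,
    }

    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
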