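"""Assembly of generated fragments into a folding-ready pseudoMSA.

Fragments are realigned to full query length by terminal gap padding —
the generation process is structure-aware, so positional padding (never a
sequence aligner) preserves the alignment implied by each fragment's
origin.  Padded rows then pass through length, complexity and redundancy
filters, may be augmented by substitution-matrix mutagenesis emulating
evolutionary drift, and are finally concatenated under the ungapped query
row.  Writers emit ColabFold-compatible A3M (or aligned FASTA) plus a
subsampling sidecar.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .alphabets import AA_ALPHABET, GAP, AminoSequence, validate_aligned_row
from .backend import ConfigError
from .generation import FragmentSpec, GeneratedRow

__all__ = [
    "PseudoMSA",
    "FilterReport",
    "MutagenesisSpec",
    "pad_to_full_length",
    "strip_gaps",
    "filter_by_length",
    "filter_low_complexity",
    "filter_redundant",
    "mutagenize_rows",
    "assemble_pseudomsa",
    "write_msa",
    "read_msa",
    "write_subsampling_sidecar",
]


class AssemblyError(RuntimeError):
    """Raised when no valid rows survive to assembly."""


@dataclass
class FilterReport:
    """Row accounting across the filter cascade; counts always reconcile."""

    input_count: int = 0
    removed_by_length: int = 0
    removed_by_complexity: int = 0
    removed_by_redundancy: int = 0
    output_count: int = 0

    def check(self) -> None:
        removed = (
            self.removed_by_length
            + self.removed_by_complexity
            + self.removed_by_redundancy
        )
        if self.input_count - removed != self.output_count:
            raise AssemblyError("filter report does not reconcile")

    def merged(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            input_count=self.input_count,
            removed_by_length=self.removed_by_length + other.removed_by_length,
            removed_by_complexity=self.removed_by_complexity
            + other.removed_by_complexity,
            removed_by_redundancy=self.removed_by_redundancy
            + other.removed_by_redundancy,
            output_count=other.output_count,
        )


@dataclass(frozen=True)
class MutagenesisSpec:
    """Controls for substitution-matrix mutagenesis of selected rows.

    ``matrix_name`` is one of BLOSUM62, PAM250 (Boltzmann-weighted over the
    half-bit scores) or MEGABLAST (uniform over the 19 non-identical
    residues, since a match/mismatch scheme carries no pair preferences).
    """

    fraction_of_rows: float = 0.2
    per_position_rate: float = 0.05
    matrix_name: str = "BLOSUM62"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_of_rows <= 1):
            raise ConfigError("fraction_of_rows must lie in [0, 1]")
        if not (0 <= self.per_position_rate <= 1):
            raise ConfigError("per_position_rate must lie in [0, 1]")
        if self.matrix_name not in ("BLOSUM62", "PAM250", "MEGABLAST"):
            raise ConfigError(f"unknown substitution matrix {self.matrix_name!r}")


@dataclass(frozen=True)
class PseudoMSA:
    """A query-first, fixed-width alignment of synthetic rows.

    The first row is always the ungapped query; every row has exactly
    ``width`` characters over the amino alphabet plus '-'.
    """

    query_row: AminoSequence
    rows: Tuple[str, ...]
    provenance: Tuple[dict, ...] = ()
    width: int = 0

    def __post_init__(self) -> None:
        L = len(self.query_row)
        object.__setattr__(self, "width", L)
        for row in self.rows:
            validate_aligned_row(row, L)
        if self.provenance and len(self.provenance) != len(self.rows):
            raise ConfigError("one provenance record per row required")

    @property
    def n_rows(self) -> int:
        """Total row count including the query."""
        return 1 + len(self.rows)

    def all_rows(self) -> List[str]:
        return [self.query_row.residues, *self.rows]


# ---------------------------------------------------------------------------
# padding

def pad_to_full_length(fragment_row: str, spec: FragmentSpec, L: int) -> str:
    """Realign a fragment to width L by N-/C-terminal gap padding."""
    if len(fragment_row) != spec.length:
        raise ConfigError(
            f"fragment row length {len(fragment_row)} != spec length {spec.length}"
        )
    if spec.start + spec.length > L:
        raise ConfigError("fragment window exceeds alignment width")
    return GAP * spec.start + fragment_row + GAP * (L - spec.start - spec.length)


def strip_gaps(row: str) -> str:
    return row.replace(GAP, "")


# ---------------------------------------------------------------------------
# filters

def filter_by_length(rows: Sequence[str], L: int) -> Tuple[List[str], FilterReport]:
    """Keep only rows that perfectly match the target width L."""
    kept = [r for r in rows if len(r) == L]
    report = FilterReport(
        input_count=len(rows),
        removed_by_length=len(rows) - len(kept),
        output_count=len(kept),
    )
    report.check()
    return kept, report


def _longest_run(seq: str) -> int:
    best = run = 0
    prev = None
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def _entropy_bits(seq: str) -> float:
    counts = Counter(seq)
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def _top_digram_frequency(seq: str) -> float:
    """Dominance of the most frequent non-overlapping di-gram.

    Counted at stride 2 in both phases (so a shifted ABAB... repeat is
    still caught); a pure di-peptide repeat scores 1.0.
    """
    if len(seq) < 2:
        return 0.0
    best = 0.0
    for phase in (0, 1):
        chunks = [seq[i : i + 2] for i in range(phase, len(seq) - 1, 2)]
        if chunks:
            best = max(best, Counter(chunks).most_common(1)[0][1] / len(chunks))
    return best


def filter_low_complexity(
    rows: Sequence[str],
    max_run: int = 6,
    min_entropy_bits: float = 2.0,
    max_digram_freq: float = 0.6,
) -> Tuple[List[str], FilterReport]:
    """Drop repetitive / non-convergent rows.

    A row is removed when, over its non-gap residues, (a) the longest
    single-residue run exceeds ``max_run``, (b) Shannon entropy falls below
    ``min_entropy_bits``, or (c) the most frequent di-gram exceeds
    ``max_digram_freq`` of all di-grams (catches ABAB... repeats that slip
    past the run rule).  All-gap rows are removed.
    """
    if max_run <= 0 or min_entropy_bits < 0:
        raise ConfigError("complexity thresholds must be positive")
    kept: List[str] = []
    removed = 0
    for row in rows:
        core = strip_gaps(row)
        if (
            not core
            or _longest_run(core) > max_run
            or _entropy_bits(core) < min_entropy_bits
            or _top_digram_frequency(core) > max_digram_freq
        ):
            removed += 1
        else:
            kept.append(row)
    report = FilterReport(
        input_count=len(rows), removed_by_complexity=removed, output_count=len(kept)
    )
    report.check()
    return kept, report


def _aligned_identity(a: str, b: str) -> float:
    """Fractional identity over alignment width; gaps never match."""
    n = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    return n / len(a)


def filter_redundant(
    rows: Sequence[str], identity_threshold: Optional[float] = 0.95
) -> Tuple[List[str], FilterReport]:
    """Collapse exact duplicates, then greedily drop near-duplicates.

    The second pass removes any row with identity >= ``identity_threshold``
    to an earlier-kept row (input order preserved); pass ``None`` to skip it.
    """
    kept: List[str] = []
    seen: set = set()
    removed = 0
    for row in rows:
        if row in seen:
            removed += 1
            continue
        if identity_threshold is not None and any(
            _aligned_identity(row, k) >= identity_threshold for k in kept
        ):
            removed += 1
            continue
        seen.add(row)
        kept.append(row)
    report = FilterReport(
        input_count=len(rows), removed_by_redundancy=removed, output_count=len(kept)
    )
    report.check()
    return kept, report


# ---------------------------------------------------------------------------
# mutagenesis

_MATRIX_CACHE: Dict[str, Dict[str, Tuple[Tuple[str, ...], Tuple[float, ...]]]] = {}


def _substitution_distributions(matrix_name: str):
    """Per-residue substitution distributions P(b|a) over b != a.

    BLOSUM62/PAM250 use Boltzmann weights exp(S(a,b)/lambda) with
    lambda = 2 (half-bit matrices); MEGABLAST is uniform over the 19
    alternatives.
    """
    if matrix_name in _MATRIX_CACHE:
        return _MATRIX_CACHE[matrix_name]
    dists: Dict[str, Tuple[Tuple[str, ...], Tuple[float, ...]]] = {}
    if matrix_name == "MEGABLAST":
        for a in AA_ALPHABET:
            others = tuple(b for b in AA_ALPHABET if b != a)
            dists[a] = (others, tuple([1.0 / 19] * 19))
    else:
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load(matrix_name)
        lam = 2.0
        for a in AA_ALPHABET:
            others = tuple(b for b in AA_ALPHABET if b != a)
            w = np.array([math.exp(mat[a, b] / lam) for b in others])
            w /= w.sum()
            dists[a] = (others, tuple(w.tolist()))
    _MATRIX_CACHE[matrix_name] = dists
    return dists


def mutagenize_rows(
    rows: Sequence[str],
    spec: MutagenesisSpec,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[str], List[dict]]:
    """Augment the alignment with matrix-mutated copies of selected rows.

    floor(fraction_of_rows * len(rows)) rows are chosen without replacement;
    each non-gap position mutates with probability ``per_position_rate`` to
    a draw from the matrix-induced distribution (identity substitutions
    excluded, so the configured rate is the realized mutation rate).  Gaps
    are never touched.  Originals are retained; returns (originals +
    mutants, per-mutant provenance records).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_pick = int(math.floor(spec.fraction_of_rows * len(rows)))
    if n_pick == 0:
        return list(rows), []
    picked = sorted(rng.choice(len(rows), size=n_pick, replace=False).tolist())
    dists = _substitution_distributions(spec.matrix_name)
    mutants: List[str] = []
    records: List[dict] = []
    for idx in picked:
        src = rows[idx]
        chars = list(src)
        mutated_positions: List[int] = []
        for i, ch in enumerate(chars):
            if ch == GAP:
                continue
            if rng.random() < spec.per_position_rate:
                others, probs = dists[ch]
                chars[i] = others[rng.choice(19, p=probs)]
                mutated_positions.append(i)
        mutants.append("".join(chars))
        records.append(
            {
                "source_index": idx,
                "matrix": spec.matrix_name,
                "n_mutations": len(mutated_positions),
                "positions": mutated_positions,
            }
        )
    return list(rows) + mutants, records


# ---------------------------------------------------------------------------
# assembly and I/O

def assemble_pseudomsa(
    query: AminoSequence,
    surviving_rows: Sequence[str],
    provenance: Optional[Sequence[dict]] = None,
) -> PseudoMSA:
    """Concatenate the query with the valid full-length rows.

    Row order is as provided (the pipeline ranks upstream); assembly fails
    if no rows survived filtering.
    """
    if not surviving_rows:
        raise AssemblyError(
            "no rows survived filtering; relax filter thresholds or increase "
            "the generation budget"
        )
    return PseudoMSA(
        query_row=query,
        rows=tuple(surviving_rows),
        provenance=tuple(provenance) if provenance else (),
    )


def write_msa(msa: PseudoMSA, path, fmt: str = "a3m") -> Path:
    """Write the alignment as A3M or aligned FASTA.

    All rows share the full width, so the A3M dialect degenerates to
    uppercase match states with '-' gaps and no insertion (lowercase)
    states — directly consumable as a custom alignment by ColabFold.
    """
    if fmt not in ("a3m", "fasta"):
        raise ConfigError(f"unknown MSA format {fmt!r}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{msa.query_row.id}\n{msa.query_row.residues}\n")
        for i, row in enumerate(msa.rows):
            rid = (
                msa.provenance[i].get("id", f"row{i}")
                if msa.provenance
                else f"row{i}"
            )
            fh.write(f">{rid}\n{row}\n")
    return path


def read_msa(path) -> PseudoMSA:
    """Read an alignment written by :func:`write_msa` (query-first)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AssemblyError(f"no records in {path}")
    query = AminoSequence(str(records[0].seq), id=records[0].id)
    rows = tuple(str(r.seq) for r in records[1:])
    prov = tuple({"id": r.id} for r in records[1:])
    return PseudoMSA(query_row=query, rows=rows, provenance=prov)


def write_subsampling_sidecar(
    path, n_rows: int, max_seq: int = 16, max_extra_seq: int = 32
) -> Path:
    """Record suggested downstream subsampling depths (max_seq:max_extra_seq).

    The synthetic alignment is information-dense: depths as small as 16/32
    preserve prediction quality, so the sidecar defaults to that ratio,
    clipped to the alignment size.
    """
    path = Path(path)
    payload = {
        "n_rows": n_rows,
        "max_seq": min(max_seq, n_rows),
        "max_extra_seq": min(max_extra_seq, n_rows),
        "ratio": "1:2",
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
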