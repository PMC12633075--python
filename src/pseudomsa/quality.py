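"""Alignment quality metrics: identity, NAD, conservation, coevolution.

The central diagnostic is the Normalized Alignment Divergence (NAD): an
all-vs-all fractional-identity matrix is thresholded at 0.5 to flag
homologous pairs, each sequence i receives weight w_i = 1/(1 + h_i) where
h_i counts the other sequences homologous to it, and the score is
(sum of w_i) / sqrt(L).  Identical alignments collapse to 1/sqrt(L)
(maximal convergence); mutually dissimilar ones reach N/sqrt(L).  A low
NAD indicates a converged, high-confidence synthetic alignment.

The coevolution map is mutual information between column pairs (gaps as a
21st symbol, additive pseudocount) with Average Product Correction — a
dependency-free estimator adequate for QC of planted or emergent
covariation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .alphabets import AA_ALPHABET, GAP
from .assembly import PseudoMSA

__all__ = [
    "NADResult",
    "ConservationProfile",
    "CoevolutionMap",
    "pairwise_identity",
    "nad_score",
    "conservation_profile",
    "identity_to_query_distribution",
    "coevolution_map",
]

_SYMBOLS = AA_ALPHABET + GAP  # 21 categories; gap last
_CODE = {ch: i for i, ch in enumerate(_SYMBOLS)}
_GAP_CODE = _CODE[GAP]


class QualityError(ValueError):
    pass


@dataclass(frozen=True)
class NADResult:
    """All-vs-all identities, per-sequence weights and the NAD score."""

    identities: np.ndarray
    weights: np.ndarray
    score: float
    threshold: float
    width: int


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column residue/gap frequencies and per-column entropy (bits).

    Frequencies include the gap as a category and sum to 1 per column;
    entropy is computed over residues only (a fully gapped column has
    entropy 0 by convention).
    """

    frequencies: np.ndarray  # (L, 21)
    entropy_bits: np.ndarray  # (L,)
    symbols: str = _SYMBOLS


@dataclass(frozen=True)
class CoevolutionMap:
    """Symmetric L x L coupling scores with zero diagonal."""

    scores: np.ndarray
    method_tag: str = "MI+APC"


def _encode(rows: List[str]) -> np.ndarray:
    return np.array([[_CODE[ch] for ch in row] for row in rows], dtype=np.int8)


def pairwise_identity(row_a: str, row_b: str, L: Optional[int] = None) -> float:
    """Fractional identity over the full alignment width.

    The denominator is the alignment width L; a gap never matches anything,
    including another gap, so heavily padded fragments score low against
    full-length rows by construction.
    """
    if L is None:
        L = len(row_a)
    if len(row_a) != L or len(row_b) != L:
        raise QualityError("rows must both have the alignment width")
    n = sum(1 for x, y in zip(row_a, row_b) if x == y and x != GAP)
    return n / L


def _identity_matrix(arr: np.ndarray) -> np.ndarray:
    """Vectorized all-vs-all fractional identity; gaps never match."""
    N, L = arr.shape
    valid = arr != _GAP_CODE
    ident = np.empty((N, N))
    for i in range(N):
        eq = (arr == arr[i]) & valid & valid[i]
        ident[i] = eq.sum(axis=1) / L
    return ident


def nad_score(msa: PseudoMSA, threshold: float = 0.5) -> NADResult:
    """Normalized Alignment Divergence of an alignment.

    Steps: all-vs-all fractional identity (query row included as an
    ordinary sequence); pairs at identity >= ``threshold`` flagged
    homologous; weight w_i = 1/(1 + #homologs of i), self excluded; score =
    (sum w_i)/sqrt(L).  Lower is more converged.
    """
    rows = msa.all_rows()
    L = msa.width
    if len(rows) < 2:
        warnings.warn("single-row alignment: NAD degenerates to 1/sqrt(L)")
        return NADResult(
            identities=np.ones((1, 1)),
            weights=np.ones(1),
            score=1.0 / np.sqrt(L),
            threshold=threshold,
            width=L,
        )
    arr = _encode(rows)
    ident = _identity_matrix(arr)
    homolog = ident >= threshold
    np.fill_diagonal(homolog, False)
    counts = homolog.sum(axis=1)
    weights = 1.0 / (1.0 + counts)
    score = float(weights.sum() / np.sqrt(L))
    return NADResult(
        identities=ident, weights=weights, score=score, threshold=threshold, width=L
    )


def conservation_profile(msa: PseudoMSA) -> ConservationProfile:
    """Column-wise residue/gap frequencies and residue-only entropy."""
    arr = _encode(msa.all_rows())
    N, L = arr.shape
    freqs = np.zeros((L, 21))
    for j in range(L):
        counts = np.bincount(arr[:, j], minlength=21)
        freqs[j] = counts / N
    res = freqs[:, :20]
    ent = np.zeros(L)
    totals = res.sum(axis=1)
    for j in range(L):
        if totals[j] > 0:
            p = res[j] / totals[j]
            p = p[p > 0]
            ent[j] = float(-(p * np.log2(p)).sum())
    return ConservationProfile(frequencies=freqs, entropy_bits=ent)


def identity_to_query_distribution(msa: PseudoMSA) -> Dict[str, object]:
    """Summary of each non-query row's identity to the query row."""
    if not msa.rows:
        raise QualityError("alignment has no non-query rows")
    q = msa.query_row.residues
    idents = np.array([pairwise_identity(row, q, msa.width) for row in msa.rows])
    hist, edges = np.histogram(idents, bins=10, range=(0.0, 1.0))
    return {
        "n": len(idents),
        "min": float(idents.min()),
        "q1": float(np.percentile(idents, 25)),
        "median": float(np.median(idents)),
        "q3": float(np.percentile(idents, 75)),
        "max": float(idents.max()),
        "histogram": hist.tolist(),
        "bin_edges": edges.tolist(),
        "identities": idents,
    }


def mutual_information_matrix(arr: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Pairwise column MI (bits) over 21 symbols with an additive pseudocount.

    The pseudocount is spread uniformly over the 21x21 joint cells; MI is
    non-negative for every pair.  Returned matrix is symmetric with zero
    diagonal and is the pre-APC quantity underlying :func:`coevolution_map`.
    """
    N, L = arr.shape
    K = 21
    mi = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            joint = np.zeros((K, K))
            np.add.at(joint, (arr[:, i], arr[:, j]), 1.0)
            joint += pseudocount / K
            joint /= joint.sum()
            pi = joint.sum(axis=1)
            pj = joint.sum(axis=0)
            nz = joint > 0
            mi_ij = float(
                (joint[nz] * np.log2(joint[nz] / np.outer(pi, pj)[nz])).sum()
            )
            mi[i, j] = mi[j, i] = mi_ij
    return mi


def coevolution_map(msa: PseudoMSA, pseudocount: float = 1.0) -> CoevolutionMap:
    """Mutual information between column pairs with APC.

    Gaps count as a 21st symbol; joint and marginal distributions carry an
    additive pseudocount.  The Average Product Correction
    MI_ij - (MI_i. * MI_.j)/MI_.. removes single-column entropy bias, the
    standard normalization for contact-map QC.
    """
    rows = msa.all_rows()
    if len(rows) < 2:
        raise QualityError("coevolution map requires at least 2 rows")
    arr = _encode(rows)
    L = arr.shape[1]
    mi = mutual_information_matrix(arr, pseudocount)
    # Average Product Correction
    col_mean = mi.sum(axis=1) / (L - 1)
    overall = mi.sum() / (L * (L - 1))
    apc = np.outer(col_mean, col_mean) / overall if overall > 0 else 0.0
    corrected = mi - apc
    np.fill_diagonal(corrected, 0.0)
    corrected = (corrected + corrected.T) / 2.0
    return CoevolutionMap(scores=corrected)
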