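"""Alignment metrics: identity, NAD, conservation, coevolution."""

import math

import numpy as np
import pytest

from pseudomsa import (
    AminoSequence,
    PseudoMSA,
    conservation_profile,
    coevolution_map,
    identity_to_query_distribution,
    nad_score,
    pairwise_identity,
)
from pseudomsa.alphabets import AA_ALPHABET, GAP
from pseudomsa.fixtures import planted_covariation_alignment
from pseudomsa.quality import QualityError


def nad_brute_force(rows, L, threshold=0.5):
    """Independent O(N^2 L) evaluation straight from the metric definition."""
    n = len(rows)
    score = 0.0
    for i in range(n):
        homologs = 0
        for j in range(n):
            if i == j:
                continue
            ident = sum(
                1 for a, b in zip(rows[i], rows[j]) if a == b and a != GAP
            ) / L
            if ident >= threshold:
                homologs += 1
        score += 1.0 / (1.0 + homologs)
    return score / math.sqrt(L)


def _msa(rows, qid="q"):
    return PseudoMSA(query_row=AminoSequence(rows[0], id=qid), rows=tuple(rows[1:]))


def _random_rows(rng, n, L):
    return ["".join(AA_ALPHABET[i] for i in rng.integers(0, 20, L)) for _ in range(n)]


def _clustered_rows(rng, n, L):
    """Rows drawn around a few templates so identities straddle 0.5."""
    templates = _random_rows(rng, max(2, n // 8), L)
    rows = []
    for _ in range(n):
        t = list(templates[rng.integers(len(templates))])
        n_mut = rng.integers(0, L // 2 + 1)
        for p in rng.choice(L, size=n_mut, replace=False):
            t[p] = AA_ALPHABET[rng.integers(20)]
        rows.append("".join(t))
    return rows


class TestPairwiseIdentity:
    def test_identical_ungapped_rows(self):
        assert pairwise_identity("ACDE", "ACDE") == 1.0

    def test_gap_gap_positions_do_not_match(self):
        assert pairwise_identity("AC--", "AC--") == 0.5

    def test_disjoint_rows(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_width_mismatch_rejected(self):
        with pytest.raises(QualityError):
            pairwise_identity("ACD", "AC", 3)


class TestNAD:
    def test_identical_rows_closed_form(self):
        rows = ["ACDEFACDEFACDEFACDEFACDEF"] * 5  # N=5, L=25
        res = nad_score(_msa(rows))
        assert res.score == pytest.approx(0.2, abs=1e-12)  # 1/sqrt(25)
        assert np.allclose(res.weights, 0.2)  # each weight 1/N

    def test_mutually_dissimilar_rows_closed_form(self, rng):
        # rotations of the alphabet share no column, so all identities are 0
        rows = [
            "".join(AA_ALPHABET[(i + k) % 20] for i in range(20)) for k in range(6)
        ]
        res = nad_score(_msa(rows))
        assert res.score == pytest.approx(6 / math.sqrt(20), abs=1e-12)
        assert np.allclose(res.weights, 1.0)

    def test_single_row_degenerates_with_warning(self, query60):
        with pytest.warns(UserWarning):
            res = nad_score(PseudoMSA(query_row=query60, rows=()))
        assert res.score == pytest.approx(1 / math.sqrt(60))

    def test_brute_force_oracle_agreement(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 30))
            L = int(rng.integers(10, 80))
            rows = _clustered_rows(rng, n, L)
            res = nad_score(_msa(rows))
            assert res.score == pytest.approx(
                nad_brute_force(rows, L), abs=1e-9
            )

    def test_bounds_and_directionality(self, rng):
        n, L = 12, 40
        rows = _clustered_rows(rng, n, L)
        score = nad_score(_msa(rows)).score
        assert 1 / math.sqrt(L) - 1e-12 <= score <= n / math.sqrt(L) + 1e-12
        identical = nad_score(_msa([rows[0]] * n)).score
        dissimilar = nad_score(
            _msa(["".join(AA_ALPHABET[(i + k) % 20] for i in range(L)) for k in range(n)])
        ).score
        assert identical < dissimilar  # converged alignments score lower

    def test_duplicating_a_row_never_increases_score(self, rng):
        rows = _clustered_rows(rng, 10, 30)
        base = nad_score(_msa(rows)).score
        dup = rows[:-1] + [rows[0]]
        assert nad_score(_msa(dup)).score <= base + 1e-12


class TestConservation:
    def test_fully_conserved_column(self):
        prof = conservation_profile(_msa(["GA", "GC", "GD"]))
        g = prof.symbols.index("G")
        assert prof.frequencies[0, g] == 1.0
        assert prof.entropy_bits[0] == 0.0

    def test_two_state_column_is_one_bit(self):
        prof = conservation_profile(_msa(["A", "C", "A", "C"]))
        assert prof.entropy_bits[0] == pytest.approx(1.0)

    def test_frequencies_sum_to_one_per_column(self, rng):
        rows = _random_rows(rng, 20, 15)
        rows = rows[:1] + [r[:5] + GAP * 5 + r[10:] for r in rows[1:]]
        prof = conservation_profile(_msa(rows))
        assert np.allclose(prof.frequencies.sum(axis=1), 1.0, atol=1e-9)


class TestIdentityToQuery:
    def test_all_rows_equal_query(self, query60):
        msa = PseudoMSA(query_row=query60, rows=(query60.residues,) * 4)
        summary = identity_to_query_distribution(msa)
        assert summary["min"] == summary["max"] == 1.0
        assert summary["n"] == 4  # rows minus query

    def test_empty_alignment_rejected(self, query60):
        with pytest.raises(QualityError):
            identity_to_query_distribution(PseudoMSA(query_row=query60, rows=()))


def mi_brute_force(rows, i, j, pseudocount=1.0):
    """Naive mutual information between two columns, 21 symbols with the
    same additive pseudocount scheme, written as explicit loops."""
    symbols = AA_ALPHABET + GAP
    code = {ch: k for k, ch in enumerate(symbols)}
    K = len(symbols)
    joint = [[0.0] * K for _ in range(K)]
    for row in rows:
        joint[code[row[i]]][code[row[j]]] += 1.0
    total = 0.0
    for a in range(K):
        for b in range(K):
            joint[a][b] += pseudocount / K
            total += joint[a][b]
    mi = 0.0
    pa = [sum(joint[a][b] for b in range(K)) / total for a in range(K)]
    pb = [sum(joint[a][b] for a in range(K)) / total for b in range(K)]
    for a in range(K):
        for b in range(K):
            p = joint[a][b] / total
            if p > 0:
                mi += p * math.log2(p / (pa[a] * pb[b]))
    return mi


class TestCoevolution:
    def test_symmetry_and_zero_diagonal(self, rng):
        msa = planted_covariation_alignment(60, 12, (2, 9), rng)
        cmap = coevolution_map(msa)
        assert np.array_equal(cmap.scores, cmap.scores.T)
        assert np.all(np.diag(cmap.scores) == 0)
        assert np.isfinite(cmap.scores).all()

    def test_planted_pair_is_top_ranked(self, rng):
        msa = planted_covariation_alignment(200, 30, (7, 23), rng)
        cmap = coevolution_map(msa)
        iu = np.triu_indices(30, k=1)
        top = np.argmax(cmap.scores[iu])
        assert (iu[0][top], iu[1][top]) == (7, 23)

    def test_independent_noise_scores_below_planted_signal(self, rng):
        planted = planted_covariation_alignment(300, 20, (3, 11), rng)
        signal = coevolution_map(planted).scores[3, 11]
        noise = planted_covariation_alignment(300, 20, (3, 11), rng, coupling_strength=0.0)
        assert coevolution_map(noise).scores.max() < signal

    def test_raw_mi_matches_loop_oracle(self, rng):
        from pseudomsa.quality import _encode, mutual_information_matrix

        msa = planted_covariation_alignment(80, 6, (1, 4), rng)
        rows = msa.all_rows()
        mi_impl = mutual_information_matrix(_encode(rows), pseudocount=1.0)
        for i in range(6):
            for j in range(i + 1, 6):
                assert mi_impl[i, j] == pytest.approx(
                    mi_brute_force(rows, i, j), abs=1e-9
                )
                assert mi_impl[i, j] >= -1e-12  # MI non-negative before APC

    def test_two_row_minimum(self, query60):
        with pytest.raises(QualityError):
            coevolution_map(PseudoMSA(query_row=query60, rows=()))
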