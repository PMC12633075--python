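"""Padding realignment, filter cascade, mutagenesis and MSA I/O."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pseudomsa import (
    AminoSequence,
    FragmentSpec,
    MutagenesisSpec,
    PseudoMSA,
    assemble_pseudomsa,
    filter_by_length,
    filter_low_complexity,
    filter_redundant,
    mutagenize_rows,
    pad_to_full_length,
    read_msa,
    write_msa,
)
from pseudomsa.alphabets import AA_ALPHABET, GAP
from pseudomsa.assembly import AssemblyError, strip_gaps
from pseudomsa.backend import ConfigError

aa_text = st.text(alphabet=AA_ALPHABET, min_size=1, max_size=40)


class TestPadding:
    def test_direct_construction(self):
        spec = FragmentSpec(start=2, length=5, coverage=0.5)
        assert pad_to_full_length("ACDEF", spec, 10) == "--ACDEF---"

    def test_full_coverage_identity(self):
        spec = FragmentSpec(start=0, length=6, coverage=1.0)
        assert pad_to_full_length("ACDEFG", spec, 6) == "ACDEFG"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            pad_to_full_length("ACD", FragmentSpec(0, 4, 0.5), 10)

    @given(aa_text, st.integers(0, 20), st.integers(0, 20))
    def test_pad_then_strip_round_trip(self, frag, start, tail):
        L = start + len(frag) + tail
        spec = FragmentSpec(start=start, length=len(frag), coverage=len(frag) / L)
        padded = pad_to_full_length(frag, spec, L)
        assert len(padded) == L
        assert strip_gaps(padded) == frag


class TestLengthFilter:
    def test_mixed_widths(self):
        rows = ["A" * 10, "A" * 9, "C" * 10]
        kept, rep = filter_by_length(rows, 10)
        assert kept == ["A" * 10, "C" * 10]
        assert (rep.removed_by_length, rep.output_count) == (1, 2)

    def test_empty_input_all_counts_zero(self):
        kept, rep = filter_by_length([], 10)
        assert kept == [] and rep.input_count == rep.output_count == 0


class TestComplexityFilter:
    def test_mono_repeat_removed_by_run_rule(self):
        kept, rep = filter_low_complexity(["A" * 12], max_run=6)
        assert kept == [] and rep.removed_by_complexity == 1

    def test_uniform_composition_kept(self, rng):
        row = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 100))
        kept, _ = filter_low_complexity([row], min_entropy_bits=2.0)
        assert kept == [row]  # entropy of a near-uniform 100-mer is ~4.1 bits

    def test_dipeptide_repeat_removed_by_digram_rule(self):
        row = "AC" * 30  # longest run is 1, entropy 1 bit -> also digram-dominated
        kept, rep = filter_low_complexity([row], min_entropy_bits=0.5, max_run=6)
        assert kept == [] and rep.removed_by_complexity == 1

    def test_all_gap_row_removed(self):
        kept, rep = filter_low_complexity([GAP * 10])
        assert kept == [] and rep.removed_by_complexity == 1

    def test_idempotent(self, rng):
        rows = ["".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 50)) for _ in range(20)]
        rows.append("A" * 50)
        once, _ = filter_low_complexity(rows)
        twice, rep = filter_low_complexity(once)
        assert twice == once and rep.removed_by_complexity == 0


class TestRedundancyFilter:
    def test_exact_duplicates_collapse(self):
        rows = ["ACDE"] * 3
        kept, rep = filter_redundant(rows, identity_threshold=None)
        assert kept == ["ACDE"] and rep.removed_by_redundancy == 2

    def test_near_duplicate_removed_at_threshold(self, rng):
        a = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 100))
        b = ("C" if a[0] != "C" else "D") + a[1:]  # identity 0.99
        kept, rep = filter_redundant([a, b], identity_threshold=0.95)
        assert kept == [a] and rep.removed_by_redundancy == 1

    def test_distinct_rows_pass_unchanged(self, rng):
        rows = ["".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 30)) for _ in range(10)]
        kept, rep = filter_redundant(rows, identity_threshold=0.95)
        assert kept == rows and rep.removed_by_redundancy == 0

    def test_idempotent(self, rng):
        rows = ["".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 30)) for _ in range(10)]
        rows += rows[:3]
        once, _ = filter_redundant(rows)
        twice, rep = filter_redundant(once)
        assert twice == once and rep.removed_by_redundancy == 0


class TestReportConservation:
    def test_counts_reconcile_across_cascade(self, rng):
        rows = ["".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 40)) for _ in range(30)]
        rows += ["A" * 40, "C" * 39] + rows[:2]
        kept, r1 = filter_by_length(rows, 40)
        kept, r2 = filter_low_complexity(kept)
        kept, r3 = filter_redundant(kept)
        merged = r1.merged(r2).merged(r3)
        merged.check()
        assert merged.input_count == len(rows)
        assert merged.output_count == len(kept)


class TestMutagenesis:
    def test_zero_rate_identical(self, rng):
        rows = ["ACDEFGHIKL"] * 5
        spec = MutagenesisSpec(fraction_of_rows=1.0, per_position_rate=0.0, seed=1)
        out, recs = mutagenize_rows(rows, spec, rng)
        assert out[5:] == rows  # mutants appended after originals
        assert all(r["n_mutations"] == 0 for r in recs)

    def test_rate_one_every_position_differs(self, rng):
        row = "ACDEFGHIKL" + GAP * 3
        spec = MutagenesisSpec(fraction_of_rows=1.0, per_position_rate=1.0, seed=2)
        out, _ = mutagenize_rows([row], spec, rng)
        mutant = out[1]
        for orig, new in zip(row, mutant):
            if orig == GAP:
                assert new == GAP  # gaps never mutated
            else:
                assert new != orig

    @pytest.mark.parametrize("matrix", ["BLOSUM62", "PAM250", "MEGABLAST"])
    def test_realized_rate_matches_configured(self, matrix, rng):
        """Configured rate 0.1 over 10,000 positions: realized fraction within
        3 binomial standard errors."""
        rows = ["".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 100)) for _ in range(100)]
        spec = MutagenesisSpec(
            fraction_of_rows=1.0, per_position_rate=0.1, matrix_name=matrix, seed=3
        )
        out, recs = mutagenize_rows(rows, spec, rng)
        n_mut = sum(r["n_mutations"] for r in recs)
        n_pos = 100 * 100
        se = np.sqrt(0.1 * 0.9 * n_pos)
        assert abs(n_mut - 0.1 * n_pos) <= 3 * se

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ConfigError):
            MutagenesisSpec(matrix_name="VTML")


class TestAssembleAndIO:
    def test_query_first_and_width(self, query60):
        rows = [query60.residues[:30] + GAP * 30, GAP * 30 + query60.residues[30:]]
        msa = assemble_pseudomsa(query60, rows)
        assert msa.all_rows()[0] == query60.residues
        assert msa.n_rows == 3
        assert all(len(r) == 60 for r in msa.all_rows())

    def test_zero_rows_is_assembly_error(self, query60):
        with pytest.raises(AssemblyError, match="relax"):
            assemble_pseudomsa(query60, [])

    @pytest.mark.parametrize("fmt", ["a3m", "fasta"])
    def test_write_read_round_trip(self, fmt, query60, tmp_path):
        rows = (query60.residues[:20] + GAP * 40, GAP * 10 + query60.residues[10:])
        msa = PseudoMSA(query_row=query60, rows=rows)
        path = write_msa(msa, tmp_path / f"t.{fmt}", fmt)
        back = read_msa(path)
        assert back.query_row.residues == msa.query_row.residues
        assert back.rows == msa.rows
        # format invariants: every record has exactly width L
        lines = [l for l in path.read_text().splitlines() if not l.startswith(">")]
        assert all(len(l) == 60 for l in lines)
        assert path.read_text().splitlines()[0] == f">{query60.id}"
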