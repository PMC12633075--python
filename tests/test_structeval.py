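"""Common-Cα matching, Kabsch superposition, RMSD and ensemble ssRMSD."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pseudomsa import (
    CaTrace,
    common_ca_rmsd,
    ensemble_ssrmsd,
    kabsch_superpose_rmsd,
    match_common_ca,
)
from pseudomsa.fixtures import toy_ca_trace
from pseudomsa.structeval import ComparisonError


def _trace(coords, numbers=None, chain="A"):
    coords = np.asarray(coords, dtype=float)
    if numbers is None:
        numbers = range(1, len(coords) + 1)
    return CaTrace(chain, tuple((n, " ") for n in numbers), coords)


def _random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-50, 50, 3)
    return R, t


def rmsd_rotation_grid_oracle(P, Q, coarse=12):
    """Independent oracle: minimize RMSD over rotations by an Euler-angle
    grid search polished with Nelder-Mead from the best grid cells."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def cost(angles):
        R = Rotation.from_euler("zyx", angles).as_matrix()
        return np.sqrt(np.mean(np.sum(((R @ P0.T).T - Q0) ** 2, axis=1)))

    grid = np.linspace(-math.pi, math.pi, coarse, endpoint=False)
    starts = sorted(
        itertools.product(grid, grid, grid), key=cost
    )[:5]
    best = math.inf
    for s in starts:
        res = minimize(cost, s, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12})
        best = min(best, res.fun)
    return best


class TestMatching:
    def test_identical_traces_pair_fully(self, rng):
        t = toy_ca_trace(50, rng)
        _, _, n = match_common_ca(t, t)
        assert n == 50

    def test_missing_prefix_reduces_pairs(self, rng):
        ref = toy_ca_trace(50, rng)
        pred = CaTrace("A", ref.residue_ids[5:], ref.coords[5:])
        _, _, n = match_common_ca(pred, ref)
        assert n == 45

    def test_disjoint_numbering_is_error(self, rng):
        a = toy_ca_trace(10, rng, start_number=1)
        b = toy_ca_trace(10, rng, start_number=100)
        with pytest.raises(ComparisonError):
            match_common_ca(a, b)


class TestKabsch:
    def test_rigid_motion_invariance(self, rng):
        t = toy_ca_trace(40, rng)
        for _ in range(50):
            R, tr = _random_rigid(rng)
            moved = (R @ t.coords.T).T + tr
            res = kabsch_superpose_rmsd(moved, t.coords)
            assert res.rmsd <= 1e-6
            assert abs(np.linalg.det(res.rotation) - 1) < 1e-9

    def test_symmetry(self, rng):
        a = rng.normal(size=(20, 3)) * 10
        b = rng.normal(size=(20, 3)) * 10
        assert kabsch_superpose_rmsd(a, b).rmsd == pytest.approx(
            kabsch_superpose_rmsd(b, a).rmsd, abs=1e-9
        )

    def test_rotation_is_orthogonal_proper(self, rng):
        for _ in range(20):
            a = rng.normal(size=(8, 3)) * 5
            b = rng.normal(size=(8, 3)) * 5
            res = kabsch_superpose_rmsd(a, b)
            assert np.allclose(res.rotation @ res.rotation.T, np.eye(3), atol=1e-9)
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_grid_search_oracle_agreement_on_small_toys(self, rng):
        for _ in range(5):
            n = int(rng.integers(4, 9))
            a = rng.normal(size=(n, 3)) * 3
            b = rng.normal(size=(n, 3)) * 3
            impl = kabsch_superpose_rmsd(a, b).rmsd
            oracle = rmsd_rotation_grid_oracle(a, b)
            assert impl == pytest.approx(oracle, abs=1e-3)
            assert impl <= oracle + 1e-9  # Kabsch is the optimum

    def test_agrees_with_biopython_superimposer(self, rng):
        from Bio.PDB.qcprot import QCPSuperimposer  # noqa: F401 - presence check
        from Bio.SVDSuperimposer import SVDSuperimposer

        a = rng.normal(size=(30, 3)) * 8
        b = rng.normal(size=(30, 3)) * 8
        sup = SVDSuperimposer()
        sup.set(b, a)  # fits the second argument onto the first
        sup.run()
        assert kabsch_superpose_rmsd(a, b).rmsd == pytest.approx(
            float(sup.get_rms()), abs=1e-6
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ComparisonError):
            kabsch_superpose_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_input_flagged_degenerate(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        res = kabsch_superpose_rmsd(line, line + [0.0, 1.0, 0.0])
        assert res.degenerate


# 4-atom planar square with out-of-plane residuals chosen so the optimal
# rotation is the identity: the residual RMSD is exactly 1 A.
_SQUARE = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], dtype=float)
_UNIT_Z = np.array([[0, 0, 1], [0, 0, -1], [0, 0, -1], [0, 0, 1]], dtype=float)


class TestEnsemble:
    def test_identical_ensemble_is_zero(self, rng):
        ref = toy_ca_trace(30, rng)
        report = ensemble_ssrmsd([ref] * 5, ref)
        assert report.ssrmsd == pytest.approx(0.0, abs=1e-12)
        assert report.n_failed == 0

    def test_five_unit_rmsd_models_sum_to_five(self):
        ref = _trace(_SQUARE)
        model = _trace(_SQUARE + _UNIT_Z)
        assert common_ca_rmsd(model, ref).rmsd == pytest.approx(1.0, abs=1e-12)
        report = ensemble_ssrmsd([model] * 5, ref)
        assert report.ssrmsd == pytest.approx(5.0, abs=1e-9)

    def test_sum_of_squares_reconciles(self, rng):
        ref = toy_ca_trace(25, rng)
        models = [
            _trace(ref.coords + rng.normal(scale=s, size=ref.coords.shape))
            for s in (0.2, 0.5, 1.0, 2.0)
        ]
        report = ensemble_ssrmsd(models, ref)
        expected = sum(common_ca_rmsd(m, ref).rmsd ** 2 for m in models)
        assert report.ssrmsd == pytest.approx(expected, abs=1e-9)

    def test_failures_counted_not_summed(self, rng):
        ref = toy_ca_trace(20, rng, start_number=1)
        good = _trace(ref.coords, numbers=range(1, 21))
        bad = toy_ca_trace(20, rng, start_number=500)
        report = ensemble_ssrmsd([good, bad], ref)
        assert report.n_failed == 1
        assert report.ssrmsd == pytest.approx(0.0, abs=1e-9)

    def test_all_failed_flagged_nan(self, rng):
        ref = toy_ca_trace(20, rng, start_number=1)
        bad = toy_ca_trace(20, rng, start_number=500)
        report = ensemble_ssrmsd([bad], ref)
        assert report.n_failed == 1
        assert math.isnan(report.ssrmsd)

    def test_adding_a_model_never_decreases_ssrmsd(self, rng):
        ref = toy_ca_trace(25, rng)
        models = [
            _trace(ref.coords + rng.normal(scale=0.5, size=ref.coords.shape))
            for _ in range(4)
        ]
        partial = ensemble_ssrmsd(models[:3], ref).ssrmsd
        full = ensemble_ssrmsd(models, ref).ssrmsd
        assert full >= partial


class TestPdbIO:
    def test_trace_round_trips_through_pdb(self, rng, tmp_path):
        from pseudomsa.fixtures import write_ca_pdb

        t = toy_ca_trace(30, rng)
        path = write_ca_pdb(tmp_path / "t.pdb", [t])
        back = CaTrace.from_pdb(path)
        assert back.residue_ids == t.residue_ids
        assert np.allclose(back.coords, t.coords, atol=1e-3)  # PDB has 3 decimals

    def test_residue_range_subsets_author_numbering(self, rng, tmp_path):
        t = toy_ca_trace(30, rng, start_number=10)
        sub = t.subrange(15, 20)
        assert len(sub) == 6
        assert sub.residue_ids[0] == (15, " ")
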