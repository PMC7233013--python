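"""Monochromatic engine: pair selection, rotation solving, scoring, search."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tcindex import (IndexerParams, NotIndexableError, build_table,
                     index_monochromatic, score_solution, select_peak_pairs,
                     solve_rotation)
from tcindex.indexer import (DegeneratePairError, nearest_integer,
                             rotations_from_pairs, score_batch)
from tcindex.reftable import ReferenceEntry

#: proper rotations of the cubic lattice; indexing a cubic cell is
#: ambiguous up to this group
OCTAHEDRAL = Rotation.create_group("O").as_matrix()


def cubic_orientation_error_deg(U_est, U_true):
    errs = [np.degrees(Rotation.from_matrix(U_est @ (U_true @ g).T).magnitude())
            for g in OCTAHEDRAL]
    return min(errs)


class TestSelectPeakPairs:
    def test_all_pairs_when_budget_allows(self):
        pairs = select_peak_pairs(np.ones(3), IndexerParams(n_pairs=10))
        assert pairs == [(0, 1), (0, 2), (1, 2)]

    def test_top_pair_by_snr(self):
        pairs = select_peak_pairs(np.array([9.0, 5.0, 1.0]),
                                  IndexerParams(n_pairs=1))
        assert pairs == [(0, 1)]

    def test_ranking_matches_exhaustive_sort(self):
        """Returned ranking equals sorting all C(20,2) pairs exhaustively."""
        rng = np.random.default_rng(5)
        key = rng.uniform(0, 100, 20)
        params = IndexerParams(n_pairs=190)
        got = select_peak_pairs(key, params)
        expect = sorted(itertools.combinations(range(20), 2),
                        key=lambda p: (-(key[p[0]] + key[p[1]]), p[0], p[1]))
        assert got == expect

    def test_single_peak_not_indexable(self):
        with pytest.raises(NotIndexableError):
            select_peak_pairs(np.ones(1), IndexerParams())


class TestSolveRotation:
    def _entry(self, cell, ha, hb):
        B = cell.b_matrix
        qa, qb = B @ np.array(ha, float), B @ np.array(hb, float)
        la, lb = np.linalg.norm(qa), np.linalg.norm(qb)
        ang = np.degrees(np.arccos(np.clip(qa @ qb / (la * lb), -1, 1)))
        if la <= lb:
            return ReferenceEntry(la, lb, ang, ha, hb)
        return ReferenceEntry(lb, la, ang, hb, ha)

    def test_identity_orientation(self, cubic_cell):
        e = self._entry(cubic_cell, (1, 0, 0), (0, 1, 1))
        B = cubic_cell.b_matrix
        q_pair = (B @ np.array(e.hkl_a, float), B @ np.array(e.hkl_b, float))
        Us = solve_rotation(q_pair, e, cubic_cell)
        assert any(np.allclose(U, np.eye(3), atol=1e-10) for U in Us)

    def test_recovers_known_rotation(self, triclinic_cell):
        rng = np.random.default_rng(6)
        B = triclinic_cell.b_matrix
        for _ in range(20):
            R = Rotation.random(rng=rng).as_matrix()
            e = self._entry(triclinic_cell, (1, 2, -1), (0, 1, 3))
            q_pair = (R @ B @ np.array(e.hkl_a, float),
                      R @ B @ np.array(e.hkl_b, float))
            Us = solve_rotation(q_pair, e, triclinic_cell)
            assert any(np.max(np.abs(U - R)) < 1e-10 for U in Us)

    def test_noisy_pair_within_a_degree(self, triclinic_cell):
        """0.5 deg of angular noise on the observed pair -> U within ~1 deg."""
        rng = np.random.default_rng(7)
        B = triclinic_cell.b_matrix
        R = Rotation.random(rng=rng).as_matrix()
        e = self._entry(triclinic_cell, (2, 1, 0), (-1, 1, 2))
        noise = Rotation.from_rotvec(np.radians(0.5) * np.array([1, 0, 0]))
        qa = noise.as_matrix() @ R @ B @ np.array(e.hkl_a, float)
        qb = R @ B @ np.array(e.hkl_b, float)
        Us = solve_rotation((qa, qb), e, triclinic_cell)
        err = min(Rotation.from_matrix(U @ R.T).magnitude() for U in Us)
        assert np.degrees(err) < 1.0

    def test_collinear_pair_raises(self, cubic_cell):
        e = self._entry(cubic_cell, (1, 0, 0), (0, 1, 0))
        with pytest.raises(DegeneratePairError):
            rotations_from_pairs(np.array([0.1, 0, 0]), np.array([0.2, 0, 0]),
                                 np.array([[0.1, 0, 0]]), np.array([[0, 0.1, 0]]))

    def test_batch_rotations_are_proper(self, triclinic_cell, table5):
        qa = np.array([0.15, 0.02, 0.01])
        qb = np.array([0.05, 0.12, -0.08])
        la, lb = sorted([np.linalg.norm(qa), np.linalg.norm(qb)])
        ang = np.degrees(np.arccos(qa @ qb / np.linalg.norm(qa) / np.linalg.norm(qb)))
        ka, kb, _, _ = table5.query_vectors(la, lb, ang, 0.0025, 1.0)
        if len(ka):
            Us = rotations_from_pairs(qa, qb, ka, kb)
            assert np.allclose(np.einsum("mij,mkj->mik", Us, Us),
                               np.eye(3), atol=1e-9)
            assert np.allclose(np.linalg.det(Us), 1.0, atol=1e-9)


class TestScoreSolution:
    def test_exact_lattice_scores_all(self, triclinic_cell):
        rng = np.random.default_rng(8)
        U = Rotation.random(rng=rng).as_matrix()
        hkl = rng.integers(-5, 6, size=(30, 3))
        hkl = hkl[np.any(hkl != 0, axis=1)]
        q = (U @ triclinic_cell.b_matrix @ hkl.T).T
        S, records = score_solution(U, triclinic_cell, q, delta=0.1)
        assert S == len(q)
        assert max(r.residual for r in records) < 1e-10

    def test_threshold_straddle(self, cubic_cell):
        """Fractional index (1.3, 0, 0): unmatched at delta 0.25, matched at 0.35."""
        U = np.eye(3)
        q = (cubic_cell.b_matrix @ np.array([1.3, 0.0, 0.0]))[None, :]
        S25, rec = score_solution(U, cubic_cell, q, delta=0.25)
        assert S25 == 0 and rec[0].residual == pytest.approx(0.3)
        S35, _ = score_solution(U, cubic_cell, q, delta=0.35)
        assert S35 == 1

    def test_matches_independent_reimplementation(self, triclinic_cell):
        """Vectorized score equals a naive per-peak check."""
        rng = np.random.default_rng(9)
        U = Rotation.random(rng=rng).as_matrix()
        q = rng.uniform(-0.2, 0.2, size=(50, 3))
        delta = 0.25
        S, records = score_solution(U, triclinic_cell, q, delta)
        UB_inv = np.linalg.inv(U @ triclinic_cell.b_matrix)
        expected = 0
        for i, qi in enumerate(q):
            hf = UB_inv @ qi
            hi = np.array([np.floor(x + 0.5) if x >= 0 else np.ceil(x - 0.5)
                           for x in hf])
            res = np.max(np.abs(hf - hi))
            assert records[i].residual == pytest.approx(res, abs=1e-12)
            expected += res <= delta
        assert S == expected

    def test_delta_monotonicity(self, triclinic_cell):
        rng = np.random.default_rng(10)
        U = Rotation.random(rng=rng).as_matrix()
        q = rng.uniform(-0.2, 0.2, size=(40, 3))
        scores = [score_solution(U, triclinic_cell, q, d)[0]
                  for d in np.linspace(0.01, 0.5, 20)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_score_batch_agrees_with_scalar_path(self, triclinic_cell):
        rng = np.random.default_rng(11)
        Us = Rotation.random(7, rng=rng).as_matrix()
        q = rng.uniform(-0.2, 0.2, size=(25, 3))
        S, tot = score_batch(Us, triclinic_cell, q, 0.25)
        for m in range(7):
            S_m, recs = score_solution(Us[m], triclinic_cell, q, 0.25)
            assert S[m] == S_m
            assert tot[m] == pytest.approx(
                sum(r.residual for r in recs if r.matched), abs=1e-12)


def test_nearest_integer_rounds_half_away_from_zero():
    x = np.array([0.5, -0.5, 1.49, -1.51, 2.5])
    assert np.array_equal(nearest_integer(x), [1, -1, 1, -2, 3])


class TestIndexMonochromatic:
    def _pattern(self, cell, U, rng, n=8, qmax=0.2):
        """Exact lattice q-vectors at a known orientation (no detector)."""
        from tcindex import enumerate_reflections
        hkl = enumerate_reflections(cell, 1.0 / qmax)
        pick = rng.choice(len(hkl), size=n, replace=False)
        return (U @ cell.b_matrix @ hkl[pick].T).T

    def test_identity_noise_free(self, cubic_cell, cubic_table):
        rng = np.random.default_rng(12)
        q = self._pattern(cubic_cell, np.eye(3), rng)
        sol = index_monochromatic(q, cubic_table,
                                  IndexerParams(n_pairs=10, min_score=6))
        assert sol is not None
        assert sol.score == len(q)
        # identity recovered up to the cubic lattice's point-group ambiguity
        assert cubic_orientation_error_deg(sol.rotation, np.eye(3)) < 1e-6

    def test_random_orientation_recovered(self, cubic_cell, cubic_table):
        rng = np.random.default_rng(13)
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            q = self._pattern(cubic_cell, R, rng)
            sol = index_monochromatic(q, cubic_table,
                                      IndexerParams(n_pairs=10, min_score=6))
            assert sol is not None and sol.score == len(q)
            assert cubic_orientation_error_deg(sol.rotation, R) < 0.2

    def test_random_peaks_return_none(self, triclinic_cell, table5):
        """Uniform random peaks (no lattice) stay below the acceptance score."""
        from tcindex.geometry import DetectorGeometry, energy_to_wavelength, pixel_to_q
        rng = np.random.default_rng(14)
        geom = DetectorGeometry()
        fs = rng.uniform(0, 1439, 60)
        ss = rng.uniform(0, 1439, 60)
        q = pixel_to_q(fs, ss, geom, energy_to_wavelength(7.0))
        sol = index_monochromatic(q, table5, IndexerParams())
        assert sol is None

    def test_label_invariance(self, cubic_cell, cubic_table):
        """Permuting the peak order does not change the best score."""
        rng = np.random.default_rng(15)
        R = Rotation.random(rng=rng).as_matrix()
        q = self._pattern(cubic_cell, R, rng)
        params = IndexerParams(n_pairs=28, min_score=6)
        sol1 = index_monochromatic(q, cubic_table, params)
        perm = rng.permutation(len(q))
        sol2 = index_monochromatic(q[perm], cubic_table, params)
        assert sol1 is not None and sol2 is not None
        assert sol1.score == sol2.score
        assert cubic_orientation_error_deg(sol1.rotation, sol2.rotation) < 0.1

    def test_too_few_peaks(self, cubic_table):
        with pytest.raises(NotIndexableError):
            index_monochromatic(np.array([[0.1, 0, 0]]), cubic_table,
                                IndexerParams())

    def test_solutions_are_proper_rotations(self, cubic_cell, cubic_table):
        rng = np.random.default_rng(16)
        R = Rotation.random(rng=rng).as_matrix()
        q = self._pattern(cubic_cell, R, rng)
        sol = index_monochromatic(q, cubic_table, IndexerParams(min_score=6))
        U = sol.rotation
        assert np.allclose(U @ U.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(U) == pytest.approx(1.0, abs=1e-9)
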