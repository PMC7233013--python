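"""Two-color indexing: joint scoring, color assignment and refinement.

A two-color still image superimposes two diffraction patterns taken at
two photon energies.  Each detector peak is converted to a reciprocal
vector under *both* wavelength hypotheses; a candidate rotation is scored
by counting peaks matched under either color (the smaller of the two
fractional-index residuals decides).  The best rotation's per-peak
residual pair ``(e_1, e_2)`` is turned into color probabilities, the
peaks are split into two color groups, and a global refinement polishes
the rotation against both groups simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .geometry import DetectorGeometry, ExperimentSetup, UnitCell, pixel_to_q
from .indexer import (IndexerParams, NotIndexableError, fractional_hkl,
                      generate_candidates, nearest_integer, score_batch,
                      select_peak_pairs)
from .reftable import ReferenceTable


@dataclass
class ColorAssignment:
    peak_id: int
    residual_1: float
    residual_2: float
    p_1: float
    p_2: float
    assigned_color: int  # 1, 2, or 0 for unassigned
    matched: bool


@dataclass
class RefinementReport:
    objective_initial: float
    objective_final: float
    n_iterations: int
    converged: bool


@dataclass
class TwoColorSolution:
    rotation: np.ndarray
    score: int
    assignments: list[ColorAssignment]
    group_1: np.ndarray  # peak ids assigned to color 1
    group_2: np.ndarray
    refinement: RefinementReport | None
    seed_pair: tuple[int, int]
    seed_rank: int
    seed_color: int      # wavelength hypothesis that generated the seed
    total_residual: float


# ---------------------------------------------------------------------------
# scoring and color probabilities
# ---------------------------------------------------------------------------

def _residuals(U: np.ndarray, cell: UnitCell, q: np.ndarray) -> np.ndarray:
    hf = fractional_hkl(U, cell, q)
    return np.max(np.abs(hf - nearest_integer(hf)), axis=1)


def score_two_color(U: np.ndarray, cell: UnitCell, q1: np.ndarray,
                    q2: np.ndarray, delta: float
                    ) -> tuple[int, np.ndarray, np.ndarray]:
    """Two-color score of one rotation.

    ``q1[i]`` and ``q2[i]`` are the same detector peak converted under the
    two wavelengths.  A peak is matched when its smaller per-color residual
    is within ``delta``.  Returns ``(S, residual_1, residual_2)``.
    """
    r1 = _residuals(U, cell, np.atleast_2d(q1))
    r2 = _residuals(U, cell, np.atleast_2d(q2))
    S = int(np.sum(np.minimum(r1, r2) <= delta))
    return S, r1, r2


def score_batch_two_color(Us: np.ndarray, cell: UnitCell, q1: np.ndarray,
                          q2: np.ndarray, delta: float, chunk: int = 2048
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-color scores for a stack of rotations.

    Returns ``(S, total_residual)`` where the residual of a matched peak is
    the smaller of its two per-color residuals.
    """
    Us = np.atleast_3d(Us).reshape(-1, 3, 3)
    S = np.zeros(len(Us), dtype=int)
    tot = np.zeros(len(Us))
    Binv = cell.b_inverse
    for lo in range(0, len(Us), chunk):
        U = Us[lo:lo + chunk]
        A = np.einsum("ij,mkj->mik", Binv, U)
        r = None
        for q in (q1, q2):
            hf = np.einsum("mij,nj->mni", A, q)
            rc = np.max(np.abs(hf - nearest_integer(hf)), axis=2)
            r = rc if r is None else np.minimum(r, rc)
        m = r <= delta
        S[lo:lo + chunk] = m.sum(axis=1)
        tot[lo:lo + chunk] = np.where(m, r, 0.0).sum(axis=1)
    return S, tot


def assign_color_probabilities(residual_1: np.ndarray, residual_2: np.ndarray,
                               delta: float) -> list[ColorAssignment]:
    """Per-peak color probabilities from the two residuals.

    The probability of color j is the *other* color's share of the summed
    residual: ``p_1 = e_2 / (e_1 + e_2)`` -- the smaller residual gets the
    larger probability, the probabilities sum to one, and equal residuals
    give the ambiguous 0.5/0.5.  A peak is assigned to the color with
    probability > 0.5 if it is matched at all (min residual <= delta);
    otherwise it stays unassigned (probabilities are still reported).
    """
    r1 = np.asarray(residual_1, dtype=float)
    r2 = np.asarray(residual_2, dtype=float)
    tot = r1 + r2
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(tot > 0, r2 / tot, 0.5)
    p2 = 1.0 - p1
    matched = np.minimum(r1, r2) <= delta
    out = []
    for i in range(len(r1)):
        if matched[i] and p1[i] > 0.5:
            color = 1
        elif matched[i] and p2[i] > 0.5:
            color = 2
        else:
            color = 0
        out.append(ColorAssignment(i, float(r1[i]), float(r2[i]),
                                   float(p1[i]), float(p2[i]), color,
                                   bool(matched[i])))
    return out


# ---------------------------------------------------------------------------
# global refinement
# ---------------------------------------------------------------------------

def refine_solution(U0: np.ndarray, cell: UnitCell, q_group1: np.ndarray,
                    q_group2: np.ndarray
                    ) -> tuple[np.ndarray, RefinementReport]:
    """Polish a rotation against both color groups jointly.

    Minimizes the sum of squared fractional-index deviations from the
    integer targets over both groups, with the targets frozen at their
    values under ``U0`` and the rotation parametrized as an axis-angle
    perturbation composed with ``U0`` (exactly orthonormal at every
    evaluation).  Never returns a rotation with a larger objective than
    ``U0``.
    """
    q_group1 = np.atleast_2d(q_group1) if len(q_group1) else np.empty((0, 3))
    q_group2 = np.atleast_2d(q_group2) if len(q_group2) else np.empty((0, 3))
    n_total = len(q_group1) + len(q_group2)
    if n_total < 3:
        return U0, RefinementReport(np.nan, np.nan, 0, False)
    Binv = cell.b_inverse

    targets = []
    for q in (q_group1, q_group2):
        hf = (Binv @ U0.T @ q.T).T if len(q) else np.empty((0, 3))
        targets.append(nearest_integer(hf))

    def objective(w: np.ndarray) -> float:
        U = Rotation.from_rotvec(w).as_matrix() @ U0
        A = Binv @ U.T
        f = 0.0
        for q, hi in zip((q_group1, q_group2), targets):
            if len(q):
                f += float(np.sum(((q @ A.T) - hi) ** 2))
        return f

    f0 = objective(np.zeros(3))
    res = minimize(objective, np.zeros(3), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 200})
    if np.isfinite(res.fun) and res.fun <= f0:
        U = Rotation.from_rotvec(res.x).as_matrix() @ U0
        return U, RefinementReport(f0, float(res.fun), int(res.nit), True)
    return U0, RefinementReport(f0, f0, int(res.nit), False)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def index_two_color(fs: np.ndarray, ss: np.ndarray, snr: np.ndarray,
                    intensity: np.ndarray, table: ReferenceTable,
                    geom: DetectorGeometry, setup: ExperimentSetup,
                    params: IndexerParams = IndexerParams()
                    ) -> TwoColorSolution | None:
    """Index one two-color pattern from its detector peak list.

    Workflow: convert every peak to reciprocal vectors under both
    wavelengths; select seed pairs once from peaks inside the reference
    table's resolution range under both wavelengths (peak-pair ranking is
    color independent); run the reference search under each wavelength
    independently; score *all* rotation candidates from both searches with
    the two-color score; keep the best; assign color probabilities; split
    the peak list into the two color groups; refine globally; re-score.

    Returns ``None`` when no candidate reaches the acceptance score.
    """
    fs = np.asarray(fs, dtype=float)
    if len(fs) < 2:
        raise NotIndexableError("need at least 2 peaks")
    cell = table.cell
    q1 = pixel_to_q(fs, ss, geom, setup.wavelength_1)
    q2 = pixel_to_q(fs, ss, geom, setup.wavelength_2)
    l1 = np.linalg.norm(q1, axis=1)
    l2 = np.linalg.norm(q2, axis=1)
    _, hi = table.length_range
    eligible = np.maximum(l1, l2) <= hi + params.tol_len
    if eligible.sum() < 2:
        raise NotIndexableError(
            "fewer than 2 peaks inside the reference table's resolution range")

    if params.sort_key == "snr":
        key, desc = np.asarray(snr, dtype=float), True
    elif params.sort_key == "intensity":
        key, desc = np.asarray(intensity, dtype=float), True
    else:  # resolution: best (highest) resolution first = largest radius
        key = np.hypot(fs - geom.beam_center[0], ss - geom.beam_center[1])
        desc = True
    pairs = select_peak_pairs(key, params, eligible, descending=desc)

    best = None  # (S, tot, color, rank, U, pair, hkl)
    for color, q in ((1, q1), (2, q2)):
        for block in generate_candidates(q, pairs, table, params):
            S, tot = score_batch_two_color(block.rotations, cell, q1, q2,
                                           params.delta)
            ties = np.flatnonzero(S == S.max())
            m = int(ties[np.argmin(tot[ties])])
            cand = (int(S[m]), float(tot[m]), color, block.seed_rank,
                    block.rotations[m], block.seed_pair)
            if best is None or cand[0] > best[0] or (
                    cand[0] == best[0] and cand[1] < best[1] - 1e-12):
                best = cand

    min_score = params.resolve_min_score(len(fs))
    if best is None or best[0] < min_score:
        return None
    S0, tot0, seed_color, seed_rank, U0, seed_pair = best

    # color split at the unrefined solution, then global refinement
    _, r1, r2 = score_two_color(U0, cell, q1, q2, params.delta)
    assignments = assign_color_probabilities(r1, r2, params.delta)
    g1 = np.array([a.peak_id for a in assignments if a.assigned_color == 1],
                  dtype=int)
    g2 = np.array([a.peak_id for a in assignments if a.assigned_color == 2],
                  dtype=int)
    U, report = refine_solution(U0, cell, q1[g1], q2[g2])

    # re-score and re-split at the refined rotation
    S, r1, r2 = score_two_color(U, cell, q1, q2, params.delta)
    assignments = assign_color_probabilities(r1, r2, params.delta)
    g1 = np.array([a.peak_id for a in assignments if a.assigned_color == 1],
                  dtype=int)
    g2 = np.array([a.peak_id for a in assignments if a.assigned_color == 2],
                  dtype=int)
    if S < S0:
        # refinement must never lose matched peaks; fall back
        U, S = U0, S0
        _, r1, r2 = score_two_color(U, cell, q1, q2, params.delta)
        assignments = assign_color_probabilities(r1, r2, params.delta)
        g1 = np.array([a.peak_id for a in assignments if a.assigned_color == 1],
                      dtype=int)
        g2 = np.array([a.peak_id for a in assignments if a.assigned_color == 2],
                      dtype=int)
        report = RefinementReport(report.objective_initial,
                                  report.objective_initial, report.n_iterations,
                                  False)
    matched_min = np.minimum([a.residual_1 for a in assignments],
                             [a.residual_2 for a in assignments])
    tot = float(np.sum(np.where(matched_min <= params.delta, matched_min, 0.0)))
    return TwoColorSolution(U, int(S), assignments, g1, g2, report,
                            seed_pair, seed_rank, seed_color, tot)
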