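"""Monochromatic reference-table indexing engine.

Given a still pattern's reciprocal vectors (all assumed to share one
wavelength), the engine selects a few seed peak pairs, looks up matching
reflection pairs in the reference table by their orientation-invariant
(length, length, angle) triple, solves a candidate rotation U for every
hypothesis, and scores each candidate by the number of peaks whose
fractional Miller index ``h_f = (U B)^{-1} q`` falls within ``delta`` of
the nearest integers in every component.  The candidate with the most
matched peaks wins; ties break by smaller summed residual over matched
peaks, then by earlier seed-pair rank.

The engine works purely on q-vectors so that the two-color layer can run
it once per wavelength and pool the rotation candidates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .geometry import UnitCell
from .reftable import ReferenceTable


class NotIndexableError(ValueError):
    """Pattern cannot be indexed at all (fewer than two usable peaks)."""


class DegeneratePairError(ValueError):
    """Collinear vector pair: carries no orientation information."""


@dataclass(frozen=True)
class IndexerParams:
    """Tunable search parameters.

    delta:
        Matching threshold on the max-component deviation of the
        fractional Miller index from the nearest integers.
    n_pairs:
        Number of top-ranked seed peak pairs to try.
    sort_key:
        Peak-pair ranking key: "intensity", "snr" (descending sum) or
        "resolution" (best resolution first, i.e. largest scattering
        angle first).
    tol_len, tol_angle:
        Reference-table matching tolerances, in 1/Angstrom and degrees.
    min_score:
        Minimum matched peaks to accept a solution; ``None`` means
        ``max(6, ceil(0.4 * n_peaks))``.
    """

    delta: float = 0.25
    n_pairs: int = 5
    sort_key: str = "snr"
    tol_len: float = 0.0025
    tol_angle: float = 1.0
    min_score: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.delta <= 0.5:
            raise ValueError("delta must lie in (0, 0.5]")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.sort_key not in ("intensity", "snr", "resolution"):
            raise ValueError(f"unknown sort_key {self.sort_key!r}")

    def resolve_min_score(self, n_peaks: int) -> int:
        if self.min_score is not None:
            return self.min_score
        return max(6, math.ceil(0.4 * n_peaks))


@dataclass
class MatchRecord:
    peak_id: int
    hkl_frac: np.ndarray
    hkl_int: np.ndarray
    residual: float
    matched: bool


@dataclass
class IndexingSolution:
    """Best rotation found for one pattern under one wavelength."""

    rotation: np.ndarray
    score: int
    match_records: list[MatchRecord]
    seed_pair: tuple[int, int]
    seed_rank: int
    seed_hkl: tuple[tuple[int, int, int], tuple[int, int, int]]
    total_residual: float


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def nearest_integer(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (pinned tie rule; ties are measure-zero)."""
    return np.trunc(x + np.copysign(0.5, x))


def select_peak_pairs(key_values: np.ndarray, params: IndexerParams,
                      eligible: np.ndarray | None = None,
                      descending: bool = True) -> list[tuple[int, int]]:
    """Rank all eligible peak pairs and return the top ``n_pairs``.

    A pair's key is the sum of its two peaks' key values.  Ranking is by
    descending key (ascending if ``descending`` is False), with a
    deterministic lexicographic peak-index tie-break.
    """
    n = len(key_values)
    idx = np.arange(n) if eligible is None else np.flatnonzero(eligible)
    if len(idx) < 2:
        raise NotIndexableError("need at least 2 peaks to form a pair")
    pairs = list(itertools.combinations(idx.tolist(), 2))
    sign = -1.0 if descending else 1.0
    pairs.sort(key=lambda p: (sign * (key_values[p[0]] + key_values[p[1]]),
                              p[0], p[1]))
    return pairs[:params.n_pairs]


def _triad(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal triad spanned by two non-collinear vectors."""
    e1 = v1 / np.linalg.norm(v1)
    c = np.cross(v1, v2)
    nc = np.linalg.norm(c)
    if nc < 1e-12 * np.linalg.norm(v1) * np.linalg.norm(v2):
        raise DegeneratePairError("collinear vector pair")
    e3 = c / nc
    e2 = np.cross(e3, e1)
    return np.stack([e1, e2, e3], axis=1)


def rotations_from_pairs(q_a: np.ndarray, q_b: np.ndarray,
                         ka: np.ndarray, kb: np.ndarray) -> np.ndarray:
    """Batch of proper rotations aligning reference pairs onto an observed pair.

    ``q_a, q_b`` are one observed vector pair; ``ka, kb`` are (M, 3) arrays
    of reference vector pairs (``B @ hkl``).  Returns (M, 3, 3) rotations
    ``U`` such that ``U @ ka ~ q_a`` and ``U @ kb ~ q_b`` in the
    least-squares triad sense.  Both triads are right-handed orthonormal,
    so ``det U = +1`` by construction.
    """
    t_obs = _triad(q_a, q_b)
    ka = np.atleast_2d(ka)
    kb = np.atleast_2d(kb)
    e1 = ka / np.linalg.norm(ka, axis=1, keepdims=True)
    c = np.cross(ka, kb)
    nc = np.linalg.norm(c, axis=1, keepdims=True)
    good = nc[:, 0] > 1e-12
    e3 = np.zeros_like(c)
    e3[good] = c[good] / nc[good]
    if not good.all():
        # the table's collinearity guard should make this unreachable
        raise DegeneratePairError("collinear reference pair in batch")
    e2 = np.cross(e3, e1)
    t_ref = np.stack([e1, e2, e3], axis=2)  # (M, 3, 3), columns are the triad
    return np.einsum("ij,mkj->mik", t_obs, t_ref)


def solve_rotation(q_pair: tuple[np.ndarray, np.ndarray],
                   entry, cell: UnitCell,
                   tol_len: float = 0.0025) -> list[np.ndarray]:
    """Candidate rotations for one observed pair and one reference entry.

    Tries the direct assignment and, when both observed lengths are within
    ``tol_len`` of both reference lengths, the swapped assignment too.
    """
    q_a, q_b = (np.asarray(q, dtype=float) for q in q_pair)
    ka = cell.b_matrix @ np.asarray(entry.hkl_a, dtype=float)
    kb = cell.b_matrix @ np.asarray(entry.hkl_b, dtype=float)
    la, lb = np.linalg.norm(q_a), np.linalg.norm(q_b)
    out = []
    if (abs(la - entry.len_a) <= tol_len) and (abs(lb - entry.len_b) <= tol_len):
        out.append(rotations_from_pairs(q_a, q_b, ka, kb)[0])
    if (abs(la - entry.len_b) <= tol_len) and (abs(lb - entry.len_a) <= tol_len):
        out.append(rotations_from_pairs(q_a, q_b, kb, ka)[0])
    if not out:
        raise ValueError("observed lengths match neither assignment of entry")
    return out


def fractional_hkl(U: np.ndarray, cell: UnitCell, q: np.ndarray) -> np.ndarray:
    """Fractional Miller indices ``(U B)^{-1} q`` for an (N, 3) q array."""
    A = cell.b_inverse @ U.T
    return np.atleast_2d(q) @ A.T


def score_solution(U: np.ndarray, cell: UnitCell, q: np.ndarray,
                   delta: float) -> tuple[int, list[MatchRecord]]:
    """Count matched peaks under rotation *U* and report per-peak records."""
    hf = fractional_hkl(U, cell, q)
    hi = nearest_integer(hf)
    res = np.max(np.abs(hf - hi), axis=1)
    matched = res <= delta
    records = [MatchRecord(i, hf[i], hi[i].astype(int), float(res[i]),
                           bool(matched[i]))
               for i in range(len(hf))]
    return int(matched.sum()), records


def score_batch(Us: np.ndarray, cell: UnitCell, q: np.ndarray, delta: float,
                chunk: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized scores for a stack of rotations.

    Returns ``(S, total_residual)`` arrays of shape (M,), where
    ``total_residual`` sums residuals over matched peaks only (the
    deterministic tie-break quantity).
    """
    Us = np.atleast_3d(Us).reshape(-1, 3, 3)
    S = np.zeros(len(Us), dtype=int)
    tot = np.zeros(len(Us))
    Binv = cell.b_inverse
    for lo in range(0, len(Us), chunk):
        U = Us[lo:lo + chunk]
        A = np.einsum("ij,mkj->mik", Binv, U)  # Binv @ U^T, (m, 3, 3)
        hf = np.einsum("mij,nj->mni", A, q)
        res = np.max(np.abs(hf - nearest_integer(hf)), axis=2)
        m = res <= delta
        S[lo:lo + chunk] = m.sum(axis=1)
        tot[lo:lo + chunk] = np.where(m, res, 0.0).sum(axis=1)
    return S, tot


# ---------------------------------------------------------------------------
# candidate generation and the monochromatic driver
# ---------------------------------------------------------------------------

@dataclass
class CandidateBlock:
    """All rotation hypotheses generated from one seed pair."""

    seed_rank: int
    seed_pair: tuple[int, int]
    rotations: np.ndarray      # (M, 3, 3)
    hkl_a: np.ndarray          # (M, 3)
    hkl_b: np.ndarray          # (M, 3)


def generate_candidates(q: np.ndarray, pairs: Sequence[tuple[int, int]],
                        table: ReferenceTable, params: IndexerParams
                        ) -> Iterator[CandidateBlock]:
    """Rotation hypotheses for each seed pair via reference-table lookup."""
    for rank, (i, j) in enumerate(pairs):
        qa, qb = q[i], q[j]
        la, lb = np.linalg.norm(qa), np.linalg.norm(qb)
        if la > lb:
            (qa, qb), (la, lb) = (qb, qa), (lb, la)
        cross = np.linalg.norm(np.cross(qa, qb))
        if cross < 1e-12:
            continue
        angle = float(np.degrees(np.arccos(
            np.clip(qa @ qb / (la * lb), -1.0, 1.0))))
        ka, kb, ha, hb = table.query_vectors(la, lb, angle,
                                             params.tol_len, params.tol_angle)
        if len(ka) == 0:
            continue
        U = rotations_from_pairs(qa, qb, ka, kb)
        yield CandidateBlock(rank, (i, j), U, ha, hb)


def index_monochromatic(q: np.ndarray, table: ReferenceTable,
                        params: IndexerParams,
                        pairs: Sequence[tuple[int, int]] | None = None,
                        key_values: np.ndarray | None = None
                        ) -> IndexingSolution | None:
    """Best-scoring rotation for a single-wavelength q list, or ``None``.

    ``pairs`` overrides seed-pair selection (the two-color layer passes a
    shared pair list); otherwise pairs are ranked by ``key_values``
    (default: uniform, i.e. pure index order) restricted to peaks whose
    length is within the table's range plus tolerance.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if len(q) < 2:
        raise NotIndexableError("need at least 2 peaks")
    cell = table.cell
    if pairs is None:
        lengths = np.linalg.norm(q, axis=1)
        lo, hi = table.length_range
        eligible = lengths <= hi + params.tol_len
        if key_values is None:
            key_values = np.zeros(len(q))
        pairs = select_peak_pairs(key_values, params, eligible)

    best: IndexingSolution | None = None
    min_score = params.resolve_min_score(len(q))
    for block in generate_candidates(q, pairs, table, params):
        S, tot = score_batch(block.rotations, cell, q, params.delta)
        # best inside the block: max S, then min matched residual
        ties = np.flatnonzero(S == S.max())
        m = int(ties[np.argmin(tot[ties])])
        if best is None or S[m] > best.score or (
                S[m] == best.score and tot[m] < best.total_residual - 1e-12):
            _, records = score_solution(block.rotations[m], cell, q, params.delta)
            best = IndexingSolution(
                rotation=block.rotations[m], score=int(S[m]),
                match_records=records, seed_pair=block.seed_pair,
                seed_rank=block.seed_rank,
                seed_hkl=(tuple(int(x) for x in block.hkl_a[m]),
                          tuple(int(x) for x in block.hkl_b[m])),
                total_residual=float(tot[m]))
    if best is None or best.score < min_score:
        return None
    return best
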