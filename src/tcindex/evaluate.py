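"""Metrics against ground truth: orientation error, rates, color accuracy.

The Euler convention is intrinsic z-y-x ("ZYX" in scipy), pinned to match
the simulator's worked examples; for a P1 triclinic lattice the proper
rotation group is trivial, so no symmetry-equivalent minimization applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

EULER_CONVENTION = "ZYX"


def _check_rotation(U: np.ndarray) -> np.ndarray:
    U = np.asarray(U, dtype=float)
    if U.shape != (3, 3) or not np.allclose(U @ U.T, np.eye(3), atol=1e-6) \
            or np.linalg.det(U) < 0:
        raise ValueError("input is not a proper rotation matrix")
    return U


def euler_angles(U: np.ndarray) -> np.ndarray:
    """Euler angles (degrees) of a rotation in the pinned convention."""
    return Rotation.from_matrix(U).as_euler(EULER_CONVENTION, degrees=True)


def orientation_error(U_est: np.ndarray, U_true: np.ndarray
                      ) -> tuple[float, np.ndarray]:
    """Total angular distance and per-Euler-angle absolute errors, degrees.

    The total error is the rotation angle of ``U_est @ U_true.T``; the
    per-angle errors are the minimal absolute circular differences of the
    two Euler decompositions.
    """
    U_est = _check_rotation(U_est)
    U_true = _check_rotation(U_true)
    total = float(Rotation.from_matrix(U_est @ U_true.T).magnitude()
                  * 180.0 / np.pi)
    d = euler_angles(U_est) - euler_angles(U_true)
    d = np.abs((d + 180.0) % 360.0 - 180.0)
    return total, d


@dataclass
class EvaluationReport:
    n_total: int
    n_indexed: int
    indexing_rate: float
    n_indexable: int
    utility: float
    angular_errors: np.ndarray           # (n_indexed,) total error, degrees
    euler_errors: np.ndarray             # (n_indexed, 3) per-angle abs errors
    median_angular_error: float
    median_euler_error: float            # median over all angles and patterns
    frac_euler_below_02: float           # fraction of per-angle errors < 0.2 deg
    color_accuracy: float                # over matched, unambiguous peaks
    n_color_checked: int

    def summary(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_indexed": self.n_indexed,
            "indexing_rate": self.indexing_rate,
            "n_indexable": self.n_indexable,
            "utility": self.utility,
            "median_angular_error_deg": self.median_angular_error,
            "median_euler_error_deg": self.median_euler_error,
            "frac_euler_errors_below_0.2deg": self.frac_euler_below_02,
            "color_accuracy": self.color_accuracy,
            "n_color_checked": self.n_color_checked,
        }


def evaluate_dataset(solutions: dict, patterns: dict,
                     min_peaks_indexable: int = 6) -> EvaluationReport:
    """Aggregate metrics for a dataset.

    Parameters
    ----------
    solutions:
        Mapping pattern_id -> TwoColorSolution or None.
    patterns:
        Mapping pattern_id -> SimulatedPattern (the truth manifest).
    min_peaks_indexable:
        A pattern counts as indexable when it has at least this many peaks
        (the utility denominator).
    """
    ids = sorted(patterns)
    missing = set(solutions) - set(ids)
    if missing:
        raise KeyError(f"solutions for unknown pattern ids: {sorted(missing)}")
    totals, eulers = [], []
    n_indexed = 0
    n_indexable = 0
    n_color_ok = 0
    n_color_checked = 0
    for pid in ids:
        pat = patterns[pid]
        if pat.n_peaks >= min_peaks_indexable:
            n_indexable += 1
        sol = solutions.get(pid)
        if sol is None:
            continue
        n_indexed += 1
        tot, d = orientation_error(sol.rotation, pat.true_rotation)
        totals.append(tot)
        eulers.append(d)
        # color accuracy over matched peaks with a clear residual margin
        for a in sol.assignments:
            if not a.matched or a.assigned_color == 0:
                continue
            if abs(a.residual_1 - a.residual_2) <= 0.05:
                continue  # indexable under both colors: excluded, counted
            n_color_checked += 1
            if a.assigned_color == int(pat.true_color[a.peak_id]):
                n_color_ok += 1
    totals = np.array(totals)
    eulers = np.array(eulers).reshape(-1, 3) if eulers else np.empty((0, 3))
    return EvaluationReport(
        n_total=len(ids),
        n_indexed=n_indexed,
        indexing_rate=n_indexed / len(ids) if ids else 0.0,
        n_indexable=n_indexable,
        utility=n_indexed / n_indexable if n_indexable else 0.0,
        angular_errors=totals,
        euler_errors=eulers,
        median_angular_error=float(np.median(totals)) if len(totals) else np.nan,
        median_euler_error=float(np.median(eulers)) if eulers.size else np.nan,
        frac_euler_below_02=float(np.mean(eulers < 0.2)) if eulers.size else np.nan,
        color_accuracy=n_color_ok / n_color_checked if n_color_checked else np.nan,
        n_color_checked=n_color_checked,
    )
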