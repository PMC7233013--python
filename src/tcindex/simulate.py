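"""Two-color still-diffraction pattern simulator with ground truth.

The model is purely geometric: reciprocal-lattice points are spheres of a
fixed radius, and a reflection is excited under a given photon energy when
its lattice point lies within that radius of the corresponding Ewald
sphere's surface.  Excited points are snapped radially onto the sphere
(the detector records where the Ewald sphere cuts the spot) and projected
to detector pixels; spots that miss the panel are dropped.  Structure
factors, partiality, mosaicity and detector noise are deliberately absent
-- peak positions and colors are exact, which is what an indexing test
needs.  All peaks carry intensity = snr = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (DetectorGeometry, ExperimentSetup, UnitCell,
                       q_to_pixel)
from .reftable import enumerate_reflections

#: Cell of the protein crystal used for the default simulated dataset
#: (PDB entry 5m2t, space group P1).
DEFAULT_CELL = UnitCell(64.3, 72.0, 89.2, 110.6, 107.5, 85.8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    sphere_radius:
        Lattice-point radius in 1/Angstrom.  The default 3e-4 makes a
        typical pattern on the default cell/geometry carry some tens of
        peaks per color (the expected count is ~ sum of r/|q| over
        reflections in range, ~68 per color before detector clipping).
    d_min:
        Resolution cutoff of simulated spots, Angstrom.  Deliberately
        higher resolution (3.0) than the default 5.0 reference table used
        for indexing, so indexing must cope with peaks outside its table.
    pixel_jitter:
        Gaussian sigma (pixels) added to spot centroids; 0 = exact.
    """

    cell: UnitCell = DEFAULT_CELL
    geom: DetectorGeometry = DetectorGeometry()
    setup: ExperimentSetup = ExperimentSetup(7.0, 9.0)
    sphere_radius: float = 3e-4
    d_min: float = 3.0
    seed: int = 0
    n_patterns: int = 100
    pixel_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")
        if self.d_min <= 0:
            raise ValueError("d_min must be positive")


@dataclass
class SimulatedPattern:
    """One still pattern with per-peak ground truth."""

    pattern_id: int
    true_rotation: np.ndarray          # (3, 3)
    fs: np.ndarray                     # (N,) pixel coordinates
    ss: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray
    true_color: np.ndarray             # (N,) int8, 1 or 2
    true_hkl: np.ndarray               # (N, 3) int
    dual_excitable: np.ndarray         # (N,) bool: within radius of BOTH spheres
    q_true: np.ndarray                 # (N, 3) on-sphere q at the true color

    @property
    def n_peaks(self) -> int:
        return len(self.fs)


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed proper rotation (normalized-quaternion method)."""
    quat = rng.normal(size=4)
    w, x, y, z = quat / np.linalg.norm(quat)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _ewald_distance(q: np.ndarray, wavelength: float) -> np.ndarray:
    """Signed-free distance of lattice points from the Ewald sphere surface."""
    k = 1.0 / wavelength
    return np.abs(np.linalg.norm(q + np.array([0.0, 0.0, k]), axis=1) - k)


def _snap_to_sphere(q: np.ndarray, wavelength: float) -> np.ndarray:
    """Project lattice points radially onto the Ewald sphere surface."""
    k = 1.0 / wavelength
    center = np.array([0.0, 0.0, -k])
    v = q - center
    return center + v * (k / np.linalg.norm(v, axis=1, keepdims=True))


def simulate_pattern(config: SimulationConfig, U_true: np.ndarray,
                     pattern_id: int = 0,
                     rng: np.random.Generator | None = None,
                     hkl: np.ndarray | None = None) -> SimulatedPattern:
    """Simulate one two-color still pattern at a known orientation.

    Reflections are enumerated to ``config.d_min``; an empty pattern is a
    valid outcome (generic orientations with a tiny sphere radius excite
    nothing).  Peaks are emitted color 1 first, each color in lexicographic
    hkl order, so a two-color pattern is exactly the concatenation of the
    two single-color simulations at the same orientation.
    """
    cell = config.cell
    if hkl is None:
        hkl = enumerate_reflections(cell, config.d_min)
    q_all = (U_true @ cell.b_matrix @ hkl.T).T
    lams = config.setup.wavelengths
    dist = np.stack([_ewald_distance(q_all, lam) for lam in lams], axis=1)
    excited = dist <= config.sphere_radius
    dual = excited.all(axis=1)

    fs_l, ss_l, col_l, hkl_l, dual_l, q_l = [], [], [], [], [], []
    for color, lam in enumerate(lams, start=1):
        sel = np.flatnonzero(excited[:, color - 1])
        if len(sel) == 0:
            continue
        q_on = _snap_to_sphere(q_all[sel], lam)
        fs, ss, on = q_to_pixel(q_on, config.geom, lam)
        if config.pixel_jitter > 0 and rng is not None:
            fs = fs + rng.normal(scale=config.pixel_jitter, size=len(fs))
            ss = ss + rng.normal(scale=config.pixel_jitter, size=len(ss))
        keep = on
        fs_l.append(fs[keep])
        ss_l.append(ss[keep])
        col_l.append(np.full(keep.sum(), color, dtype=np.int8))
        hkl_l.append(hkl[sel][keep])
        dual_l.append(dual[sel][keep])
        q_l.append(q_on[keep])

    if fs_l:
        fs = np.concatenate(fs_l)
        ss = np.concatenate(ss_l)
        color = np.concatenate(col_l)
        hkl_out = np.concatenate(hkl_l)
        dual_out = np.concatenate(dual_l)
        q_out = np.concatenate(q_l)
    else:
        fs = ss = np.empty(0)
        color = np.empty(0, dtype=np.int8)
        hkl_out = np.empty((0, 3), dtype=int)
        dual_out = np.empty(0, dtype=bool)
        q_out = np.empty((0, 3))
    n = len(fs)
    return SimulatedPattern(pattern_id, np.asarray(U_true), fs, ss,
                            np.ones(n), np.ones(n), color, hkl_out,
                            dual_out, q_out)


def simulate_dataset(config: SimulationConfig) -> list[SimulatedPattern]:
    """Simulate ``config.n_patterns`` patterns at seeded random orientations.

    Each pattern draws its orientation (and optional jitter) from an
    independent child stream of the dataset seed, so the output is
    reproducible pattern-by-pattern.
    """
    if config.n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    hkl = enumerate_reflections(config.cell, config.d_min)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patterns)
    out = []
    for i, ss_ in enumerate(streams):
        rng = np.random.default_rng(ss_)
        U = random_orientation(rng)
        out.append(simulate_pattern(config, U, pattern_id=i, rng=rng, hkl=hkl))
    return out


def expected_peaks_per_color(config: SimulationConfig) -> float:
    """Geometric expectation of excited spots per color (shell estimate).

    For a reflection of length g, the probability over uniform orientations
    of lying within ``r`` of an Ewald sphere surface is ~ r/g (band area of
    the orientation sphere).  Detector clipping is ignored, so this is an
    upper bound within tens of percent for the default geometry.
    """
    hkl = enumerate_reflections(config.cell, config.d_min)
    g = np.linalg.norm(hkl @ config.cell.b_matrix.T, axis=1)
    return float(np.minimum(config.sphere_radius / g, 1.0).sum())
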