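"""Unit-cell and detector geometry mathematics.

Conventions used throughout the package (they are pinned here once and
relied on everywhere else):

* Reciprocal space uses the crystallographic convention ``|k| = 1/lambda``
  (no factor of 2*pi), so a resolution cutoff of ``d`` Angstrom corresponds
  to ``|q| <= 1/d`` inverse Angstrom.
* Laboratory frame: X-ray beam along +z, detector plane perpendicular to
  the beam at ``z = distance``; detector fast axis = +x, slow axis = +y.
* Pixel coordinates are 0-based with pixel centres on integer coordinates.
* The reciprocal basis matrix ``B`` is in the Busing-Levy orientation:
  a* along x, b* in the x-y plane.  Only the product ``U @ B`` is physical,
  but a fixed convention keeps tests and serialized solutions well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

#: hc in keV * Angstrom; divides photon energy to give wavelength.
HC_KEV_ANGSTROM = 12.39841984


class InvalidCellError(ValueError):
    """Raised when triclinic cell parameters do not define a real lattice."""


def energy_to_wavelength(energy_kev: float) -> float:
    """Photon energy in keV -> wavelength in Angstrom."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell with its reciprocal orthogonalization matrix.

    Parameters
    ----------
    a, b, c:
        Cell edge lengths in Angstrom.
    alpha, beta, gamma:
        Cell angles in degrees.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidCellError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise InvalidCellError("cell angles must lie in (0, 180) degrees")
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0.0:
            raise InvalidCellError(
                "angle combination gives non-positive cell volume")

    @cached_property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom (standard triclinic formula)."""
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return float(self.a * self.b * self.c
                     * np.sqrt(1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg))

    @cached_property
    def reciprocal_parameters(self) -> tuple[float, float, float, float, float, float]:
        """(a*, b*, c*, alpha*, beta*, gamma*) in 1/Angstrom and degrees."""
        a, b, c = self.a, self.b, self.c
        al, be, ga = (np.radians(x) for x in (self.alpha, self.beta, self.gamma))
        v = self.volume
        a_s = b * c * np.sin(al) / v
        b_s = a * c * np.sin(be) / v
        c_s = a * b * np.sin(ga) / v
        cos_al_s = (np.cos(be) * np.cos(ga) - np.cos(al)) / (np.sin(be) * np.sin(ga))
        cos_be_s = (np.cos(al) * np.cos(ga) - np.cos(be)) / (np.sin(al) * np.sin(ga))
        cos_ga_s = (np.cos(al) * np.cos(be) - np.cos(ga)) / (np.sin(al) * np.sin(be))
        return (float(a_s), float(b_s), float(c_s),
                float(np.degrees(np.arccos(cos_al_s))),
                float(np.degrees(np.arccos(cos_be_s))),
                float(np.degrees(np.arccos(cos_ga_s))))

    @cached_property
    def b_matrix(self) -> np.ndarray:
        """3x3 matrix whose columns are a*, b*, c* (Busing-Levy frame).

        For an integer triple ``h``, ``B @ h`` is that reflection's
        reciprocal vector in the crystal-fixed frame, in 1/Angstrom.
        """
        return build_b_matrix(self)

    @cached_property
    def b_inverse(self) -> np.ndarray:
        return np.linalg.inv(self.b_matrix)


def build_b_matrix(cell: UnitCell) -> np.ndarray:
    """Construct the reciprocal orthogonalization matrix B for *cell*.

    Busing-Levy orientation: a* along +x, b* in the x-y plane with positive
    y component.  Columns are the reciprocal basis vectors in 1/Angstrom.
    """
    a_s, b_s, c_s, al_s, be_s, ga_s = cell.reciprocal_parameters
    al = np.radians(cell.alpha)
    cg_s, sg_s = np.cos(np.radians(ga_s)), np.sin(np.radians(ga_s))
    cb_s, sb_s = np.cos(np.radians(be_s)), np.sin(np.radians(be_s))
    B = np.array([
        [a_s, b_s * cg_s, c_s * cb_s],
        [0.0, b_s * sg_s, -c_s * sb_s * np.cos(al)],
        [0.0, 0.0, 1.0 / cell.c],
    ])
    return B


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat single-panel detector perpendicular to the beam.

    ``distance`` and ``pixel_size`` are in meters; ``beam_center`` is the
    (fast, slow) pixel coordinate pierced by the direct beam.
    """

    n_fast: int = 1440
    n_slow: int = 1440
    pixel_size: float = 100e-6
    distance: float = 0.1
    beam_center: tuple[float, float] = (719.5, 719.5)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.distance <= 0:
            raise ValueError("pixel_size and distance must be positive")


@dataclass(frozen=True)
class ExperimentSetup:
    """The two photon energies of a two-color experiment.

    Equal energies are allowed and degrade gracefully to monochromatic
    behaviour in all downstream code.
    """

    energy_1: float = 7.0
    energy_2: float = 9.0

    @property
    def wavelength_1(self) -> float:
        return energy_to_wavelength(self.energy_1)

    @property
    def wavelength_2(self) -> float:
        return energy_to_wavelength(self.energy_2)

    @property
    def wavelengths(self) -> tuple[float, float]:
        return (self.wavelength_1, self.wavelength_2)


def pixel_to_q(fs, ss, geom: DetectorGeometry, wavelength: float) -> np.ndarray:
    """Convert detector pixel coordinates to reciprocal vectors.

    With the beam along +z and ``k_in = (0, 0, 1/lambda)``, the scattering
    vector is ``q = k_out - k_in`` where ``k_out`` points from the sample to
    the pixel with ``|k_out| = 1/lambda``.  Every returned q therefore lies
    exactly on the Ewald sphere of *wavelength*.

    Accepts scalars or arrays; returns shape (3,) or (N, 3) in 1/Angstrom.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    fs = np.asarray(fs, dtype=float)
    ss = np.asarray(ss, dtype=float)
    scalar = fs.ndim == 0
    x = (fs - geom.beam_center[0]) * geom.pixel_size
    y = (ss - geom.beam_center[1]) * geom.pixel_size
    z = np.full_like(np.atleast_1d(x), geom.distance)
    r = np.stack([np.atleast_1d(x), np.atleast_1d(y), z], axis=-1)
    k_out = r / np.linalg.norm(r, axis=-1, keepdims=True) / wavelength
    q = k_out - np.array([0.0, 0.0, 1.0 / wavelength])
    return q[0] if scalar else q


def q_to_pixel(q, geom: DetectorGeometry, wavelength: float):
    """Project reciprocal vectors on the Ewald sphere back to pixels.

    Inverse of :func:`pixel_to_q` for on-detector reflections.  Returns
    ``(fs, ss, on_detector)``; ``on_detector`` is False for diffracted beams
    that miss the panel or travel backwards, and for unreachable reflections
    with ``|q| > 2/lambda`` (beyond the back-scattering limit), where pixel
    coordinates are NaN.
    """
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 1
    q2 = np.atleast_2d(q)
    k = 1.0 / wavelength
    k_out = q2 + np.array([0.0, 0.0, k])
    norm = np.linalg.norm(k_out, axis=-1)
    qlen = np.linalg.norm(q2, axis=-1)
    reachable = qlen <= 2.0 * k + 1e-12
    forward = k_out[:, 2] > 0
    ok = reachable & forward
    fs = np.full(q2.shape[0], np.nan)
    ss = np.full(q2.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = geom.distance / k_out[:, 2]
        x = k_out[:, 0] * scale
        y = k_out[:, 1] * scale
    fs_ok = x[ok] / geom.pixel_size + geom.beam_center[0]
    ss_ok = y[ok] / geom.pixel_size + geom.beam_center[1]
    fs[ok] = fs_ok
    ss[ok] = ss_ok
    on_panel = ok.copy()
    on_panel[ok] &= ((fs_ok >= -0.5) & (fs_ok <= geom.n_fast - 0.5)
                     & (ss_ok >= -0.5) & (ss_ok <= geom.n_slow - 0.5))
    if scalar:
        return float(fs[0]), float(ss[0]), bool(on_panel[0])
    return fs, ss, on_panel


def ewald_residual(q, wavelength: float) -> np.ndarray:
    """| |q + k_in| - 1/lambda | -- zero for vectors on the Ewald sphere."""
    q = np.asarray(q, dtype=float)
    k = 1.0 / wavelength
    k_out = np.atleast_2d(q) + np.array([0.0, 0.0, k])
    res = np.abs(np.linalg.norm(k_out, axis=-1) - k)
    return float(res[0]) if q.ndim == 1 else res
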