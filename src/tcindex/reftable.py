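"""Orientation-independent reference table of reflection pairs.

The indexer matches an observed pair of Bragg vectors against reference
reflections of the prior unit cell through an orientation-invariant
descriptor: the two vector lengths and the angle between them (a
"reference triple").  For realistic resolution cutoffs the number of
unordered reflection pairs is enormous (the default triclinic cell at
5 Angstrom has ~12k reflections, i.e. ~7.6e7 pairs), so the table stores
the reflection list sorted by vector length and generates the matching
pair entries lazily at query time.  A query is exactly equivalent to a
linear scan over all pairs (tested against one), without ever holding
them in memory.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

import h5py
import numpy as np

from .geometry import UnitCell


class TableTooLargeError(RuntimeError):
    """Resolution cutoff would produce more entries than the configured cap."""


class TableTooSmallError(ValueError):
    """Fewer than two reflections: no pair table can be built."""


#: Default cap on materialized pair entries.
MAX_ENTRIES = 5_000_000
#: Default cap on enumerated reflections (memory guard).
MAX_REFLECTIONS = 1_000_000


@dataclass(frozen=True)
class ReferenceEntry:
    """One unordered reflection pair in canonical order (len_a <= len_b)."""

    len_a: float
    len_b: float
    angle: float
    hkl_a: tuple[int, int, int]
    hkl_b: tuple[int, int, int]


def enumerate_reflections(cell: UnitCell, d_min: float,
                          max_reflections: int = MAX_REFLECTIONS) -> np.ndarray:
    """All integer triples (excluding the origin) with d-spacing >= d_min.

    Both Friedel mates (+hkl and -hkl) are kept: the table is built for
    space group P1 and the rotation solver then sees every sign
    combination.  Returns an (N, 3) int array in lexicographic order.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    q_max = 1.0 / d_min
    # |h| <= |a_vec| * |q| where the rows of B^-1 are the real-space axes.
    axes = cell.b_inverse  # rows: a, b, c in the Busing-Levy cartesian frame
    bounds = np.floor(np.linalg.norm(axes, axis=1) * q_max).astype(int) + 1
    est = np.prod(2 * bounds + 1)
    if est > 50 * max_reflections:
        raise TableTooLargeError(
            f"d_min={d_min} implies enumerating ~{est} index triples")
    h = np.arange(-bounds[0], bounds[0] + 1)
    k = np.arange(-bounds[1], bounds[1] + 1)
    l = np.arange(-bounds[2], bounds[2] + 1)
    hkl = np.array(np.meshgrid(h, k, l, indexing="ij")).reshape(3, -1).T
    hkl = hkl[np.any(hkl != 0, axis=1)]
    q = hkl @ cell.b_matrix.T
    keep = np.linalg.norm(q, axis=1) <= q_max + 1e-12
    hkl = hkl[keep]
    if len(hkl) > max_reflections:
        raise TableTooLargeError(
            f"{len(hkl)} reflections at d_min={d_min} exceed the cap "
            f"of {max_reflections}")
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]


class ReferenceTable:
    """Pair table over a reflection list, queried by (len, len, angle).

    Entries are unordered reflection pairs with both lengths at or below
    the resolution cutoff and an inter-vector angle in
    ``[min_angle_sep, 180 - min_angle_sep]`` degrees; near-collinear pairs
    carry no orientation information and are excluded.
    """

    def __init__(self, cell: UnitCell, hkl: np.ndarray, d_min: float,
                 min_angle_sep: float = 10.0,
                 max_entries: int = MAX_ENTRIES) -> None:
        if len(hkl) < 2:
            raise TableTooSmallError("need at least 2 reflections")
        self.cell = cell
        self.d_min = float(d_min)
        self.min_angle_sep = float(min_angle_sep)
        self.max_entries = int(max_entries)
        self.hkl = np.asarray(hkl, dtype=np.int64)
        q = self.hkl @ cell.b_matrix.T
        lengths = np.linalg.norm(q, axis=1)
        order = np.argsort(lengths, kind="stable")
        self._hkl_sorted = self.hkl[order]
        self._q_sorted = q[order]
        self._len_sorted = lengths[order]
        self._unit_sorted = q[order] / lengths[order][:, None]

    # -- basic properties -------------------------------------------------

    @property
    def n_reflections(self) -> int:
        return len(self.hkl)

    @property
    def length_range(self) -> tuple[float, float]:
        return float(self._len_sorted[0]), float(self._len_sorted[-1])

    def _pair_angles(self, ia: np.ndarray, ib: np.ndarray) -> np.ndarray:
        dots = np.einsum("ij,ij->i", self._unit_sorted[ia], self._unit_sorted[ib])
        return np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))

    def _angle_ok(self, ang: np.ndarray) -> np.ndarray:
        # exactly collinear pairs carry no orientation information and are
        # excluded even when min_angle_sep is zero; eps absorbs the arccos
        # round-off near +-1 (~1e-6 deg)
        eps = 1e-5
        return ((ang >= self.min_angle_sep) & (ang <= 180.0 - self.min_angle_sep)
                & (ang > eps) & (ang < 180.0 - eps))

    @property
    def n_entries(self) -> int:
        """Number of pair entries (computed without materializing them)."""
        n = 0
        for i in range(self.n_reflections - 1):
            ib = np.arange(i + 1, self.n_reflections)
            ang = self._pair_angles(np.full(len(ib), i), ib)
            n += int(np.sum(self._angle_ok(ang)))
        return n

    # -- query ------------------------------------------------------------

    def _candidates_for_length(self, length: float, tol: float) -> np.ndarray:
        lo = np.searchsorted(self._len_sorted, length - tol, side="left")
        hi = np.searchsorted(self._len_sorted, length + tol, side="right")
        return np.arange(lo, hi)

    def query_arrays(self, len_a: float, len_b: float, angle: float,
                     tol_len: float, tol_angle: float
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Matching *ordered* pairs as index arrays into the sorted lists.

        Returns every assignment ``(ia, ib)`` of distinct reflections with
        ``|length[ia] - len_a| <= tol_len``, ``|length[ib] - len_b| <= tol_len``
        and the inter-vector angle within ``tol_angle`` of *angle* (and
        inside the collinearity guard band).  When the two observed lengths
        are within tolerance of each other this naturally contains both
        assignments of each unordered pair, which is exactly the set of
        rotation hypotheses the solver must try.
        """
        ia = self._candidates_for_length(len_a, tol_len)
        ib = self._candidates_for_length(len_b, tol_len)
        if len(ia) == 0 or len(ib) == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        IA, IB = np.meshgrid(ia, ib, indexing="ij")
        IA, IB = IA.ravel(), IB.ravel()
        distinct = IA != IB
        IA, IB = IA[distinct], IB[distinct]
        ang = self._pair_angles(IA, IB)
        ok = (np.abs(ang - angle) <= tol_angle) & self._angle_ok(ang)
        return IA[ok], IB[ok]

    def query(self, len_a: float, len_b: float, angle: float,
              tol_len: float, tol_angle: float) -> list[ReferenceEntry]:
        """Matching canonical (unordered) entries for an observed triple.

        Result is identical to scanning all pair entries linearly and
        keeping those within tolerance of ``(len_a, len_b, angle)`` with
        ``len_a <= len_b`` canonically ordered.
        """
        ia, ib = self.query_arrays(len_a, len_b, angle, tol_len, tol_angle)
        ang = self._pair_angles(ia, ib) if len(ia) else np.empty(0)
        out: list[ReferenceEntry] = []
        seen: set[tuple[int, int]] = set()
        for j in range(len(ia)):
            i1, i2 = int(ia[j]), int(ib[j])
            la, lb = self._len_sorted[i1], self._len_sorted[i2]
            if la > lb:
                # swapped-assignment hit; as a canonical entry it matches
                # the observed triple only if the direct ordering also
                # passed, which is a separate element of the hit list.
                continue
            key = (min(i1, i2), max(i1, i2))
            if key in seen:
                continue
            seen.add(key)
            out.append(ReferenceEntry(
                float(la), float(lb), float(ang[j]),
                tuple(int(x) for x in self._hkl_sorted[i1]),
                tuple(int(x) for x in self._hkl_sorted[i2])))
        return out

    def query_vectors(self, len_a: float, len_b: float, angle: float,
                      tol_len: float, tol_angle: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Matching assignments as reference vectors for the rotation solver.

        Returns ``(ka, kb, hkl_a, hkl_b)`` where ``ka[j]`` is hypothesised
        to correspond to the caller's first observed vector.
        """
        ia, ib = self.query_arrays(len_a, len_b, angle, tol_len, tol_angle)
        return (self._q_sorted[ia], self._q_sorted[ib],
                self._hkl_sorted[ia], self._hkl_sorted[ib])

    # -- materialization (small tables only) -------------------------------

    def iter_entries(self) -> Iterator[ReferenceEntry]:
        """All entries in deterministic order; guarded by the entry cap."""
        n_pairs = self.n_reflections * (self.n_reflections - 1) // 2
        if n_pairs > self.max_entries:
            raise TableTooLargeError(
                f"{n_pairs} pairs exceed the cap of {self.max_entries}; "
                "use query() on the lazy table instead")
        # deterministic order: lexicographic reflection order, i < j
        inv = np.lexsort((self.hkl[:, 2], self.hkl[:, 1], self.hkl[:, 0]))
        hkl = self.hkl[inv] if not np.array_equal(inv, np.arange(len(inv))) else self.hkl
        q = hkl @ self.cell.b_matrix.T
        lengths = np.linalg.norm(q, axis=1)
        units = q / lengths[:, None]
        for i, j in itertools.combinations(range(len(hkl)), 2):
            ang = float(np.degrees(np.arccos(np.clip(units[i] @ units[j], -1, 1))))
            if not self._angle_ok(np.array([ang]))[0]:
                continue
            a, b = (i, j) if lengths[i] <= lengths[j] else (j, i)
            yield ReferenceEntry(float(lengths[a]), float(lengths[b]), ang,
                                 tuple(int(x) for x in hkl[a]),
                                 tuple(int(x) for x in hkl[b]))

    # -- serialization ------------------------------------------------------

    def to_hdf5(self, path) -> None:
        """Cache the table; pair entries are included only when small."""
        with h5py.File(path, "w") as f:
            # track_times=False keeps the cache byte-deterministic
            f.create_dataset("/hkl", data=self.hkl, track_times=False)
            c = self.cell
            f.attrs["cell"] = [c.a, c.b, c.c, c.alpha, c.beta, c.gamma]
            f.attrs["d_min"] = self.d_min
            f.attrs["min_angle_sep"] = self.min_angle_sep
            n_pairs = self.n_reflections * (self.n_reflections - 1) // 2
            if n_pairs <= min(self.max_entries, 200_000):
                entries = list(self.iter_entries())
                pairs = np.array([e.hkl_a + e.hkl_b for e in entries],
                                 dtype=np.int64).reshape(-1, 6)
                triples = np.array([[e.len_a, e.len_b, e.angle] for e in entries],
                                   dtype=float).reshape(-1, 3)
                f.create_dataset("/hkl_pairs", data=pairs, track_times=False)
                f.create_dataset("/triples", data=triples, track_times=False)

    @classmethod
    def from_hdf5(cls, path) -> "ReferenceTable":
        with h5py.File(path, "r") as f:
            a, b, c, al, be, ga = f.attrs["cell"]
            cell = UnitCell(a, b, c, al, be, ga)
            return cls(cell, f["/hkl"][...], float(f.attrs["d_min"]),
                       float(f.attrs["min_angle_sep"]))


def build_table(cell: UnitCell, d_min: float, min_angle_sep: float = 10.0,
                max_entries: int = MAX_ENTRIES,
                max_reflections: int = MAX_REFLECTIONS) -> ReferenceTable:
    """Enumerate reflections to *d_min* and build the pair table."""
    hkl = enumerate_reflections(cell, d_min, max_reflections)
    return ReferenceTable(cell, hkl, d_min, min_angle_sep, max_entries)


def build_table_from_reflections(cell: UnitCell, hkl: np.ndarray, d_min: float,
                                 min_angle_sep: float = 10.0) -> ReferenceTable:
    return ReferenceTable(cell, hkl, d_min, min_angle_sep)
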