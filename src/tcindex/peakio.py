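"""Peak-list, dataset and solution file formats.

TSV peak lists have columns ``fs ss intensity snr`` (header optional).
Simulated datasets live in one HDF5 file with the layout::

    /patterns/<id>/peaks       (n, 4) float: fs, ss, intensity, snr
    /patterns/<id>/truth/U     (3, 3) float
    /patterns/<id>/truth/color (n,)   int
    /patterns/<id>/truth/hkl   (n, 3) int
    /patterns/<id>/truth/dual  (n,)   bool

Solutions are written as one TSV row per pattern plus an optional
per-peak classification table.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .simulate import SimulatedPattern

PEAK_COLUMNS = ["fs", "ss", "intensity", "snr"]


class PeakFileError(ValueError):
    pass


@dataclass
class PeakList:
    fs: np.ndarray
    ss: np.ndarray
    intensity: np.ndarray
    snr: np.ndarray

    def __len__(self) -> int:
        return len(self.fs)

    @classmethod
    def from_pattern(cls, pat: SimulatedPattern) -> "PeakList":
        return cls(pat.fs, pat.ss, pat.intensity, pat.snr)


def read_peaks_tsv(path) -> PeakList:
    """Read a TSV peak list; the header row is optional."""
    try:
        first = pd.read_csv(path, sep="\t", header=None, nrows=1)
    except pd.errors.EmptyDataError:
        return PeakList(*(np.empty(0) for _ in range(4)))
    has_header = first.iloc[0].astype(str).str.contains("[A-Za-z]").any()
    df = pd.read_csv(path, sep="\t",
                     header=0 if has_header else None)
    if df.shape[1] != 4:
        raise PeakFileError(
            f"{path}: expected 4 columns (fs ss intensity snr), "
            f"got {df.shape[1]}")
    df.columns = PEAK_COLUMNS
    for col in PEAK_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + (2 if has_header else 1)
            raise PeakFileError(f"{path}: malformed value in line {line}")
    return PeakList(df.fs.to_numpy(float), df.ss.to_numpy(float),
                    df.intensity.to_numpy(float), df.snr.to_numpy(float))


def write_peaks_tsv(path, peaks: PeakList) -> None:
    df = pd.DataFrame({c: getattr(peaks, c) for c in PEAK_COLUMNS})
    df.to_csv(path, sep="\t", index=False)


def write_dataset_hdf5(path, patterns: list[SimulatedPattern]) -> None:
    with h5py.File(path, "w") as f:
        for pat in patterns:
            g = f.create_group(f"patterns/{pat.pattern_id}")
            g.create_dataset("peaks", data=np.stack(
                [pat.fs, pat.ss, pat.intensity, pat.snr], axis=1))
            t = g.create_group("truth")
            t.create_dataset("U", data=pat.true_rotation)
            t.create_dataset("color", data=pat.true_color.astype(np.int8))
            t.create_dataset("hkl", data=pat.true_hkl.astype(np.int64))
            t.create_dataset("dual", data=pat.dual_excitable.astype(bool))
            t.create_dataset("q_true", data=pat.q_true)


def read_dataset_hdf5(path) -> dict[int, SimulatedPattern]:
    out = {}
    with h5py.File(path, "r") as f:
        for key in f["patterns"]:
            g = f[f"patterns/{key}"]
            peaks = g["peaks"][...]
            t = g["truth"]
            pid = int(key)
            out[pid] = SimulatedPattern(
                pattern_id=pid, true_rotation=t["U"][...],
                fs=peaks[:, 0], ss=peaks[:, 1], intensity=peaks[:, 2],
                snr=peaks[:, 3], true_color=t["color"][...],
                true_hkl=t["hkl"][...], dual_excitable=t["dual"][...],
                q_true=t["q_true"][...])
    return out


def solutions_to_frame(solutions: dict, cell_b: np.ndarray) -> pd.DataFrame:
    """Per-pattern solution table: id, score, U (row-major), A = U B."""
    rows = []
    for pid in sorted(solutions):
        sol = solutions[pid]
        if sol is None:
            continue
        U = sol.rotation
        A = U @ cell_b
        row = {"pattern_id": pid, "score": sol.score,
               "n_color1": len(sol.group_1), "n_color2": len(sol.group_2),
               "seed_peak_i": sol.seed_pair[0], "seed_peak_j": sol.seed_pair[1]}
        for r in range(3):
            for c in range(3):
                row[f"u{r}{c}"] = U[r, c]
                row[f"a{r}{c}"] = A[r, c]
        rows.append(row)
    return pd.DataFrame(rows)


def write_solutions_tsv(path, solutions: dict, cell_b: np.ndarray) -> None:
    solutions_to_frame(solutions, cell_b).to_csv(path, sep="\t", index=False)


def write_classified_peaks_hdf5(path, fs, ss, intensity, snr, solution) -> None:
    """Write the two color groups of an indexed pattern back to HDF5."""
    with h5py.File(path, "w") as f:
        for name, ids in (("color1", solution.group_1),
                          ("color2", solution.group_2)):
            g = f.create_group(name)
            g.create_dataset("peaks", data=np.stack(
                [np.asarray(fs)[ids], np.asarray(ss)[ids],
                 np.asarray(intensity)[ids], np.asarray(snr)[ids]], axis=1))
        f.create_dataset("U", data=solution.rotation)
        f.attrs["score"] = solution.score
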