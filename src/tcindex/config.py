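"""Flat key-value run configuration (YAML) with explicit units in key names.

Unknown keys are rejected so that a typo cannot silently fall back to a
default.  ``parse -> serialize -> parse`` is lossless.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .geometry import DetectorGeometry, ExperimentSetup, UnitCell
from .indexer import IndexerParams
from .simulate import SimulationConfig


class ConfigError(ValueError):
    pass


_DEFAULTS = {
    # unit cell, Angstrom / degrees
    "cell_a": 64.3, "cell_b": 72.0, "cell_c": 89.2,
    "cell_alpha": 110.6, "cell_beta": 107.5, "cell_gamma": 85.8,
    # detector geometry
    "distance_m": 0.1, "pixel_size_m": 100e-6,
    "n_fast": 1440, "n_slow": 1440,
    "beam_center_fs": 719.5, "beam_center_ss": 719.5,
    # photon energies
    "energy_1_kev": 7.0, "energy_2_kev": 9.0,
    # indexer
    "delta": 0.25, "n_pairs": 5, "sort_key": "snr",
    "tol_len_inv_angstrom": 0.0025, "tol_angle_deg": 1.0,
    "min_score": None,
    "table_d_min_angstrom": 5.0, "min_angle_sep_deg": 10.0,
    # simulator
    "sim_d_min_angstrom": 3.0, "sim_sphere_radius_inv_angstrom": 3e-4,
    "sim_n_patterns": 100, "sim_seed": 0, "sim_pixel_jitter_px": 0.0,
}


@dataclass
class RunConfig:
    values: dict = field(default_factory=lambda: dict(_DEFAULTS))

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_DEFAULTS)
        merged.update(self.values)
        self.values = merged

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a flat key-value mapping")
        return cls(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.values, f, sort_keys=True)

    # -- typed views -------------------------------------------------------

    @property
    def cell(self) -> UnitCell:
        v = self.values
        return UnitCell(v["cell_a"], v["cell_b"], v["cell_c"],
                        v["cell_alpha"], v["cell_beta"], v["cell_gamma"])

    @property
    def geometry(self) -> DetectorGeometry:
        v = self.values
        return DetectorGeometry(
            n_fast=int(v["n_fast"]), n_slow=int(v["n_slow"]),
            pixel_size=v["pixel_size_m"], distance=v["distance_m"],
            beam_center=(v["beam_center_fs"], v["beam_center_ss"]))

    @property
    def setup(self) -> ExperimentSetup:
        return ExperimentSetup(self.values["energy_1_kev"],
                               self.values["energy_2_kev"])

    @property
    def indexer_params(self) -> IndexerParams:
        v = self.values
        return IndexerParams(
            delta=v["delta"], n_pairs=int(v["n_pairs"]),
            sort_key=v["sort_key"], tol_len=v["tol_len_inv_angstrom"],
            tol_angle=v["tol_angle_deg"],
            min_score=None if v["min_score"] is None else int(v["min_score"]))

    @property
    def simulation(self) -> SimulationConfig:
        v = self.values
        return SimulationConfig(
            cell=self.cell, geom=self.geometry, setup=self.setup,
            sphere_radius=v["sim_sphere_radius_inv_angstrom"],
            d_min=v["sim_d_min_angstrom"], seed=int(v["sim_seed"]),
            n_patterns=int(v["sim_n_patterns"]),
            pixel_jitter=v["sim_pixel_jitter_px"])
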