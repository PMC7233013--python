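import numpy as np
import pytest

from tcindex import (DetectorGeometry, ExperimentSetup, IndexerParams,
                     UnitCell, build_table)
from tcindex.simulate import DEFAULT_CELL, SimulationConfig


@pytest.fixture(scope="session")
def triclinic_cell() -> UnitCell:
    """The default simulated crystal's cell (P1 triclinic)."""
    return DEFAULT_CELL


@pytest.fixture(scope="session")
def cubic_cell() -> UnitCell:
    return UnitCell(10.0, 10.0, 10.0, 90.0, 90.0, 90.0)


@pytest.fixture(scope="session")
def geom() -> DetectorGeometry:
    return DetectorGeometry()


@pytest.fixture(scope="session")
def setup() -> ExperimentSetup:
    return ExperimentSetup(7.0, 9.0)


@pytest.fixture(scope="session")
def table5(triclinic_cell):
    """Reference table of the triclinic cell to 5 Angstrom."""
    return build_table(triclinic_cell, 5.0)


@pytest.fixture(scope="session")
def cubic_table(cubic_cell):
    """Toy table: cubic 10 A cell, 32 reflections at 5 A."""
    return build_table(cubic_cell, 5.0)


@pytest.fixture(scope="session")
def default_params() -> IndexerParams:
    return IndexerParams()


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig()
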