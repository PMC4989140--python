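"""Shared fixtures: coarse grids for speed, cached reference solves."""

import numpy as np
import pytest

import endostim as es

#: Coarse-but-resolving grid used by most tests (0.5 mm across the wall).
COARSE = dict(spacing=0.5e-3, axial_spacing=1e-3)


@pytest.fixture(scope="session")
def config_n4():
    """The optimal endovascular configuration: 4 electrodes, 13 mm, 40 V."""
    return es.ElectrodeConfiguration(scheme=1, n_electrodes=4,
                                     inter_electrode_distance=13e-3)


@pytest.fixture(scope="session")
def coarse_solution(config_n4):
    """Coarse-grid conduction solve of the 4-electrode configuration."""
    domain = es.domain_for(config_n4, **COARSE)
    return es.solve(domain)


@pytest.fixture(scope="session")
def default_solution(config_n4):
    """Default-grid solve of the 4-electrode configuration."""
    domain = es.domain_for(config_n4)
    return es.solve(domain)


@pytest.fixture()
def uniform_solution():
    """Synthetic solution with a uniform 100 V/m field on a default domain."""
    domain = es.build_domain(**COARSE)
    shape = domain.shape
    return es.FieldSolution(domain, potential=np.zeros(shape),
                            ex=np.full(shape, 100.0), ey=np.zeros(shape),
                            pulse_potential=40.0)
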