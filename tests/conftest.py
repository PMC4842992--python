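import numpy as np
import pytest

import spisim as sp
from spisim import fixtures


@pytest.fixture(scope="session")
def desk_geom():
    return fixtures.desk_detector()


@pytest.fixture(scope="session")
def qmap(desk_geom):
    return sp.build_qmap(desk_geom)


@pytest.fixture(scope="session")
def cluster20():
    return fixtures.make_fixture("random-cluster", seed=7)


@pytest.fixture(scope="session")
def full_scale_beam():
    """The stated beam: 13e11-photon 9 fs shot through the factor-2.3
    beamline into a 250 x 160 nm^2 FWHM focus."""
    p = sp.generate_sase_pulse(fdhm=9.0, mean_photons=13e11,
                               jitter_rel=0.0, seed=1)
    return sp.apply_beamline(p)


@pytest.fixture(scope="session")
def emc_desk_run(cluster20, desk_geom, qmap):
    """One desk-scale EMC experiment shared across tests: 2,000
    known-orientation 200-photon patterns, 600-rotation quadrature."""
    patterns = fixtures.make_known_orientation_patterns(
        cluster20, desk_geom, n_patterns=fixtures.DESK_N_PATTERNS,
        photons_per_pattern=fixtures.DESK_PHOTONS_PER_PATTERN, seed=5)
    rotations = sp.sample_rotations(fixtures.DESK_N_ROTATIONS)
    volume, posterior, trace = sp.emc_iterate(
        patterns, None, rotations, qmap, n_iter=40, seed=11)
    return patterns, rotations, volume, posterior, trace
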