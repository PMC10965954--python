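import pytest

import sibloc as sl


@pytest.fixture(scope="session")
def geo_tiny():
    """2 counties x 2 districts x 2 parishes x 25 cells = 200 cells."""
    return sl.build_geography(2, 2, 2, 25, seed=7)


@pytest.fixture(scope="session")
def geo_full():
    """Full-scale geography: 98 counties, 1372 districts, 2744 parishes."""
    return sl.build_geography(seed=0)


@pytest.fixture(scope="session")
def geo_reduced():
    """Reduced-extent geography (12 counties) with full-size units; used for
    cell-level simulations."""
    return sl.build_geography(n_counties=12, seed=0)


@pytest.fixture(scope="session")
def cohort_default(geo_full):
    """Calibrated default cohort on the full geography (18,479 pairs)."""
    return sl.simulate_cohort(geo_full, sl.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_reduced(geo_reduced):
    """Calibrated default cohort on the reduced geography."""
    return sl.simulate_cohort(geo_reduced, sl.CohortConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_tiny(geo_tiny):
    return sl.simulate_cohort(
        geo_tiny, sl.CohortConfig(n_families=400, seed=3))
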