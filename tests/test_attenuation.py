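import numpy as np
import pandas as pd
import pytest

import sibloc as sl
from sibloc._rng import stream
from sibloc.attenuation import (_draw_assignment, _exposure_triple,
                                _select_true)
from sibloc.discordance import DiscordanceDefinition, _pair_frame


def test_conditional_error_prob_values():
    assert sl.conditional_error_prob(0.158, 0.009, 4.5) == pytest.approx(
        0.878, abs=5e-4)
    assert sl.conditional_error_prob(0.3, 0.0, 4.5) == 1.0
    assert sl.conditional_error_prob(1e-9, 0.01, 4.5) == pytest.approx(0.0,
                                                                       abs=1e-5)
    with pytest.raises(ValueError):
        sl.conditional_error_prob(0.0, 0.0, 0.0)


def test_assign_errors_rates(cohort_default, geo_full):
    """Empirical E and B rates match the conditional Bernoulli design."""
    p, q = 0.158, 0.009
    d = DiscordanceDefinition.at_level("district")
    a = sl.assign_errors(cohort_default, d, p, q, seed=3, geography=geo_full)
    disc = sl.discordance_indicator(cohort_default, d,
                                    geo_full).to_numpy().astype(bool)
    gaps = _pair_frame(cohort_default)["agegap_years"].to_numpy()
    assert not a.E[~disc].any()
    expected_e = sl.conditional_error_prob(p, q, gaps[disc]).mean()
    assert a.E[disc].mean() == pytest.approx(expected_e, abs=0.01)
    b_rate = a.B[a.E].mean()
    assert b_rate == pytest.approx(p ** 2 / (2 * p - p ** 2), abs=0.01)
    # single-error pairs choose a sibling uniformly
    single = a.E & ~a.B
    assert (a.which[single] == 1).mean() == pytest.approx(0.5, abs=0.03)


def test_assign_errors_concordant_cohort(geo_tiny):
    coh = sl.simulate_cohort(geo_tiny, sl.CohortConfig(n_families=200, p=0.0,
                                                       q=0.0, seed=2))
    a = sl.assign_errors(coh, DiscordanceDefinition.beyond_km(0), 0.2, 0.01,
                         seed=1, geography=geo_tiny)
    assert not a.E.any()


def test_error_assignment_invariants():
    with pytest.raises(ValueError):
        sl.ErrorAssignment(E=np.array([False]), B=np.array([True]),
                           which=np.array([0], dtype=np.int8))
    with pytest.raises(ValueError):
        sl.ErrorAssignment(E=np.array([True]), B=np.array([False]),
                           which=np.array([0], dtype=np.int8))


@pytest.fixture(scope="module")
def district_setup(cohort_default, geo_full):
    coh = cohort_default.sort_values(
        ["family_id", "sibling_index"]).reset_index(drop=True)
    S = sl.simulate_sar(geo_full.weights["district"], 0.0, stream(3, "s"))
    surf = sl.mix_time_variation(
        S, 0.0, (int(coh["birth_year"].min()), int(coh["birth_year"].max())),
        stream(3, "t"), level="district")
    unit = geo_full.unit_of_cell(coh["reported_cell"].to_numpy(), "district")
    surf.standardise_on(unit, coh["birth_year"].to_numpy(),
                        coh["birth_month"].to_numpy())
    disc = sl.discordance_indicator(
        coh, DiscordanceDefinition.at_level("district"),
        geo_full).to_numpy().astype(bool)
    gaps = _pair_frame(coh)["agegap_years"].to_numpy()
    return coh, geo_full, surf, disc, gaps


def test_construct_exposures_no_errors(district_setup):
    coh, geo, surf, disc, gaps = district_setup
    a = _draw_assignment(disc, gaps, 0.0, 0.009, np.random.default_rng(1))
    x_true, x_obs = sl.construct_exposures(coh, geo, surf, a)
    assert np.array_equal(x_true, x_obs)


def test_construct_exposures_follows_branches(district_setup):
    coh, geo, surf, disc, gaps = district_setup
    a = _draw_assignment(disc, gaps, 0.158, 0.009, np.random.default_rng(2))
    x_true, x_obs = sl.construct_exposures(coh, geo, surf, a)
    x_own, x_sib, x_mid = _exposure_triple(coh, geo, surf)
    n_fam = a.E.size
    sib_no = np.tile([1, 2], n_fam)
    own_err = np.repeat(a.B, 2) | (np.repeat(a.which, 2) == sib_no)
    both = np.repeat(a.B, 2)
    assert np.array_equal(x_true[both], x_mid[both])
    single = own_err & ~both
    assert np.array_equal(x_true[single], x_sib[single])
    clean = ~own_err
    assert np.array_equal(x_true[clean], x_own[clean])
    assert np.array_equal(x_obs, x_own)


def test_midpoint_snapping(geo_tiny):
    """Both-error pair reporting (1,1) and (5,9): midpoint cell is (3,5)."""
    e = geo_tiny.easting
    n = geo_tiny.northing
    a = geo_tiny.cell_id(np.array([1, 5]), np.array([1, 9]))
    mid = geo_tiny.snap((e(a[0]) + e(a[1])) / 2, (n(a[0]) + n(a[1])) / 2)
    assert e(mid) == 3 and n(mid) == 5


def test_outcome_variance_and_slope():
    rng = np.random.default_rng(4)
    x = rng.standard_normal(200_000)
    y = sl.simulate_outcome(x, 5)
    assert y.var() == pytest.approx(2.0, abs=0.05)
    slope = np.cov(x, y)[0, 1] / x.var()
    assert slope == pytest.approx(1.0, abs=0.02)
    y0 = sl.simulate_outcome(x, 5, noise_sd=0.0)
    assert np.allclose(y0, (x - x.mean()) / x.std())


def test_estimate_bias_zero_without_error():
    rng = np.random.default_rng(6)
    x = rng.standard_normal(20_000)
    y = x + rng.standard_normal(20_000)
    fam = np.repeat(np.arange(10_000), 2)
    for est in ("ols", "sibling_fe"):
        assert sl.estimate_bias(y, x, x, fam, est) == pytest.approx(0.0)


def test_classical_attenuation_half():
    """Equal-variance classical noise attenuates OLS by ~50%."""
    rng = np.random.default_rng(7)
    x = rng.standard_normal(300_000)
    y = x + rng.standard_normal(300_000)
    x_obs = x + rng.standard_normal(300_000)
    fam = np.repeat(np.arange(150_000), 2)
    bias = sl.estimate_bias(y, x, x_obs, fam, "ols")
    assert bias == pytest.approx(50.0, abs=1.0)
    assert sl.classical_attenuation_oracle(1.0, 1.0) == 50.0
    assert sl.classical_attenuation_oracle(1.0, 0.0) == 0.0
    with pytest.raises(ValueError):
        sl.classical_attenuation_oracle(0.0, 0.0)


def test_estimate_bias_fe_requires_within_variance():
    fam = np.repeat(np.arange(50), 2)
    x = np.repeat(np.arange(50, dtype=float), 2)  # constant within pairs
    y = x.copy()
    with pytest.raises(ValueError):
        sl.estimate_bias(y, x, x, fam, "sibling_fe")


def test_nonclassical_error_negative_correlation(district_setup):
    """Among error-affected observations, the measurement error is negatively
    correlated with the true exposure (regression to the mean)."""
    coh, geo, surf, disc, gaps = district_setup
    a = _draw_assignment(disc, gaps, 0.158, 0.009, np.random.default_rng(9))
    x_true, x_obs = sl.construct_exposures(coh, geo, surf, a)
    err = x_obs - x_true
    affected = err != 0
    corr = np.corrcoef(x_true[affected], err[affected])[0, 1]
    assert corr < -0.3


def test_oriv_removes_classical_error():
    rng = np.random.default_rng(11)
    n = 100_000
    x = rng.standard_normal(n)
    y = x + rng.standard_normal(n)
    m1 = x + rng.standard_normal(n)
    m2 = x + rng.standard_normal(n)
    slope, f, weak = sl.oriv_estimate(y, m1, m2)
    assert slope == pytest.approx(1.0, abs=0.03)
    assert not weak
    naive = np.cov(m1, y)[0, 1] / m1.var()
    assert naive < 0.6  # attenuated without the instrument


def test_oriv_no_error_slope_one(district_setup):
    coh, geo, surf, disc, gaps = district_setup
    x_own, x_sib, _ = _exposure_triple(coh, geo, surf)
    rng = np.random.default_rng(13)
    y = x_own + rng.standard_normal(x_own.size)
    # errors off: both measures are clean reports of a shared exposure for
    # concordant pairs; restrict to them for a pure check
    same = np.repeat(~disc, 2)
    slope, _, _ = sl.oriv_estimate(y[same], x_own[same], x_sib[same])
    assert slope == pytest.approx(1.0, abs=0.03)


def test_bias_grid_deterministic(geo_tiny):
    coh = sl.simulate_cohort(geo_tiny, sl.CohortConfig(n_families=400, seed=3))
    kwargs = dict(levels=["district"], rho_grid=[0.0], k_grid=[0.0],
                  p_by_level={"district": 0.158}, q_by_level={"district": 0.009},
                  n_reps=10, n_surfaces=2, seed=5)
    a = sl.run_bias_grid(coh, geo_tiny, **kwargs)
    b = sl.run_bias_grid(coh, geo_tiny, **kwargs)
    pd.testing.assert_frame_equal(a, b)


def test_bias_grid_rejects_empty_grid(geo_tiny, cohort_tiny):
    with pytest.raises(ValueError):
        sl.run_bias_grid(cohort_tiny, geo_tiny, levels=[], rho_grid=[0.0],
                         k_grid=[0.0], p_by_level={}, q_by_level={})
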