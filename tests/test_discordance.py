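import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sibloc as sl
from sibloc.discordance import DiscordanceDefinition


def _two_report_cohort(geography, coords):
    """Minimal cohort from a list of ((e1, n1), (e2, n2), agegap) tuples."""
    rows = []
    for fam, ((e1, n1), (e2, n2), gap) in enumerate(coords):
        for sib, (e, n) in enumerate([(e1, n1), (e2, n2)], start=1):
            cell = int(geography.cell_id(np.array([e]), np.array([n]))[0])
            rows.append(dict(family_id=fam, sibling_index=sib, birth_year=1950,
                             birth_month=1, agegap_years=gap, true_cell=cell,
                             reported_cell=cell, has_error=False, moved=False))
    return pd.DataFrame(rows)


def test_indicator_identical_reports_zero(geo_tiny):
    coh = _two_report_cohort(geo_tiny, [((3, 4), (3, 4), 2.0)])
    for d in sl.TABLE1_DEFINITIONS:
        assert sl.discordance_indicator(coh, d, geo_tiny).iloc[0] == 0


def test_indicator_three_four_five_triangle(geo_reduced):
    """Reports 3 km east and 4 km north apart are exactly 5 km apart:
    discordant at d>0, concordant at d>5 (strict inequality) and d>10."""
    coh = _two_report_cohort(geo_reduced, [((100, 100), (103, 104), 1.0)])
    val = {t: sl.discordance_indicator(
        coh, DiscordanceDefinition.beyond_km(t), geo_reduced).iloc[0]
        for t in (0, 5, 10)}
    assert val == {0: 1, 5: 0, 10: 0}


def test_lpm_three_point_closed_form():
    """OLS through (0,0), (1,0), (2,1): alpha = -1/6, beta = 1/2."""
    fit = sl.fit_lpm([0, 0, 1], [0.0, 1.0, 2.0])
    assert fit.alpha == pytest.approx(-1 / 6)
    assert fit.beta == pytest.approx(1 / 2)
    assert fit.n_pairs == 3


def test_lpm_constant_indicator_warns():
    with pytest.warns(UserWarning, match="constant"):
        fit = sl.fit_lpm([0, 0, 0, 0], [0.0, 1.0, 2.0, 3.0])
    assert fit.alpha == pytest.approx(0.0)
    assert fit.beta == pytest.approx(0.0)


def test_lpm_degenerate_design_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        sl.fit_lpm([0, 1, 0], [2.0, 2.0, 2.0])


def test_lpm_quadratic_term(cohort_default, geo_full):
    """The quadratic term is available and small on the calibrated cohort."""
    ind = sl.discordance_indicator(cohort_default,
                                   DiscordanceDefinition.beyond_km(0), geo_full)
    gaps = cohort_default.groupby("family_id")["agegap_years"].first().to_numpy()
    fit = sl.fit_lpm(ind.to_numpy(), gaps, quadratic=True)
    assert fit.beta2 is not None
    assert abs(fit.beta2) < 0.003


@pytest.mark.parametrize("alpha,expected", [
    (0.486, 0.283), (0.307, 0.168), (0.292, 0.159), (0.123, 0.064),
    (0.066, 0.034),
])
def test_derived_error_probability_matches_table(alpha, expected):
    """p = 1 - sqrt(1 - alpha) reproduces the published derived row."""
    fit = sl.LpmFit(alpha=alpha, beta=0.01, se_alpha=0.005, se_beta=0.001,
                    ci_alpha=(0, 1), ci_beta=(0, 1), n_pairs=18479)
    est = sl.derive_probabilities(fit, DiscordanceDefinition.beyond_km(0))
    assert est.p_hat == pytest.approx(expected, abs=5e-4)
    assert est.q_hat == fit.beta


def test_derived_probability_exact_inverse():
    fit = sl.LpmFit(alpha=0.19, beta=0.0, se_alpha=0.01, se_beta=0.001,
                    ci_alpha=(0, 1), ci_beta=(0, 1), n_pairs=100)
    est = sl.derive_probabilities(fit, DiscordanceDefinition.beyond_km(0))
    assert est.p_hat == pytest.approx(0.1)
    # delta-method SE: se_alpha / (2 sqrt(1 - alpha))
    assert est.se_p == pytest.approx(0.01 / (2 * np.sqrt(0.81)))


def test_derived_probability_clamps_and_errors():
    bad = sl.LpmFit(alpha=1.2, beta=0.0, se_alpha=0.01, se_beta=0.001,
                    ci_alpha=(0, 1), ci_beta=(0, 1), n_pairs=10)
    with pytest.raises(ValueError):
        sl.derive_probabilities(bad, DiscordanceDefinition.beyond_km(0))
    neg = sl.LpmFit(alpha=-0.05, beta=0.0, se_alpha=0.01, se_beta=0.001,
                    ci_alpha=(0, 1), ci_beta=(0, 1), n_pairs=10)
    with pytest.warns(UserWarning, match="clamp"):
        est = sl.derive_probabilities(neg, DiscordanceDefinition.beyond_km(0))
    assert est.p_hat == 0.0


@given(p=st.floats(min_value=0.0, max_value=0.99))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_error_probability_round_trip(p):
    """derive(2p - p^2) == p for any p in [0, 1)."""
    share = 2 * p - p ** 2
    assert sl.repeat_error_probability(share) == pytest.approx(p, abs=1e-12)


def test_repeat_error_probability_examples():
    assert sl.repeat_error_probability(0.0) == 0.0
    assert sl.repeat_error_probability(0.4315) == pytest.approx(0.246, abs=5e-4)
    assert sl.repeat_error_probability(0.75) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        sl.repeat_error_probability(1.0)


def test_misreporting_share_values():
    assert sl.misreporting_share(0.158, 0.009, 4.5) == pytest.approx(0.878,
                                                                     abs=5e-4)
    assert sl.misreporting_share(0.0, 0.01, 4.5) == 0.0
    assert sl.misreporting_share(0.2, 0.0, 4.5) == 1.0
    with pytest.raises(ValueError):
        sl.misreporting_share(0.0, 0.0, 4.5)


def test_p_hat_monotone_in_distance_threshold(cohort_default, geo_full):
    """Larger thresholds can only remove discordances, so p_hat declines."""
    gaps = cohort_default.groupby("family_id")["agegap_years"].first().to_numpy()
    last = 1.0
    for t in (0, 5, 10, 20, 30, 50):
        ind = sl.discordance_indicator(
            cohort_default, DiscordanceDefinition.beyond_km(t), geo_full)
        fit = sl.fit_lpm(ind.to_numpy(), gaps)
        est = sl.derive_probabilities(fit, DiscordanceDefinition.beyond_km(t))
        assert est.p_hat <= last + 1e-12
        last = est.p_hat


def test_delta_method_se_close_to_bootstrap(geo_reduced):
    """Delta-method se_p agrees with a pair bootstrap within 15%."""
    coh = sl.simulate_cohort(geo_reduced, sl.CohortConfig(n_families=5000,
                                                          seed=21))
    d = DiscordanceDefinition.beyond_km(0)
    ind = sl.discordance_indicator(coh, d, geo_reduced).to_numpy()
    gaps = coh.groupby("family_id")["agegap_years"].first().to_numpy()
    est = sl.derive_probabilities(sl.fit_lpm(ind, gaps), d)
    rng = np.random.default_rng(17)
    boots = []
    for _ in range(300):
        idx = rng.integers(0, ind.size, ind.size)
        fit = sl.fit_lpm(ind[idx], gaps[idx])
        boots.append(1 - np.sqrt(1 - fit.alpha))
    boot_se = np.std(boots, ddof=1)
    assert est.se_p == pytest.approx(boot_se, rel=0.15)


def test_parameter_recovery_coverage(geo_reduced):
    """Over repeated cohorts, mean p_hat is within 0.01 of truth and the 95%
    CI covers the truth at a nominal-looking rate."""
    p_true = 0.283
    hits, estimates = 0, []
    n_rep = 60
    d = DiscordanceDefinition.beyond_km(0)
    for s in range(n_rep):
        coh = sl.simulate_cohort(geo_reduced, sl.CohortConfig(
            n_families=18479, p=p_true, q=0.012, seed=1000 + s))
        ind = sl.discordance_indicator(coh, d, geo_reduced).to_numpy()
        gaps = coh.groupby("family_id")["agegap_years"].first().to_numpy()
        est = sl.derive_probabilities(sl.fit_lpm(ind, gaps), d)
        estimates.append(est.p_hat)
        if abs(est.p_hat - p_true) < 1.96 * est.se_p:
            hits += 1
    assert np.mean(estimates) == pytest.approx(p_true, abs=0.01)
    assert 0.88 <= hits / n_rep <= 1.0


def test_make_table1_layout(cohort_tiny, geo_tiny):
    table = sl.make_table1(cohort_tiny, geo_tiny)
    assert list(table["definition"]) == ["parish", "district", "county",
                                         "d>0km", "d>5km", "d>10km",
                                         "d>30km", "d>50km"]
    assert (table["q_hat"] == table["beta"]).all()
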