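"""Monte Carlo quantification of attenuation bias from misreported birth
locations.

The design conditions on the *reported* discordance in the sibling data.
For each sibling pair whose reported locations differ under the analysis
level, a Bernoulli variable E_s marks the pair as error-affected with the
conditional probability

    P(error | discordant) = (2p - p^2) / (q * agegap + 2p - p^2),

and, given E_s = 1, a second Bernoulli B_s marks both reports as wrong with
probability p^2 / (2p - p^2); otherwise one sibling is chosen at random.
The true exposure of an individual is then the surface value at the
sibling's reported location (own error only), at the midpoint of the two
reported locations (both wrong), or at the own reported location (no
error) - always at the individual's own birth year-month. The observed
exposure is always the own-report value. Outcomes are Y = X_true + N(0,1),
so the true slope is 1, and bias is measured as 100 (b1 - b2) / b1 between
regressions of Y on the true and on the observed exposure, for pooled OLS
and for sibling (within-pair) fixed effects, with an optional ORIV
(sibling-instrumented two-sample 2SLS) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .discordance import DiscordanceDefinition, discordance_indicator, _pair_frame
from .exposure import ExposureSurface, mix_time_variation, simulate_sar
from .geography import Geography

__all__ = [
    "ErrorAssignment", "BiasResult", "conditional_error_prob", "assign_errors",
    "construct_exposures", "simulate_outcome", "estimate_bias", "oriv_estimate",
    "run_bias_grid", "classical_attenuation_oracle",
]


@dataclass
class ErrorAssignment:
    """Per-family error flags: E (any error), B (both siblings), and the
    erroneous sibling index (1 or 2) for single-error pairs (0 otherwise)."""

    E: np.ndarray
    B: np.ndarray
    which: np.ndarray

    def __post_init__(self):
        if np.any(self.B & ~self.E):
            raise ValueError("B implies E")
        single = self.E & ~self.B
        if np.any((self.which != 0) != single):
            raise ValueError("which must be set exactly for single-error pairs")


@dataclass
class BiasResult:
    estimator: str
    level: str
    rho: float
    k: float
    mean_bias_pct: float
    mc_se: float
    n_reps: int
    n_individuals: int


def conditional_error_prob(p: float, q: float, agegap) -> np.ndarray | float:
    """P(error in either report | reported locations differ)."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must lie in [0, 1), got {p}")
    agegap = np.asarray(agegap, dtype=float)
    err = 2.0 * p - p ** 2
    denom = q * agegap + err
    if np.any(denom <= 0.0):
        raise ValueError("p and q*agegap cannot both be zero")
    out = err / denom
    return float(out) if out.ndim == 0 else out


def _draw_assignment(discordant: np.ndarray, agegaps: np.ndarray,
                     p: float, q: float, rng: np.random.Generator) -> ErrorAssignment:
    n = discordant.size
    E = np.zeros(n, dtype=bool)
    B = np.zeros(n, dtype=bool)
    which = np.zeros(n, dtype=np.int8)
    idx = np.flatnonzero(discordant)
    if idx.size and p > 0.0:
        prob_e = conditional_error_prob(p, q, agegaps[idx])
        e = rng.random(idx.size) < prob_e
        E[idx] = e
        both_prob = p ** 2 / (2.0 * p - p ** 2)
        eidx = idx[e]
        b = rng.random(eidx.size) < both_prob
        B[eidx] = b
        sidx = eidx[~b]
        which[sidx] = rng.integers(1, 3, sidx.size).astype(np.int8)
    return ErrorAssignment(E=E, B=B, which=which)


def assign_errors(cohort: pd.DataFrame, definition: DiscordanceDefinition,
                  p: float, q: float, seed: int,
                  geography: Geography | None = None) -> ErrorAssignment:
    """Draw the (E, B, which) error flags for every family.

    Concordant pairs (under ``definition``) get E = 0; discordant pairs are
    error-affected with the conditional probability above.
    """
    ind = discordance_indicator(cohort, definition, geography).to_numpy().astype(bool)
    gaps = _pair_frame(cohort)["agegap_years"].to_numpy()
    return _draw_assignment(ind, gaps, p, q, stream(seed, "assign_errors"))


# ------------------------------------------------------------- exposures

def _exposure_triple(cohort: pd.DataFrame, geography: Geography,
                     surface: ExposureSurface) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual surface values at own-report, sibling-report and
    midpoint locations, all at the individual's own birth year-month."""
    rep = cohort["reported_cell"].to_numpy()
    year = cohort["birth_year"].to_numpy()
    month = cohort["birth_month"].to_numpy()
    n = len(cohort)
    # sibling's reported cell: rows alternate sibling 1/2 within family
    sib_rep = rep.reshape(n // 2, 2)[:, ::-1].ravel()
    mid_e = (geography.easting(rep) + geography.easting(sib_rep)) / 2.0
    mid_n = (geography.northing(rep) + geography.northing(sib_rep)) / 2.0
    mid = geography.snap(mid_e, mid_n)
    unit_own = geography.unit_of_cell(rep, surface.level)
    unit_sib = geography.unit_of_cell(sib_rep, surface.level)
    unit_mid = geography.unit_of_cell(mid, surface.level)
    x_own = surface.values(unit_own, year, month)
    x_sib = surface.values(unit_sib, year, month)
    x_mid = surface.values(unit_mid, year, month)
    return x_own, x_sib, x_mid


def _select_true(x_own: np.ndarray, x_sib: np.ndarray, x_mid: np.ndarray,
                 assignment: ErrorAssignment) -> np.ndarray:
    n_fam = assignment.E.size
    sib_no = np.tile([1, 2], n_fam)
    own_err = np.repeat(assignment.B, 2) | (np.repeat(assignment.which, 2) == sib_no)
    both = np.repeat(assignment.B, 2)
    return np.where(both, x_mid, np.where(own_err, x_sib, x_own))


def construct_exposures(cohort: pd.DataFrame, geography: Geography,
                        surface: ExposureSurface, assignment: ErrorAssignment,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(X_true, X_obs) per individual. X_obs is always the own-report value;
    X_true follows the sibloc/midloc/ownloc branches of the assignment."""
    cohort = cohort.sort_values(["family_id", "sibling_index"])
    x_own, x_sib, x_mid = _exposure_triple(cohort, geography, surface)
    return _select_true(x_own, x_sib, x_mid, assignment), x_own


def simulate_outcome(x_true: np.ndarray, rng: np.random.Generator | int,
                     noise_sd: float = 1.0) -> np.ndarray:
    """Y = standardised X_true + N(0, noise_sd); the true slope is 1."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = np.asarray(x_true, dtype=float)
    sd = x.std()
    if sd > 0:
        x = (x - x.mean()) / sd
    return x + noise_sd * rng.standard_normal(x.size)


def _slope(y: np.ndarray, x: np.ndarray) -> float:
    x = x - x.mean()
    return float((x @ (y - y.mean())) / (x @ x))


def _within(v: np.ndarray) -> np.ndarray:
    """Demean within sibling pairs (rows sorted family-major, two per pair)."""
    pairs = v.reshape(-1, 2)
    return (pairs - pairs.mean(axis=1, keepdims=True)).ravel()


def estimate_bias(y: np.ndarray, x_true: np.ndarray, x_obs: np.ndarray,
                  family_ids: np.ndarray, estimator: str) -> float:
    """Per-repetition percentage bias 100 (b1 - b2) / b1 of the observed-
    exposure slope relative to the true-exposure slope."""
    y = np.asarray(y, float)
    xt = np.asarray(x_true, float)
    xo = np.asarray(x_obs, float)
    if estimator == "ols":
        b1, b2 = _slope(y, xt), _slope(y, xo)
    elif estimator == "sibling_fe":
        order = np.argsort(family_ids, kind="stable")
        yw = _within(y[order])
        xtw = _within(xt[order])
        xow = _within(xo[order])
        if xtw @ xtw == 0 or xow @ xow == 0:
            raise ValueError("zero within-family variance; cannot fit sibling FE")
        b1 = float((xtw @ yw) / (xtw @ xtw))
        b2 = float((xow @ yw) / (xow @ xow))
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return 100.0 * (b1 - b2) / b1


def oriv_estimate(y: np.ndarray, x_obs_own: np.ndarray, x_obs_sib: np.ndarray,
                  family_ids: np.ndarray | None = None,
                  f_floor: float = 10.0) -> tuple[float, float, bool]:
    """Obviously-related IV: stack the data with the two reports' exposure
    measures swapped, instrument each measure with the other, and estimate a
    single slope by 2SLS. Returns (slope, first_stage_F, weak_flag)."""
    y = np.asarray(y, float)
    x1 = np.asarray(x_obs_own, float)
    x2 = np.asarray(x_obs_sib, float)
    ys = np.concatenate([y, y])
    xs = np.concatenate([x1, x2])
    zs = np.concatenate([x2, x1])
    zd = zs - zs.mean()
    xd = xs - xs.mean()
    denom = zd @ xd
    n = ys.size
    r2 = (denom / np.sqrt((zd @ zd) * (xd @ xd))) ** 2
    f_stat = np.inf if r2 >= 1.0 - 1e-12 else r2 / (1 - r2) * (n - 2)
    slope = float((zd @ (ys - ys.mean())) / denom)
    return slope, float(f_stat), bool(f_stat < f_floor)


def classical_attenuation_oracle(var_signal: float, var_error: float) -> float:
    """Closed-form percentage attenuation under classical iid error:
    100 * var_error / (var_signal + var_error)."""
    if var_signal < 0 or var_error < 0:
        raise ValueError("variances must be non-negative")
    total = var_signal + var_error
    if total == 0:
        raise ValueError("total variance is zero")
    return 100.0 * var_error / total


# ------------------------------------------------------------------ grid

def run_bias_grid(cohort: pd.DataFrame, geography: Geography,
                  levels: Sequence[str], rho_grid: Sequence[float],
                  k_grid: Sequence[float], p_by_level: dict,
                  q_by_level: dict, n_reps: int = 200, n_surfaces: int = 10,
                  seed: int = 0, include_oriv: bool = False,
                  estimators: Sequence[str] = ("ols", "sibling_fe"),
                  time_range: Optional[tuple[int, int]] = None) -> pd.DataFrame:
    """Mean percentage bias over the (level, rho, k) grid.

    For each grid point, ``n_surfaces`` independent SAR fields are drawn and
    the repetitions are split evenly across them; each repetition re-draws
    the error assignment and the outcome noise. Returns one row per
    (estimator, level, rho, k) with the mean bias, its Monte Carlo standard
    error and the repetition count.
    """
    if not levels or len(rho_grid) == 0 or len(k_grid) == 0:
        raise ValueError("levels, rho_grid and k_grid must be non-empty")
    cohort = cohort.sort_values(["family_id", "sibling_index"]).reset_index(drop=True)
    if time_range is None:
        time_range = (int(cohort["birth_year"].min()), int(cohort["birth_year"].max()))
    gaps = _pair_frame(cohort)["agegap_years"].to_numpy()
    fam = cohort["family_id"].to_numpy()
    year = cohort["birth_year"].to_numpy()
    month = cohort["birth_month"].to_numpy()
    reps_per_surface = max(1, n_reps // n_surfaces)

    rows = []
    for level in levels:
        p = p_by_level[level]
        q = q_by_level[level]
        definition = (DiscordanceDefinition.beyond_km(0) if level == "cell"
                      else DiscordanceDefinition.at_level(level))
        disc = discordance_indicator(cohort, definition, geography).to_numpy().astype(bool)
        weights = geography.weights[level]
        unit_own = geography.unit_of_cell(cohort["reported_cell"].to_numpy(), level)
        for rho in rho_grid:
            fields = [simulate_sar(weights, rho,
                                   stream(seed, "bias_grid", f"{level}", f"rho{rho}", f"s{j}"))
                      for j in range(n_surfaces)]
            for k in k_grid:
                per_rep: dict[str, list[float]] = {e: [] for e in estimators}
                if include_oriv:
                    per_rep["oriv"] = []
                for j, S in enumerate(fields):
                    rng_mix = stream(seed, "bias_grid", f"{level}", f"rho{rho}",
                                     f"k{k}", f"mix{j}")
                    surface = mix_time_variation(S, k, time_range, rng_mix,
                                                 level=level, rho=rho)
                    surface.standardise_on(unit_own, year, month)
                    x_own, x_sib, x_mid = _exposure_triple(cohort, geography, surface)
                    for r in range(reps_per_surface):
                        rng_rep = stream(seed, "bias_grid", f"{level}", f"rho{rho}",
                                         f"k{k}", f"rep{j}.{r}")
                        assignment = _draw_assignment(disc, gaps, p, q, rng_rep)
                        x_true = _select_true(x_own, x_sib, x_mid, assignment)
                        y = simulate_outcome(x_true, rng_rep)
                        for est in estimators:
                            per_rep[est].append(
                                estimate_bias(y, x_true, x_own, fam, est))
                        if include_oriv:
                            slope, _, _ = oriv_estimate(y, x_own, x_sib, fam)
                            per_rep["oriv"].append(100.0 * (1.0 - slope))
                for est, vals in per_rep.items():
                    vals = np.asarray(vals)
                    rows.append(BiasResult(
                        estimator=est, level=level, rho=float(rho), k=float(k),
                        mean_bias_pct=float(vals.mean()),
                        mc_se=float(vals.std(ddof=1) / np.sqrt(vals.size))
                        if vals.size > 1 else 0.0,
                        n_reps=int(vals.size), n_individuals=len(cohort)))
    return pd.DataFrame([vars(r) for r in rows])
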