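"""Synthetic sibling cohort with household moves and reporting errors.

Each family contributes exactly two siblings. The data-generating process
mirrors the decomposition used in the discordance analysis:

* the family's true location at the first birth is uniform over cells;
* the age gap has a point mass of twins and a discretised gamma bulk with
  mean ~4.5 years, truncated to [9 months, 27 years];
* each individual's *reported* birth cell is wrong with probability ``p``
  (optionally correlated within the pair via a Gaussian copula), displaced
  from the true cell by the error kernel; correct reports equal the true
  cell (the residence at that sibling's birth);
* a household move occurs between the births with marginal probability
  ``q * agegap_years`` and relocates the second sibling's true birth cell by
  the move kernel. Moves are drawn among pairs without reporting errors
  (with probability ``q * agegap / (1 - P(either report wrong))``), so that
  move- and error-induced discordance are disjoint events and the pair
  discordance probability is exactly additive,
  ``P(y = 1 | gap) = (2p - p^2) + q * gap``,
  which is the decomposition the discordance regression estimates. Both
  marginal rates are preserved exactly.

The residual-location convention: sibling 1 (the older) is always born at
the family's initial cell; a move relocates sibling 2's true birth cell.

The resulting table has one row per individual and is the input of the
discordance and Monte Carlo modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import stream
from .geography import Geography
from .kernels import DisplacementKernel, ERROR_KERNEL, MOVE_KERNEL

__all__ = [
    "CohortConfig", "simulate_cohort", "simulate_repeat_reports",
    "simulate_spatial_trait", "write_cohort_csv", "read_cohort_csv",
]

#: share of twin pairs in the sibling sample (227 of 18,479 pairs)
DEFAULT_TWIN_SHARE = 227 / 18479

#: gamma shape of the non-twin age-gap bulk; scale follows from the mean
AGEGAP_GAMMA_SHAPE = 2.0

MAX_AGEGAP_YEARS = 27.0
MIN_NONTWIN_GAP_MONTHS = 9  # no observable gaps of 1-8 months (gestation)


@dataclass
class CohortConfig:
    """Parameters of the synthetic sibling cohort.

    ``q`` is the annual probability of a household move between the two
    births; ``p`` the probability that a single birth-location report is
    wrong. ``sibling_error_correlation`` correlates the two error indicators
    of a pair (0 = independent errors).
    """

    n_families: int = 18479
    q: float = 0.012
    p: float = 0.283
    agegap_mean: float = 4.5
    twin_share: float = DEFAULT_TWIN_SHARE
    error_kernel: DisplacementKernel = field(default_factory=lambda: ERROR_KERNEL)
    move_kernel: DisplacementKernel = field(default_factory=lambda: MOVE_KERNEL)
    sibling_error_correlation: float = 0.0
    birth_year_range: tuple[int, int] = (1936, 1965)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must lie in [0, 1], got {self.q}")
        if not 0.0 <= self.twin_share <= 1.0:
            raise ValueError("twin_share must lie in [0, 1]")
        if not 0.0 <= self.sibling_error_correlation <= 1.0:
            raise ValueError("sibling_error_correlation must lie in [0, 1]")
        if self.n_families < 1:
            raise ValueError("n_families must be positive")


def _draw_agegap_months(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Age gaps in months: twin point mass at 0, gamma bulk truncated to
    [9, 324] months."""
    n = cfg.n_families
    twins = rng.random(n) < cfg.twin_share
    mean_nontwin = cfg.agegap_mean / max(1.0 - cfg.twin_share, 1e-12)
    scale = mean_nontwin / AGEGAP_GAMMA_SHAPE
    years = rng.gamma(AGEGAP_GAMMA_SHAPE, scale, size=n)
    months = np.clip(np.rint(years * 12.0), MIN_NONTWIN_GAP_MONTHS,
                     MAX_AGEGAP_YEARS * 12).astype(np.int64)
    months[twins] = 0
    return months


def pair_error_union_prob(p: float, corr: float = 0.0) -> float:
    """P(either sibling's report is wrong) under the Gaussian copula;
    reduces to 2p - p^2 for independent errors."""
    if p == 0.0:
        return 0.0
    if corr == 0.0:
        return 2.0 * p - p ** 2
    from scipy.stats import multivariate_normal

    thr = norm.ppf(p)
    both = float(multivariate_normal(mean=[0.0, 0.0],
                                     cov=[[1.0, corr], [corr, 1.0]]).cdf([thr, thr]))
    return 2.0 * p - both


def _correlated_errors(p: float, corr: float, n_pairs: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli(p) error indicators for both siblings with Gaussian-copula
    correlation ``corr`` between the pair's indicators."""
    if p == 0.0:
        z = np.zeros(n_pairs, dtype=bool)
        return z, z.copy()
    if corr == 0.0:
        return rng.random(n_pairs) < p, rng.random(n_pairs) < p
    z_shared = rng.standard_normal(n_pairs)
    a = np.sqrt(corr)
    b = np.sqrt(1.0 - corr)
    z1 = a * z_shared + b * rng.standard_normal(n_pairs)
    z2 = a * z_shared + b * rng.standard_normal(n_pairs)
    thr = norm.ppf(p)
    return z1 < thr, z2 < thr


def simulate_cohort(geography: Geography, config: CohortConfig) -> pd.DataFrame:
    """Simulate the two-sibling cohort; deterministic given ``config.seed``.

    Returns a DataFrame with two rows per family (sibling_index 1 = older),
    columns ``family_id, sibling_index, birth_year, birth_month,
    agegap_years, true_cell, reported_cell, has_error, moved``.
    """
    cfg = config
    n = cfg.n_families

    gap_months = _draw_agegap_months(cfg, stream(cfg.seed, "cohort", "agegap"))
    gap_years = gap_months / 12.0
    e_union = pair_error_union_prob(cfg.p, cfg.sibling_error_correlation)
    if cfg.q > 0 and cfg.q * gap_years.max() > 1.0 - e_union:
        raise ValueError(
            f"move probability overflow: q * max age gap = "
            f"{cfg.q * gap_years.max():.3f} exceeds the error-free pair share "
            f"{1.0 - e_union:.3f}; lower q, p or the age-gap range")

    rng_loc = stream(cfg.seed, "cohort", "location")
    base_cell = rng_loc.integers(0, geography.n_cells, n)

    y0, y1 = cfg.birth_year_range
    months0 = rng_loc.integers(0, (y1 - y0 + 1) * 12, n)  # older sibling
    months1 = months0 + gap_months

    err1, err2 = _correlated_errors(cfg.p, cfg.sibling_error_correlation, n,
                                    stream(cfg.seed, "cohort", "errors"))

    # moves only among error-free pairs, upweighted so the marginal move
    # probability is q * agegap and discordance decomposes additively
    rng_move = stream(cfg.seed, "cohort", "moves")
    p_move = np.minimum(1.0, cfg.q * gap_years / max(1.0 - e_union, 1e-300))
    moved = ~(err1 | err2) & (rng_move.random(n) < p_move)
    true1 = base_cell.copy()
    true2 = base_cell.copy()
    if moved.any():
        true2[moved] = cfg.move_kernel.draw(geography, base_cell[moved],
                                            stream(cfg.seed, "cohort", "move_kernel"))
    rng_err_kernel = stream(cfg.seed, "cohort", "error_kernel")
    rep1 = true1.copy()
    rep2 = true2.copy()
    if err1.any():
        rep1[err1] = cfg.error_kernel.draw(geography, true1[err1], rng_err_kernel)
    if err2.any():
        rep2[err2] = cfg.error_kernel.draw(geography, true2[err2], rng_err_kernel)

    fam = np.arange(n)
    df = pd.DataFrame({
        "family_id": np.repeat(fam, 2),
        "sibling_index": np.tile([1, 2], n),
        "birth_year": y0 + np.stack([months0, months1], axis=1).ravel() // 12,
        "birth_month": 1 + np.stack([months0, months1], axis=1).ravel() % 12,
        "agegap_years": np.repeat(gap_years, 2),
        "true_cell": np.stack([true1, true2], axis=1).ravel(),
        "reported_cell": np.stack([rep1, rep2], axis=1).ravel(),
        "has_error": np.stack([err1, err2], axis=1).ravel(),
        "moved": np.repeat(moved, 2),
    })
    df.attrs["config"] = asdict(cfg)
    return df


def simulate_repeat_reports(cohort: pd.DataFrame, p: float, seed: int,
                            geography: Geography,
                            kernel: DisplacementKernel = ERROR_KERNEL) -> pd.DataFrame:
    """Add a second, independent report of each individual's (time-invariant)
    true birth cell, wrong with probability ``p``. No moves enter: the repeat
    report refers to the same true location as the first."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    out = cohort.copy()
    rng = stream(seed, "repeat_reports")
    true_cell = out["true_cell"].to_numpy()
    err = rng.random(len(out)) < p
    repeat = true_cell.copy()
    if err.any():
        repeat[err] = kernel.draw(geography, true_cell[err], stream(seed, "repeat_kernel"))
    out["repeat_reported_cell"] = repeat
    return out


def family_origin_cell(cohort: pd.DataFrame) -> np.ndarray:
    """Per-individual cell of the family's original household: the older
    sibling's true birth cell (moves relocate only the second birth)."""
    c = cohort.sort_values(["family_id", "sibling_index"])
    origin = c["true_cell"].to_numpy()[0::2]
    out = np.repeat(origin, 2)
    # restore the caller's row order
    back = np.empty(len(c), dtype=np.int64)
    back[c.index.get_indexer(cohort.index)] = np.arange(len(c))
    return out[back]


def simulate_spatial_trait(geography: Geography, cohort: pd.DataFrame,
                           rho: float, noise_sd: float, seed: int,
                           level: str = "district",
                           field: np.ndarray | None = None) -> np.ndarray:
    """Spatially structured, inherited individual trait (a genetic-PC
    analog).

    The trait is a spatial-autoregressive field simulated over units of
    ``level`` (district by default, where such traits show strong spatial
    autocorrelation), evaluated at the *family origin* cell - the older
    sibling's true birth cell - plus iid Gaussian noise. Both siblings share
    the field component always: the trait is inherited, so a household move
    between the births does not change it, it only decouples the younger
    sibling's (truthfully reported) birth location from the family's
    ancestry field.
    """
    from .exposure import simulate_sar  # local import to avoid a cycle

    if field is None:
        field = simulate_sar(geography.weights[level], rho,
                             stream(seed, "trait", "field"))
    unit = geography.unit_of_cell(family_origin_cell(cohort), level)
    noise = stream(seed, "trait", "noise").standard_normal(len(cohort)) * noise_sd
    return field[unit] + noise


# --------------------------------------------------------------------- I/O

_CSV_COLUMNS = ["family_id", "sibling_index", "birth_year", "birth_month",
                "true_easting", "true_northing", "reported_easting",
                "reported_northing", "parish_id", "district_id", "county_id"]


def write_cohort_csv(cohort: pd.DataFrame, geography: Geography, path) -> None:
    """Write one row per individual with integer-km coordinates and the
    administrative units of the *reported* location."""
    rep = cohort["reported_cell"].to_numpy()
    true = cohort["true_cell"].to_numpy()
    out = pd.DataFrame({
        "family_id": cohort["family_id"],
        "sibling_index": cohort["sibling_index"],
        "birth_year": cohort["birth_year"],
        "birth_month": cohort["birth_month"],
        "true_easting": geography.easting(true),
        "true_northing": geography.northing(true),
        "reported_easting": geography.easting(rep),
        "reported_northing": geography.northing(rep),
        "parish_id": geography.unit_of_cell(rep, "parish"),
        "district_id": geography.unit_of_cell(rep, "district"),
        "county_id": geography.unit_of_cell(rep, "county"),
    })
    out.to_csv(path, index=False)


def read_cohort_csv(path, geography: Geography) -> pd.DataFrame:
    """Read a cohort CSV (same dialect accepted for user data)."""
    raw = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    df = raw.copy()
    df["true_cell"] = geography.cell_id(raw["true_easting"].to_numpy(),
                                        raw["true_northing"].to_numpy())
    df["reported_cell"] = geography.cell_id(raw["reported_easting"].to_numpy(),
                                            raw["reported_northing"].to_numpy())
    # reconstruct the pair-level age gap from year-month birth dates
    months = raw["birth_year"].to_numpy() * 12 + raw["birth_month"].to_numpy()
    gaps = (pd.Series(months).groupby(raw["family_id"]).transform(lambda s: s.max() - s.min())
            / 12.0)
    df["agegap_years"] = gaps
    df["has_error"] = df["true_cell"] != df["reported_cell"]
    return df
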