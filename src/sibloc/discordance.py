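"""Sibling birth-location discordance and the move/error decomposition.

For each sibling pair a binary indicator y_s records whether the two
reported birth locations differ under a chosen definition: different
administrative unit (parish / district / county) or reported coordinates
more than a distance threshold apart. The linear probability model

    P(y_s = 1 | agegap_s) = alpha + beta * agegap_s

separates the two sources of discordance: the slope beta is the annual
household move probability q (moves accumulate linearly with birth
spacing), while the intercept alpha is the discordance among twins, driven
purely by reporting error. With per-report error probability p and
independent errors within a pair, alpha = 2p - p^2, so

    p_hat = 1 - sqrt(1 - alpha_hat),

with a delta-method standard error se_p = se_alpha / (2 sqrt(1 - alpha)).
The same inversion applies to repeat reports of the same individual, where
moves cannot contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .geography import Geography

__all__ = [
    "DiscordanceDefinition", "LpmFit", "ProbabilityEstimate",
    "discordance_indicator", "fit_lpm", "derive_probabilities",
    "repeat_error_probability", "misreporting_share", "make_table1",
    "TABLE1_DEFINITIONS",
]


@dataclass(frozen=True)
class DiscordanceDefinition:
    """One column of the discordance table: a level or a distance rule."""

    mode: str                       # "level" | "distance"
    level: Optional[str] = None     # parish | district | county
    threshold_km: Optional[float] = None

    def __post_init__(self):
        if self.mode == "level":
            if self.level is None or self.threshold_km is not None:
                raise ValueError("mode='level' requires level and no threshold")
        elif self.mode == "distance":
            if self.threshold_km is None or self.level is not None:
                raise ValueError("mode='distance' requires threshold_km and no level")
            if self.threshold_km < 0:
                raise ValueError("threshold_km must be >= 0")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def at_level(cls, level: str) -> "DiscordanceDefinition":
        return cls(mode="level", level=level)

    @classmethod
    def beyond_km(cls, threshold_km: float) -> "DiscordanceDefinition":
        return cls(mode="distance", threshold_km=threshold_km)

    @property
    def label(self) -> str:
        if self.mode == "level":
            return self.level
        t = self.threshold_km
        return f"d>{int(t) if float(t).is_integer() else t}km"


#: the eight column definitions of the discordance table
TABLE1_DEFINITIONS: tuple[DiscordanceDefinition, ...] = (
    DiscordanceDefinition.at_level("parish"),
    DiscordanceDefinition.at_level("district"),
    DiscordanceDefinition.at_level("county"),
    DiscordanceDefinition.beyond_km(0),
    DiscordanceDefinition.beyond_km(5),
    DiscordanceDefinition.beyond_km(10),
    DiscordanceDefinition.beyond_km(30),
    DiscordanceDefinition.beyond_km(50),
)


@dataclass
class LpmFit:
    """Linear probability model fit with heteroskedasticity-robust (HC1)
    standard errors and 95% normal confidence intervals."""

    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    ci_alpha: tuple[float, float]
    ci_beta: tuple[float, float]
    n_pairs: int
    beta2: Optional[float] = None
    se_beta2: Optional[float] = None


@dataclass
class ProbabilityEstimate:
    """Derived (q_hat, p_hat) with standard errors for one definition."""

    q_hat: float
    p_hat: float
    se_q: float
    se_p: float
    definition: DiscordanceDefinition
    alpha: float = np.nan
    n_pairs: int = 0


def _pair_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per family with both reported cells and the age gap."""
    c = cohort.sort_values(["family_id", "sibling_index"])
    counts = c.groupby("family_id").size()
    if not (counts == 2).all():
        bad = counts.index[counts != 2]
        raise ValueError(f"families without exactly two siblings: {list(bad[:5])} ...")
    first = c.iloc[0::2].reset_index(drop=True)
    second = c.iloc[1::2].reset_index(drop=True)
    return pd.DataFrame({
        "family_id": first["family_id"],
        "cell_1": first["reported_cell"].to_numpy(),
        "cell_2": second["reported_cell"].to_numpy(),
        "agegap_years": first["agegap_years"].to_numpy(),
    })


def discordance_indicator(cohort: pd.DataFrame,
                          definition: DiscordanceDefinition,
                          geography: Geography | None = None) -> pd.Series:
    """Binary discordance indicator per family under ``definition``.

    Distance mode compares Euclidean distance between reported cells with a
    strict ``>`` (a threshold of 0 km therefore flags any coordinate
    difference). Level mode compares the administrative units of the
    reported coordinates under the fixed generation-time boundaries.
    Families with missing reported coordinates are excluded (count logged
    via a warning).
    """
    pairs = _pair_frame(cohort)
    valid = pairs["cell_1"].notna() & pairs["cell_2"].notna()
    if (~valid).any():
        warnings.warn(f"excluding {int((~valid).sum())} families with missing "
                      "reported coordinates")
        pairs = pairs[valid]
    c1 = pairs["cell_1"].to_numpy().astype(np.int64)
    c2 = pairs["cell_2"].to_numpy().astype(np.int64)
    if definition.mode == "distance":
        if geography is None:
            raise ValueError("geography is required to compute distances between cells")
        if definition.threshold_km == 0:
            ind = c1 != c2
        else:
            ind = geography.distance_km(c1, c2) > definition.threshold_km
    else:
        if geography is None:
            raise ValueError("geography is required for level-mode definitions")
        ind = (geography.unit_of_cell(c1, definition.level)
               != geography.unit_of_cell(c2, definition.level))
    return pd.Series(ind.astype(np.int8), index=pairs["family_id"].to_numpy(),
                     name=definition.label)


def fit_lpm(indicators: Sequence[int], agegaps: Sequence[float],
            quadratic: bool = False) -> LpmFit:
    """OLS of the binary indicator on the age gap, HC1 robust SEs."""
    y = np.asarray(indicators, dtype=float)
    g = np.asarray(agegaps, dtype=float)
    if y.size != g.size:
        raise ValueError("indicators and agegaps must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 families to fit the probability model")
    if np.any(g < 0):
        raise ValueError("age gaps must be non-negative")
    if np.ptp(g) == 0:
        raise ValueError("degenerate design: all families have the same age gap")
    if np.ptp(y) == 0:
        warnings.warn("constant discordance indicator; slope is 0 by construction")
    X = sm.add_constant(np.column_stack([g, g ** 2] if quadratic else [g]))
    res = sm.OLS(y, X).fit(cov_type="HC1")
    ci = res.conf_int(alpha=0.05)
    return LpmFit(
        alpha=float(res.params[0]), beta=float(res.params[1]),
        se_alpha=float(res.bse[0]), se_beta=float(res.bse[1]),
        ci_alpha=(float(ci[0][0]), float(ci[0][1])),
        ci_beta=(float(ci[1][0]), float(ci[1][1])),
        n_pairs=int(y.size),
        beta2=float(res.params[2]) if quadratic else None,
        se_beta2=float(res.bse[2]) if quadratic else None,
    )


def derive_probabilities(fit: LpmFit,
                         definition: DiscordanceDefinition) -> ProbabilityEstimate:
    """Invert alpha = 2p - p^2 into p_hat with a delta-method SE.

    q_hat equals the slope exactly. Negative intercepts (possible in small
    subgroups) clamp p_hat to 0 with a warning; alpha >= 1 is an error.
    """
    alpha = fit.alpha
    if alpha >= 1.0:
        raise ValueError(f"intercept {alpha:.3f} >= 1: error probability overflows")
    if alpha < 0.0:
        warnings.warn(f"negative intercept {alpha:.4f}; clamping p_hat to 0")
        p_hat, se_p = 0.0, np.nan
    else:
        p_hat = 1.0 - np.sqrt(1.0 - alpha)
        se_p = fit.se_alpha / (2.0 * np.sqrt(1.0 - alpha))
    return ProbabilityEstimate(q_hat=fit.beta, p_hat=float(p_hat),
                               se_q=fit.se_beta, se_p=float(se_p),
                               definition=definition, alpha=alpha,
                               n_pairs=fit.n_pairs)


def repeat_error_probability(share_discordant: float) -> float:
    """Per-report error probability from the share of individuals whose two
    reports of the same true location disagree: p = 1 - sqrt(1 - share)."""
    if not 0.0 <= share_discordant < 1.0:
        raise ValueError(f"share must lie in [0, 1), got {share_discordant}")
    return 1.0 - np.sqrt(1.0 - share_discordant)


def misreporting_share(p: float, q: float, agegap: float) -> float:
    """Share of discordance driven by reporting error rather than moves:
    (2p - p^2) / (q * agegap + 2p - p^2)."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"p must lie in [0, 1), got {p}")
    err = 2.0 * p - p ** 2
    denom = q * agegap + err
    if denom <= 0.0:
        raise ValueError("no discordance: both error and move components are zero")
    return err / denom


def make_table1(cohort: pd.DataFrame, geography: Geography,
                definitions: Sequence[DiscordanceDefinition] = TABLE1_DEFINITIONS,
                ) -> pd.DataFrame:
    """Discordance-table report: one row per definition with the LPM fit and
    the derived (q_hat, p_hat)."""
    rows = []
    for definition in definitions:
        ind = discordance_indicator(cohort, definition, geography)
        gaps = _pair_frame(cohort)["agegap_years"].to_numpy()
        fit = fit_lpm(ind.to_numpy(), gaps)
        est = derive_probabilities(fit, definition)
        rows.append({
            "definition": definition.label,
            "alpha": fit.alpha, "alpha_ci_low": fit.ci_alpha[0],
            "alpha_ci_high": fit.ci_alpha[1],
            "beta": fit.beta, "beta_ci_low": fit.ci_beta[0],
            "beta_ci_high": fit.ci_beta[1],
            "q_hat": est.q_hat, "se_q": est.se_q,
            "p_hat": est.p_hat, "se_p": est.se_p,
            "n_pairs": fit.n_pairs,
        })
    return pd.DataFrame(rows)
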