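"""Spatially autocorrelated, time-varying exposure surfaces.

A unit-level field S follows a spatial autoregressive (SAR) model,
S = (I - rho W)^{-1} eps with iid standard-normal innovations and
row-standardised weights W (|rho| < 1). Temporal structure enters through
year-month fixed effects T drawn iid standard normal (no temporal
autocorrelation). The observed exposure mixes the two standardised parts,

    V = sqrt(k) * T + sqrt(1 - k) * S,

so that k is the share of exposure variance due to purely temporal
variation. V is re-standardised over the person-level evaluation population
before use, because the downstream bias formulas operate on person-level
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["ExposureSurface", "simulate_sar", "mix_time_variation",
           "moran_i", "read_exposure_csv"]

#: below this many units the SAR system is solved directly (sparse LU)
_DIRECT_SOLVE_MAX = 5000
_POWER_TOL = 1e-8
_POWER_MAX_TERMS = 5000


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot standardise a zero-variance vector")
    return (x - x.mean()) / sd


def simulate_sar(weights: sp.spmatrix, rho: float,
                 rng: np.random.Generator | int,
                 method: str = "auto") -> np.ndarray:
    """Draw one standardised SAR field S = (I - rho W)^{-1} eps.

    ``method`` is "auto" (direct solve for small systems, truncated
    Neumann/power series otherwise), "direct" or "power".
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not abs(rho) < 1.0:
        raise ValueError(f"|rho| must be < 1 for row-standardised weights, got {rho}")
    w = sp.csr_matrix(weights)
    n = w.shape[0]
    eps = rng.standard_normal(n)
    if rho == 0.0:
        return _standardise(eps)
    if method == "auto":
        method = "direct" if n <= _DIRECT_SOLVE_MAX else "power"
    if method == "direct":
        try:
            s = spla.splu((sp.identity(n, format="csc") - rho * w).tocsc()).solve(eps)
        except RuntimeError as exc:  # pragma: no cover - singular only if |rho|>=1
            raise ValueError(f"SAR system singular at rho={rho}") from exc
    elif method == "power":
        s = eps.copy()
        term = eps.copy()
        for _ in range(_POWER_MAX_TERMS):
            term = rho * (w @ term)
            s += term
            if np.abs(term).max() < _POWER_TOL * max(np.abs(s).max(), 1.0):
                break
        else:
            raise ValueError(
                f"SAR power series did not converge at rho={rho} "
                f"within {_POWER_MAX_TERMS} terms")
    else:
        raise ValueError(f"unknown method {method!r}")
    return _standardise(s)


@dataclass
class ExposureSurface:
    """V[unit, month] = sqrt(k) T[month] + sqrt(1-k) S[unit], standardised.

    ``month0`` encodes the first column as an absolute month index
    (year * 12 + (month - 1)); column j is month0 + j.
    """

    level: str
    rho: float
    k: float
    S: np.ndarray
    T: np.ndarray
    V: np.ndarray
    month0: int

    def month_index(self, year: np.ndarray, month: np.ndarray) -> np.ndarray:
        idx = np.asarray(year) * 12 + (np.asarray(month) - 1) - self.month0
        if np.any(idx < 0) or np.any(idx >= self.V.shape[1]):
            bad = np.unique(np.asarray(year)[(idx < 0) | (idx >= self.V.shape[1])])
            raise ValueError(f"surface does not cover birth years {bad.tolist()}")
        return idx

    def values(self, unit: np.ndarray, year: np.ndarray, month: np.ndarray) -> np.ndarray:
        unit = np.asarray(unit)
        if unit.max() >= self.V.shape[0]:
            raise ValueError(
                f"unit id {int(unit.max())} outside surface with {self.V.shape[0]} units")
        return self.V[unit, self.month_index(year, month)]

    def standardise_on(self, unit: np.ndarray, year: np.ndarray,
                       month: np.ndarray) -> "ExposureSurface":
        """Re-standardise V to mean 0 / SD 1 over the person-level
        population given by (unit, year, month) per individual."""
        vals = self.values(unit, year, month)
        sd = vals.std()
        if sd == 0:
            raise ValueError("exposure has zero variance over the evaluation population")
        self.V = (self.V - vals.mean()) / sd
        return self

    def to_frame(self) -> pd.DataFrame:
        units, months = np.meshgrid(np.arange(self.V.shape[0]),
                                    np.arange(self.V.shape[1]), indexing="ij")
        am = self.month0 + months.ravel()
        return pd.DataFrame({"unit_id": units.ravel(), "year": am // 12,
                             "month": am % 12 + 1, "value": self.V.ravel()})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, level: str,
                   rho: float = np.nan, k: float = np.nan) -> "ExposureSurface":
        """Build a surface from an external long-format exposure table with
        columns unit_id, year, month, value (one row per unit x month; any
        missing combination is an error)."""
        required = {"unit_id", "year", "month", "value"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"exposure table missing columns: {sorted(missing)}")
        am = frame["year"].to_numpy() * 12 + (frame["month"].to_numpy() - 1)
        month0 = int(am.min())
        n_months = int(am.max()) - month0 + 1
        n_units = int(frame["unit_id"].max()) + 1
        if len(frame) != n_units * n_months:
            raise ValueError(
                f"exposure table is not a complete unit x month grid: "
                f"{len(frame)} rows for {n_units} units x {n_months} months")
        V = np.full((n_units, n_months), np.nan)
        V[frame["unit_id"].to_numpy(), am - month0] = frame["value"].to_numpy()
        if np.isnan(V).any():
            raise ValueError("exposure table has duplicate or missing entries")
        return cls(level=level, rho=rho, k=k, S=V.mean(axis=1), T=V.mean(axis=0),
                   V=V, month0=month0)


def read_exposure_csv(path, level: str) -> ExposureSurface:
    """Read an external exposure table (unit_id, year, month, value)."""
    return ExposureSurface.from_frame(pd.read_csv(path), level=level)


def mix_time_variation(S: np.ndarray, k: float, time_range: tuple[int, int],
                       rng: np.random.Generator | int, level: str = "district",
                       rho: float = np.nan) -> ExposureSurface:
    """Combine a standardised spatial field with iid year-month effects.

    ``time_range`` is (first_year, last_year) inclusive; T has one value per
    year-month with no temporal autocorrelation.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"k must lie in [0, 1], got {k}")
    y0, y1 = time_range
    n_months = (y1 - y0 + 1) * 12
    T = rng.standard_normal(n_months)
    S = _standardise(np.asarray(S, dtype=float))
    T = _standardise(T)
    V = np.sqrt(k) * T[None, :] + np.sqrt(1.0 - k) * S[:, None]
    return ExposureSurface(level=level, rho=rho, k=k, S=S, T=T, V=V, month0=y0 * 12)


def moran_i(values: np.ndarray, weights: sp.spmatrix) -> float:
    """Global Moran's I with (row-standardised) sparse weights."""
    z = np.asarray(values, dtype=float)
    w = sp.csr_matrix(weights)
    if z.ndim != 1 or w.shape[0] != z.size:
        raise ValueError("values and weights do not conform")
    z = z - z.mean()
    denom = z @ z
    if denom == 0:
        raise ValueError("Moran's I undefined for zero-variance values")
    s0 = w.sum()
    return float(z.size / s0 * (z @ (w @ z)) / denom)
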