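"""Spatial-trait correlation by sibling discordance distance.

For each individual in the sibling sample, compare their spatially
structured trait (a genetic-PC analog) with the mean trait of *non-sibling*
reference individuals who reported the same birth cell. The Pearson
correlation is computed within bins of the distance between the two
siblings' reported birth locations. The trait is inherited (anchored at the
family origin), so both reporting errors and household moves decouple the
reported birth cell from the ancestry field, and the correlation declines
with discordance distance; with both mechanisms switched off the curve is
flat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .cohort import simulate_spatial_trait
from .exposure import simulate_sar
from .geography import Geography
from .kernels import DisplacementKernel, ERROR_KERNEL

__all__ = ["TraitCorrelationCurve", "location_reference_means",
           "correlation_by_discordance", "make_reference_population",
           "run_trait_curve", "DEFAULT_BINS"]

#: (label, low, high] distance bins in km; the first bin is exactly 0
DEFAULT_BINS: tuple[tuple[str, float, float], ...] = (
    ("0", -np.inf, 0.0),
    ("(0,10]", 0.0, 10.0),
    ("(10,50]", 10.0, 50.0),
    ("(50,100]", 50.0, 100.0),
    ("(100,200]", 100.0, 200.0),
    (">200", 200.0, np.inf),
)

MIN_BIN_N = 10


@dataclass
class TraitCorrelationCurve:
    table: pd.DataFrame  # bin, correlation, ci_low, ci_high, n

    def correlation(self, bin_label: str) -> float:
        row = self.table[self.table["bin"] == bin_label]
        return float(row["correlation"].iloc[0])


def location_reference_means(traits: np.ndarray, reported_cells: np.ndarray,
                             exclude_family: np.ndarray | None = None,
                             family_ids: np.ndarray | None = None) -> pd.Series:
    """Mean reference trait per reported cell.

    ``exclude_family``/``family_ids`` drop reference individuals belonging
    to any of the queried families before averaging (the reference
    population is non-sibling by construction, so this is usually a no-op).
    """
    traits = np.asarray(traits, float)
    cells = np.asarray(reported_cells)
    if exclude_family is not None:
        if family_ids is None:
            raise ValueError("family_ids required when exclude_family is given")
        keep = ~np.isin(np.asarray(family_ids), np.asarray(exclude_family))
        traits, cells = traits[keep], cells[keep]
    return pd.Series(traits).groupby(pd.Series(cells)).mean()


def _fisher_ci(r: float, n: int) -> tuple[float, float]:
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = 1.959963984540054 / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlation_by_discordance(cohort: pd.DataFrame, traits: np.ndarray,
                               reference_means: pd.Series, geography: Geography,
                               bins: Sequence[tuple[str, float, float]] = DEFAULT_BINS,
                               ) -> TraitCorrelationCurve:
    """Correlation of individual trait with the own-reported-cell reference
    mean, within sibling-discordance-distance bins (Fisher-z 95% CIs)."""
    cohort = cohort.sort_values(["family_id", "sibling_index"]).reset_index(drop=True)
    rep = cohort["reported_cell"].to_numpy()
    n = len(cohort)
    sib_rep = rep.reshape(n // 2, 2)[:, ::-1].ravel()
    dist = geography.distance_km(rep, sib_rep)

    ref = reference_means.reindex(rep)
    ok = ref.notna().to_numpy()
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} individuals whose reported cell "
                      "has no reference residents")
    traits = np.asarray(traits, float)

    rows = []
    for label, lo, hi in bins:
        mask = ok & (dist > lo) & (dist <= hi)
        nb = int(mask.sum())
        if nb < MIN_BIN_N:
            rows.append({"bin": label, "correlation": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "n": nb, "low_n": True})
            continue
        r = float(np.corrcoef(traits[mask], ref.to_numpy()[mask])[0, 1])
        lo_ci, hi_ci = _fisher_ci(r, nb)
        rows.append({"bin": label, "correlation": r, "ci_low": lo_ci,
                     "ci_high": hi_ci, "n": nb, "low_n": False})
    return TraitCorrelationCurve(table=pd.DataFrame(rows))


def make_reference_population(geography: Geography, n: int, p_error: float,
                              seed: int,
                              kernel: DisplacementKernel = ERROR_KERNEL,
                              ) -> pd.DataFrame:
    """Synthetic non-sibling reference population: uniform true cells,
    reported cells subject to the same per-report error process."""
    rng = stream(seed, "reference", "cells")
    true_cell = rng.integers(0, geography.n_cells, n)
    reported = true_cell.copy()
    err = stream(seed, "reference", "errors").random(n) < p_error
    if err.any():
        reported[err] = kernel.draw(geography, true_cell[err],
                                    stream(seed, "reference", "kernel"))
    return pd.DataFrame({"true_cell": true_cell, "reported_cell": reported})


def run_trait_curve(geography: Geography, cohort: pd.DataFrame,
                    rho: float = 0.975, noise_sd: float = 1.0,
                    p_error: float = 0.283, ref_multiple: int = 10,
                    level: str = "district",
                    bins: Sequence[tuple[str, float, float]] = DEFAULT_BINS,
                    seed: int = 0) -> TraitCorrelationCurve:
    """End-to-end curve: shared ancestry field, inherited sibling traits
    anchored at the family origin, reference population with the same
    reporting-error process."""
    field = simulate_sar(geography.weights[level], rho, stream(seed, "trait", "field"))
    sib_traits = simulate_spatial_trait(geography, cohort, rho, noise_sd,
                                        seed, level=level, field=field)

    ref = make_reference_population(geography, ref_multiple * len(cohort),
                                    p_error, seed)
    ref_unit = geography.unit_of_cell(ref["true_cell"].to_numpy(), level)
    ref_noise = stream(seed, "reference", "noise").standard_normal(len(ref)) * noise_sd
    ref_traits = field[ref_unit] + ref_noise

    means = location_reference_means(ref_traits, ref["reported_cell"].to_numpy())
    return correlation_by_discordance(cohort, sib_traits, means, geography, bins)
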