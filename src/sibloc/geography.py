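"""Hierarchical synthetic geography on a 1-km integer grid.

The geography is a contiguous rectangular tiling of 1-km cells, nested into
parishes, districts and counties as spatially compact rectangular blocks.
It stands in for the 1951 administrative hierarchy of Great Britain used in
birth-location studies (98 counties, ~1,363 local government districts,
~2,518 parishes covered by the sibling sample), with unit areas matched to
the historical averages: a parish of ~90 km^2, a district of ~180 km^2 and a
county of ~2,500 km^2.

Spatial weights are queen contiguity at every level (8 neighbours for
interior cells on the grid), row-standardised, stored as sparse CSR
matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["Geography", "build_geography", "grid_queen_weights", "row_standardise"]

LEVELS = ("cell", "parish", "district", "county")


def _near_square_factors(n: int) -> tuple[int, int]:
    """Most-square factor pair (a, b) of n with a <= b."""
    for a in range(int(math.isqrt(n)), 0, -1):
        if n % a == 0:
            return a, n // a
    raise ValueError(f"cannot factor {n}")  # pragma: no cover - isqrt>=1 always divides


def _orient(block_h: int, block_w: int, count: int) -> tuple[int, int]:
    """Arrange `count` blocks of (block_h, block_w) into the grid (rows, cols)
    whose combined block has aspect ratio closest to 1."""
    a, b = _near_square_factors(count)
    options = [(a, b), (b, a)]
    def aspect(rc):
        h, w = rc[0] * block_h, rc[1] * block_w
        return max(h, w) / min(h, w)
    return min(options, key=aspect)


def grid_queen_weights(n_rows: int, n_cols: int) -> sp.csr_matrix:
    """Binary queen-contiguity matrix for a full rectangular grid.

    A 1x1 grid gets a unit self-weight so that every row still sums to 1
    after standardisation."""
    n = n_rows * n_cols
    if n == 1:
        return sp.csr_matrix(np.ones((1, 1)))
    idx = np.arange(n).reshape(n_rows, n_cols)
    rows, cols = [], []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r0, r1 = max(0, -dr), min(n_rows, n_rows - dr)
            c0, c1 = max(0, -dc), min(n_cols, n_cols - dc)
            rows.append(idx[r0:r1, c0:c1].ravel())
            cols.append(idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel())
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    w = sp.csr_matrix((np.ones(r.size), (r, c)), shape=(n, n))
    return w


def row_standardise(w: sp.spmatrix) -> sp.csr_matrix:
    """Row-standardise a non-negative weights matrix; isolated rows rejected."""
    w = sp.csr_matrix(w)
    rs = np.asarray(w.sum(axis=1)).ravel()
    if np.any(rs == 0):
        raise ValueError("weights matrix has isolated units (all-zero rows)")
    return sp.diags(1.0 / rs) @ w


@dataclass
class Geography:
    """Nested rectangular geography with per-level spatial weights.

    ``cells`` has one row per 1-km cell with its integer easting/northing and
    the parish/district/county it belongs to. ``weights[level]`` is the
    row-standardised queen-contiguity matrix over units of that level.
    """

    n_rows: int
    n_cols: int
    cells: pd.DataFrame
    parish_of_cell: np.ndarray
    district_of_parish: np.ndarray
    county_of_district: np.ndarray
    weights: Mapping[str, sp.csr_matrix]
    unit_grids: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    seed: int | None = None

    # ------------------------------------------------------------------ sizes
    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_parishes(self) -> int:
        return self.district_of_parish.size

    @property
    def n_districts(self) -> int:
        return self.county_of_district.size

    @property
    def n_counties(self) -> int:
        return int(self.county_of_district.max()) + 1

    def n_units(self, level: str) -> int:
        return {"cell": self.n_cells, "parish": self.n_parishes,
                "district": self.n_districts, "county": self.n_counties}[level]

    # ----------------------------------------------------------- conversions
    def cell_id(self, easting: np.ndarray, northing: np.ndarray) -> np.ndarray:
        return np.asarray(northing) * self.n_cols + np.asarray(easting)

    def easting(self, cell: np.ndarray) -> np.ndarray:
        return np.asarray(cell) % self.n_cols

    def northing(self, cell: np.ndarray) -> np.ndarray:
        return np.asarray(cell) // self.n_cols

    def district_of_cell(self, cell: np.ndarray) -> np.ndarray:
        return self.district_of_parish[self.parish_of_cell[cell]]

    def county_of_cell(self, cell: np.ndarray) -> np.ndarray:
        return self.county_of_district[self.district_of_cell(cell)]

    def unit_of_cell(self, cell: np.ndarray, level: str) -> np.ndarray:
        """Map cell ids to unit ids of the requested aggregation level."""
        cell = np.asarray(cell)
        if level == "cell":
            return cell
        if level == "parish":
            return self.parish_of_cell[cell]
        if level == "district":
            return self.district_of_cell(cell)
        if level == "county":
            return self.county_of_cell(cell)
        raise ValueError(f"unknown level {level!r}")

    def snap(self, easting: np.ndarray, northing: np.ndarray) -> np.ndarray:
        """Nearest grid cell to fractional coordinates (all-land geography)."""
        e = np.clip(np.rint(easting).astype(np.int64), 0, self.n_cols - 1)
        n = np.clip(np.rint(northing).astype(np.int64), 0, self.n_rows - 1)
        return self.cell_id(e, n)

    def distance_km(self, cell_a: np.ndarray, cell_b: np.ndarray) -> np.ndarray:
        """Euclidean distance between cell centres in km."""
        de = self.easting(cell_a) - self.easting(cell_b)
        dn = self.northing(cell_a) - self.northing(cell_b)
        return np.hypot(de, dn)

    # ----------------------------------------------------------------- export
    def write_cells_csv(self, path: str | Path) -> None:
        self.cells.to_csv(path, index=False)

    def write_membership_csv(self, path: str | Path) -> None:
        rows = []
        for parish, district in enumerate(self.district_of_parish):
            rows.append(("parish", parish, "district", district))
        for district, county in enumerate(self.county_of_district):
            rows.append(("district", district, "county", county))
        pd.DataFrame(rows, columns=["unit_level", "unit_id", "parent_level", "parent_id"]).to_csv(
            path, index=False)

    def write_weights_mtx(self, level: str, path: str | Path) -> None:
        from scipy.io import mmwrite

        mmwrite(str(path), self.weights[level])


def build_geography(n_counties: int = 98,
                    districts_per_county: int = 14,
                    parishes_per_district: int = 2,
                    cells_per_parish: int = 90,
                    seed: int | None = None) -> Geography:
    """Build the nested rectangular geography.

    The defaults reproduce the scale of the 1951 hierarchy covered by the
    sibling sample: 98 counties x 14 districts x 2 parishes x 90 cells, i.e.
    1,372 districts and 2,744 parishes over ~247,000 km^2 of 1-km cells.
    The layout is deterministic; ``seed`` is stored for provenance only.
    """
    for name, v in [("n_counties", n_counties), ("districts_per_county", districts_per_county),
                    ("parishes_per_district", parishes_per_district),
                    ("cells_per_parish", cells_per_parish)]:
        if int(v) != v or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")

    # compact blocks, built bottom-up with near-square orientations
    ph, pw = _near_square_factors(cells_per_parish)          # parish block, cells
    pdr, pdc = _orient(ph, pw, parishes_per_district)        # parishes per district grid
    dh, dw = pdr * ph, pdc * pw                              # district block, cells
    dcr, dcc = _orient(dh, dw, districts_per_county)         # districts per county grid
    ch, cw = dcr * dh, dcc * dw                              # county block, cells
    ccr, ccc = _orient(ch, cw, n_counties)                   # counties on the map
    n_rows, n_cols = ccr * ch, ccc * cw

    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    parish_rows = n_rows // ph
    parish_cols = n_cols // pw
    parish_of_cell = ((rr // ph) * parish_cols + (cc // pw)).ravel().astype(np.int64)

    p_idx = np.arange(parish_rows * parish_cols)
    p_r, p_c = p_idx // parish_cols, p_idx % parish_cols
    district_cols = n_cols // dw
    district_of_parish = ((p_r // pdr) * district_cols + (p_c // pdc)).astype(np.int64)

    district_rows = n_rows // dh
    d_idx = np.arange(district_rows * district_cols)
    d_r, d_c = d_idx // district_cols, d_idx % district_cols
    county_cols = n_cols // cw
    county_of_district = ((d_r // dcr) * county_cols + (d_c // dcc)).astype(np.int64)

    cell = np.arange(n_rows * n_cols)
    cells = pd.DataFrame({
        "cell_id": cell,
        "easting_km": cell % n_cols,
        "northing_km": cell // n_cols,
        "parish_id": parish_of_cell,
        "district_id": district_of_parish[parish_of_cell],
    })
    cells["county_id"] = county_of_district[cells["district_id"].to_numpy()]

    weights = {
        "cell": row_standardise(grid_queen_weights(n_rows, n_cols)),
        "parish": row_standardise(grid_queen_weights(parish_rows, parish_cols)),
        "district": row_standardise(grid_queen_weights(district_rows, district_cols)),
        "county": row_standardise(grid_queen_weights(ccr, ccc)),
    }
    unit_grids = {"cell": (n_rows, n_cols), "parish": (parish_rows, parish_cols),
                  "district": (district_rows, district_cols), "county": (ccr, ccc)}
    return Geography(n_rows=n_rows, n_cols=n_cols, cells=cells,
                     parish_of_cell=parish_of_cell,
                     district_of_parish=district_of_parish,
                     county_of_district=county_of_district,
                     weights=weights, unit_grids=unit_grids, seed=seed)
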