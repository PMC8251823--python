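"""Gridded candidate-origin surfaces and plot geometry.

A *basemap* is the discrete set of candidate natal-origin cells over a
species' breeding range.  Each cell carries the expected value of every
intrinsic marker (here feather hydrogen isotope ratio delta-2H in permil
and wing chord in mm), a relative-abundance prior weight, and its centre
coordinates.  Study plots are the sampling locations whose individuals
are assigned back onto the basemap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

#: Published correction from precipitation to feather isotope values for
#: ground-foraging migratory songbirds: d2Hf = -175.57 + 0.95 * d2Hp.
CALIBRATION_INTERCEPT = -175.57
CALIBRATION_SLOPE = 0.95

MARKER_COLUMNS = ("expected_isotope", "expected_wing")


def calibrate_isoscape(precip_values, intercept: float = CALIBRATION_INTERCEPT,
                       slope: float = CALIBRATION_SLOPE):
    """Convert a precipitation isoscape (d2Hp, permil) to expected feather
    values (d2Hf, permil) with an affine calibration.

    Parameters
    ----------
    precip_values : array_like
        Expected amount-weighted growing-season precipitation d2H per cell.
    intercept, slope : float
        Calibration coefficients; defaults are the published feather
        correction for ground-foraging migrants.
    """
    x = np.asarray(precip_values, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = np.flatnonzero(~np.isfinite(x))
        raise ValueError(
            f"precipitation isoscape contains {bad.size} non-finite value(s) "
            f"(first at index {bad[0]})"
        )
    return intercept + slope * x


def great_circle_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance (haversine) between points in decimal degrees."""
    lat1 = np.asarray(lat1, dtype=float)
    lat2 = np.asarray(lat2, dtype=float)
    if np.any(np.abs(lat1) > 90.0) or np.any(np.abs(lat2) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    lon1 = np.radians(np.asarray(lon1, dtype=float))
    lon2 = np.radians(np.asarray(lon2, dtype=float))
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlat = p2 - p1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def normalize_abundance(raw_counts):
    """Normalise non-negative per-cell abundances to a probability vector.

    The relative-abundance prior N_j is the cell's share of total breeding
    abundance across the (range-masked) grid.
    """
    x = np.asarray(raw_counts, dtype=float)
    if x.size == 0:
        raise ValueError("empty abundance vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("abundance contains non-finite values")
    if np.any(x < 0):
        raise ValueError("abundance contains negative values")
    total = x.sum()
    if total <= 0:
        raise ValueError("abundance must contain at least one positive value")
    return x / total


@dataclass(frozen=True)
class Basemap:
    """Ordered collection of candidate origin cells.

    Attributes
    ----------
    cells : pandas.DataFrame
        One row per in-range cell with columns ``cell_id``, ``lon``, ``lat``,
        ``expected_isotope`` (permil), ``expected_wing`` (mm) and
        ``rel_abundance`` (sums to 1).
    cell_size_km : float
        Grid resolution; also sets the default distance floor
        (half a cell) used by the dispersal kernel.
    """

    cells: pd.DataFrame
    cell_size_km: float = 30.0

    def __post_init__(self):
        required = {"cell_id", "lon", "lat", "rel_abundance", *MARKER_COLUMNS}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"basemap missing columns: {sorted(missing)}")
        if len(self.cells) < 2:
            raise ValueError("degenerate basemap: need at least 2 cells")
        ids = self.cells["cell_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("cell_ids are not unique")
        vals = self.cells[["lon", "lat", *MARKER_COLUMNS]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("basemap contains non-finite coordinates or markers")
        ab = self.cells["rel_abundance"].to_numpy(dtype=float)
        if np.any(ab < 0):
            raise ValueError("rel_abundance must be non-negative")
        if abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"rel_abundance sums to {ab.sum():.12g}, not 1; "
                "normalise with normalize_abundance() first"
            )
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    def __len__(self):
        return len(self.cells)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def mu(self) -> np.ndarray:
        """(n_cells, 2) expected marker matrix, column order (isotope, wing)."""
        return self.cells[list(MARKER_COLUMNS)].to_numpy(dtype=float)

    @property
    def abundance(self) -> np.ndarray:
        return self.cells["rel_abundance"].to_numpy(dtype=float)

    @property
    def lonlat(self) -> np.ndarray:
        return self.cells[["lon", "lat"]].to_numpy(dtype=float)

    @classmethod
    def from_layers(cls, lon, lat, expected_isotope, expected_wing, abundance,
                    cell_size_km: float = 30.0, range_mask=None) -> "Basemap":
        """Assemble a basemap from aligned per-cell layer vectors.

        ``range_mask`` (boolean, same length) clips to the breeding range
        BEFORE the abundance prior is normalised, so probabilities are
        conditional on the range.
        """
        layers = {
            "lon": np.asarray(lon, dtype=float),
            "lat": np.asarray(lat, dtype=float),
            "expected_isotope": np.asarray(expected_isotope, dtype=float),
            "expected_wing": np.asarray(expected_wing, dtype=float),
        }
        n = len(layers["lon"])
        for name, v in layers.items():
            if len(v) != n:
                raise ValueError(f"layer {name!r} has length {len(v)}, expected {n}")
        raw_ab = np.asarray(abundance, dtype=float)
        if len(raw_ab) != n:
            raise ValueError("abundance layer misaligned with grid")
        if range_mask is None:
            range_mask = np.ones(n, dtype=bool)
        range_mask = np.asarray(range_mask, dtype=bool)
        cells = pd.DataFrame(layers)[range_mask].reset_index(drop=True)
        cells.insert(0, "cell_id", np.arange(len(cells)))
        cells["rel_abundance"] = normalize_abundance(raw_ab[range_mask])
        return cls(cells=cells, cell_size_km=cell_size_km)

    @classmethod
    def from_csv(cls, path, cell_size_km: float = 30.0) -> "Basemap":
        """Read a flat basemap CSV with columns cell_id, lon, lat,
        expected_isotope, expected_wing, rel_abundance (comma separated,
        header row, '.' decimal).  Abundance is renormalised if it does not
        already sum to 1 (e.g. raw counts were written)."""
        cells = pd.read_csv(path)
        cells.columns = [c.strip().lower() for c in cells.columns]
        required = {"cell_id", "lon", "lat", "expected_isotope", "expected_wing",
                    "rel_abundance"}
        missing = required - set(cells.columns)
        if missing:
            raise ValueError(f"basemap CSV missing columns: {sorted(missing)}")
        cells["rel_abundance"] = normalize_abundance(cells["rel_abundance"].to_numpy())
        order = ["cell_id", "lon", "lat", "expected_isotope", "expected_wing",
                 "rel_abundance"]
        return cls(cells=cells[order].reset_index(drop=True),
                   cell_size_km=cell_size_km)

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


@dataclass(frozen=True)
class StudyPlots:
    """Breeding study plots: ``plot_id``, ``lon``, ``lat`` and optionally
    covariate columns (see :mod:`isoassign.selection`)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"plot_id", "lon", "lat"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"plots table missing columns: {sorted(missing)}")
        ids = self.table["plot_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("plot_ids are not unique")
        coords = self.table[["lon", "lat"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("plot coordinates must be finite")

    def __len__(self):
        return len(self.table)

    @property
    def plot_ids(self) -> np.ndarray:
        return self.table["plot_id"].to_numpy()

    def row_index(self, plot_id) -> int:
        idx = np.flatnonzero(self.plot_ids == plot_id)
        if idx.size == 0:
            raise KeyError(f"unknown plot_id {plot_id!r}")
        return int(idx[0])

    @classmethod
    def from_csv(cls, path) -> "StudyPlots":
        t = pd.read_csv(path)
        # case-insensitive headers; covariate column R keeps its canonical name
        canonical = {"plot_id": "plot_id", "lon": "lon", "lat": "lat",
                     "r": "R", "habitat_ha": "habitat_ha",
                     "density": "density", "n": "n"}
        t.columns = [canonical.get(c.strip().lower(), c.strip())
                     for c in t.columns]
        return cls(table=t)


def distance_matrix(plots: StudyPlots, basemap: Basemap,
                    radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Great-circle distance (km) from every study plot to every cell centre.

    Returns an (n_plots, n_cells) array; row order follows the plots table,
    column order the basemap cells.  The kernel prior is later evaluated at
    these cell-centre distances.
    """
    plon = plots.table["lon"].to_numpy(dtype=float)[:, None]
    plat = plots.table["lat"].to_numpy(dtype=float)[:, None]
    clon = basemap.cells["lon"].to_numpy(dtype=float)[None, :]
    clat = basemap.cells["lat"].to_numpy(dtype=float)[None, :]
    return great_circle_km(plon, plat, clon, clat, radius_km=radius_km)
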