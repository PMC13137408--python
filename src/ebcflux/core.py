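"""Shared data model and half-hourly flux-table / site-metadata I/O.

The interchange formats are deliberately plain text: CSV for flux tables
(FLUXNET/ICOS-style column names, ``-9999`` missing sentinel, TIMESTAMP_END
convention), YAML for site metadata, and ESRI ASCII grids for single-band
rasters (DEM, surface reflectance, land-surface temperature, footprint
weights).

Timestamps follow the end-of-interval convention: a record stamped ``t``
covers the half-open interval ``(t - 30 min, t]``, matching FLUXNET
TIMESTAMP_END practice.  In memory missing values are ``NaN``; the ``-9999``
sentinel exists only on disk.

Profile column groups (air temperature / moisture at several heights, soil
temperature / moisture at several depths, replicate soil heat-flux plates)
are encoded as ``VAR_1 .. VAR_n`` columns with a sidecar JSON mapping index
to height/depth so that plain CSV remains the interchange format.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import MISSING_SENTINEL

logger = logging.getLogger("ebcflux")

TIMESTAMP_COL = "TIMESTAMP_END"
TIMESTAMP_FMT = "%Y%m%d%H%M"
STEP_S = 1800


class FluxTableError(ValueError):
    """Raised for malformed flux tables (timestamps, ranges, layering)."""


# ---------------------------------------------------------------------------
# FluxTable
# ---------------------------------------------------------------------------

@dataclass
class FluxTable:
    """Half-hourly record set of meteorology, radiation, fluxes and flags.

    Parameters
    ----------
    data
        DataFrame indexed by ``TIMESTAMP_END`` (strictly increasing,
        constant 1800 s step).  Standard units: radiation and fluxes in
        W m-2, TA in degC, RH in %, PA in kPa, USTAR in m s-1, GPP in
        umol CO2 m-2 s-1.  Missing values are NaN.
    profiles
        Mapping of profile group name (e.g. ``"TA"``, ``"H2O"``, ``"TS"``,
        ``"SWC"``, ``"G"``) to the ordered list of heights (m above ground)
        or depths (m below ground) of the ``VAR_1..VAR_n`` columns.
    """

    data: pd.DataFrame
    profiles: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ----------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise FluxTableError("flux table index must be datetimes")
        dup = idx[idx.duplicated()]
        if len(dup):
            raise FluxTableError(f"duplicate timestamp: {dup[0]}")
        if len(idx) > 1:
            steps = np.diff(idx.view("int64")) / 1e9
            if (steps <= 0).any():
                bad = idx[1:][steps <= 0][0]
                raise FluxTableError(f"non-monotone timestamp at {bad}")
            if (steps != STEP_S).any():
                bad = idx[1:][steps != STEP_S][0]
                raise FluxTableError(f"non half-hourly step before {bad}")
        for flag_col in [c for c in self.data.columns if c.endswith("_FLAG")]:
            vals = self.data[flag_col].dropna()
            if not vals.isin([0, 1, 2]).all():
                raise FluxTableError(f"{flag_col} outside {{0,1,2}}")
        if "RH" in self.data:
            rh = self.data["RH"].dropna()
            if ((rh < 0) | (rh > 100)).any():
                raise FluxTableError("RH outside [0, 100]")
        for c in ("SW_IN", "SW_OUT"):
            if c in self.data and (self.data[c].dropna() < 0).any():
                raise FluxTableError(f"{c} negative")

    # -- helpers -----------------------------------------------------------
    def profile_columns(self, group: str) -> list[str]:
        """Column names ``group_1 .. group_n`` for a profile group."""
        n = len(self.profiles.get(group, []))
        return [f"{group}_{i}" for i in range(1, n + 1)]

    def copy(self) -> "FluxTable":
        return FluxTable(self.data.copy(), {k: list(v) for k, v in self.profiles.items()})

    def __len__(self) -> int:
        return len(self.data)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".profiles.json")


def read_flux_table(path: str | Path, dialect: dict | None = None) -> FluxTable:
    """Read a delimited half-hourly flux table.

    ``dialect`` may contain ``rename`` (mapping of file column -> standard
    name), ``sep`` (delimiter, default ","), and ``timestamp_column``.
    The ``-9999`` sentinel is harmonized to NaN and units normalized with
    :func:`normalize_units`.  Unknown columns are preserved.
    """
    path = Path(path)
    dialect = dialect or {}
    sep = dialect.get("sep", ",")
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if rename := dialect.get("rename"):
        df = df.rename(columns=rename)
    ts_col = dialect.get("timestamp_column", TIMESTAMP_COL)
    if ts_col not in df.columns:
        raise FluxTableError(f"missing timestamp column {ts_col!r} in {path}")
    ts = pd.to_datetime(df[ts_col].astype(str).str.strip(), format=TIMESTAMP_FMT, errors="coerce")
    if ts.isna().any():
        ts = pd.to_datetime(df[ts_col], errors="coerce")
    if ts.isna().any():
        raise FluxTableError("unparseable timestamps")
    df = df.drop(columns=[ts_col]).set_index(pd.DatetimeIndex(ts, name=TIMESTAMP_COL))
    df = df.replace(MISSING_SENTINEL, np.nan)
    df = normalize_units(df)
    profiles: dict[str, list[float]] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        profiles = {k: list(map(float, v)) for k, v in json.loads(sidecar.read_text()).items()}
    table = FluxTable(df, profiles)
    logger.info("read %d half-hourly records from %s", len(table), path)
    return table


def write_flux_table(table: FluxTable, path: str | Path) -> None:
    """Write a flux table to CSV with the ``-9999`` sentinel.

    Round-trips bit-for-bit through :func:`read_flux_table` (Python's
    shortest-repr float formatting is exact).
    """
    path = Path(path)
    df = table.data.copy()
    out = df.where(df.notna(), MISSING_SENTINEL)
    out.insert(0, TIMESTAMP_COL, df.index.strftime(TIMESTAMP_FMT))
    out.to_csv(path, index=False)
    if table.profiles:
        _sidecar_path(path).write_text(json.dumps(table.profiles, indent=1))
    logger.info("wrote %d records to %s", len(table), path)


def normalize_units(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize common unit variants to the standard set (idempotent).

    TA columns in kelvin are converted to degC (detected by median > 150),
    PA in Pa to kPa (median > 2000), RH given as a 0-1 fraction to %
    (maximum <= 1).  Applying the function twice equals applying it once.
    """
    df = df.copy()
    for c in df.columns:
        s = df[c]
        if not pd.api.types.is_numeric_dtype(s) or s.dropna().empty:
            continue
        if c == "TA" or c.startswith("TA_"):
            if s.median() > 150:
                df[c] = s - 273.15
        elif c == "PA":
            if s.median() > 2000:
                df[c] = s / 1000.0
        elif c == "RH":
            if s.max() <= 1.0:
                df[c] = s * 100.0
    return df


# ---------------------------------------------------------------------------
# Site metadata
# ---------------------------------------------------------------------------

@dataclass
class RadiometerMeta:
    mount_height: float = 2.0            # m above ground
    sw_fov_angle: float = 170.0          # pyranometer total FoV (deg)
    lw_fov_angle: float = 150.0          # pyrgeometer total FoV (deg)
    horizontal_distance_to_tower: float = 3.0   # m


@dataclass
class TowerMeta:
    cross_section_width: float = 1.0     # m
    lattice_void_reduction: float = 0.40  # fraction of width that is void
    albedo: float = 0.2                  # ALB_t, ferrous structures
    emissivity: float = 0.3              # eps_t, aluminium/iron average

    @property
    def effective_width(self) -> float:
        """Cross-section width after lattice void reduction."""
        return self.cross_section_width * (1.0 - self.lattice_void_reduction)


@dataclass
class SiteMeta:
    """Geographic, structural and instrument-geometry constants of a station."""

    latitude: float
    longitude: float
    ec_height: float                     # z_m, m above ground
    canopy_height: float = 0.0
    elevation: float = 0.0
    slope: float = 0.0                   # landscape slope beta (deg)
    aspect: float = 0.0                  # downslope azimuth (deg from N)
    wet_biomass: float = 0.0             # m_v, kg m-2 (fresh weight)
    has_profile: bool = True
    soil_plate_depth: float = 0.05       # m
    radiometer: RadiometerMeta = field(default_factory=RadiometerMeta)
    tower: TowerMeta = field(default_factory=TowerMeta)

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValueError("latitude outside [-90, 90]")
        if not -180 <= self.longitude <= 180:
            raise ValueError("longitude outside [-180, 180]")
        if not 0 <= self.slope < 90:
            raise ValueError("slope outside [0, 90)")
        if self.canopy_height < 0 or self.ec_height <= self.canopy_height:
            raise ValueError("need ec_height > canopy_height >= 0")
        for a in (self.radiometer.sw_fov_angle, self.radiometer.lw_fov_angle):
            if not 0 < a < 180:
                raise ValueError("FoV angle outside (0, 180)")
        if self.soil_plate_depth <= 0:
            raise ValueError("soil_plate_depth must be positive")
        if self.wet_biomass < 0:
            raise ValueError("wet_biomass must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


REQUIRED_META_KEYS = ("latitude", "longitude", "ec_height")


def load_site_meta(path: str | Path) -> SiteMeta:
    """Load site metadata from YAML, applying defaults for optional keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    missing = [k for k in REQUIRED_META_KEYS if k not in raw]
    if missing:
        raise KeyError(f"site metadata missing required keys: {missing}")
    rad = RadiometerMeta(**raw.pop("radiometer", {}))
    tower = TowerMeta(**raw.pop("tower", {}))
    return SiteMeta(radiometer=rad, tower=tower, **raw)


def save_site_meta(meta: SiteMeta, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(meta.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Plain-text single-band raster grid
# ---------------------------------------------------------------------------

@dataclass
class Grid:
    """Single-band raster on a regular grid (ESRI ASCII interchange).

    ``data[0, 0]`` is the north-west cell; ``x`` grows east, ``y`` north.
    Coordinates are planar metres (site-local projection).
    """

    data: np.ndarray                     # shape (nrows, ncols)
    cellsize: float
    xll: float = 0.0                     # x of lower-left cell corner
    yll: float = 0.0
    nodata: float = -9999.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows = self.data.shape[0]
        x = self.xll + (col + 0.5) * self.cellsize
        y = self.yll + (nrows - row - 0.5) * self.cellsize
        return x, y

    def xy_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        nrows, ncols = self.data.shape
        x = self.xll + (np.arange(ncols) + 0.5) * self.cellsize
        y = self.yll + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return np.meshgrid(x, y)

    def value_at(self, x: float, y: float) -> float:
        """Nearest-cell value at planar coordinates (x, y)."""
        nrows, ncols = self.data.shape
        if not (self.xll <= x <= self.xll + ncols * self.cellsize
                and self.yll <= y <= self.yll + nrows * self.cellsize):
            raise ValueError("point outside grid")
        col = min(int((x - self.xll) / self.cellsize), ncols - 1)
        row = min(int(nrows - (y - self.yll) / self.cellsize), nrows - 1)
        return float(self.data[row, col])


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    nrows, ncols = grid.data.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {grid.xll}\nyllcorner {grid.yll}\n"
        f"cellsize {grid.cellsize}\nNODATA_value {grid.nodata}\n"
    )
    body = np.where(np.isnan(grid.data), grid.nodata, grid.data)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Grid:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = data.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    nodata = hdr.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    return Grid(data, hdr["cellsize"], hdr.get("xllcorner", 0.0),
                hdr.get("yllcorner", 0.0), nodata)
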