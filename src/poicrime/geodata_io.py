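"""Reading, filtering and spatial windowing of crime and POI point tables.

Crime tables follow the open UK police-data CSV dialect (columns ``Crime
ID``, ``Month``, ``Reported by``, ``Falls within``, ``Longitude``,
``Latitude``, ``LSOA code``, ``LSOA name``, ``Crime type``, ``Last outcome
category``); header matching is case-insensitive.  POI tables carry planar
coordinates plus a three-level class hierarchy (class -> category ->
group); the analysis operates on the lowest (class) level.

All downstream computation is in planar metres.  Longitude/latitude are
projected at read time through a CRS from :mod:`poicrime.projection`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .projection import BritishNationalGrid

logger = logging.getLogger(__name__)

__all__ = [
    "CrimeRecord",
    "PoiRecord",
    "StudyArea",
    "PointSet",
    "SchemaError",
    "HierarchyError",
    "VIOLENCE_CRIME_TYPE",
    "read_crime_table",
    "read_poi_table",
    "window_points",
    "grid_geometry",
]

#: The crime category the analysis is restricted to.  Robbery is a separate
#: source category and is excluded simply by not including it in the filter.
VIOLENCE_CRIME_TYPE = "Violence and sexual offences"

CRIME_COLUMNS = [
    "Crime ID", "Month", "Reported by", "Falls within", "Longitude",
    "Latitude", "LSOA code", "LSOA name", "Crime type",
    "Last outcome category",
]
_REQUIRED_CRIME_COLUMNS = ["Month", "Longitude", "Latitude", "Crime type"]

#: Default column mapping for POI tables (keys are logical names).
DEFAULT_POI_COLUMNS = {
    "x": "Easting",
    "y": "Northing",
    "name": "Name",
    "class_name": "Class",
    "category": "Category",
    "group": "Group",
}


class SchemaError(ValueError):
    """A table is missing required columns."""


class HierarchyError(ValueError):
    """The POI class hierarchy is inconsistent."""


@dataclass(frozen=True)
class CrimeRecord:
    crime_id: str
    month: str               # "YYYY-MM"
    reported_by: str
    falls_within: str
    x: float                 # planar metres
    y: float
    lsoa_code: str
    lsoa_name: str
    crime_type: str
    outcome: str | None = None


@dataclass(frozen=True)
class PoiRecord:
    x: float
    y: float
    name: str
    class_name: str
    category: str
    group: str


@dataclass(frozen=True)
class StudyArea:
    """Square analysis window: centre plus side length, gridded for KDE.

    Defaults follow the convention of analysing the central 3 km x 3 km of
    a city on a 150 x 150 raster (cell size = side/150 = 20 m) with KDE
    bandwidth side/40 = 75 m.
    """

    centre_x: float
    centre_y: float
    side: float = 3000.0
    n_cells_per_side: int = 150
    bandwidth_divisor: float = 40.0

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("side must be positive")
        if self.n_cells_per_side < 1:
            raise ValueError("n_cells_per_side must be >= 1")

    @property
    def cell_size(self) -> float:
        return self.side / self.n_cells_per_side

    @property
    def kde_bandwidth(self) -> float:
        return self.side / self.bandwidth_divisor

    @property
    def xmin(self) -> float:
        return self.centre_x - self.side / 2

    @property
    def ymin(self) -> float:
        return self.centre_y - self.side / 2


@dataclass
class PointSet:
    """Planar points of one labelled class (a POI class, or crimes)."""

    label: str
    points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if pts.size and not np.isfinite(pts).all():
            raise ValueError(f"non-finite coordinates in point set {self.label!r}")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


def _ci_column_lookup(df: pd.DataFrame) -> dict[str, str]:
    return {c.strip().lower(): c for c in df.columns}


def read_crime_table(path, crime_type_filter=None, crs=None,
                     ) -> tuple[list[CrimeRecord], int]:
    """Read a police-dialect crime CSV, filter by crime type, project to metres.

    Parameters
    ----------
    path : str or file-like
        CSV with the police open-data header (case-insensitive match).
    crime_type_filter : set of str or None
        Categories to keep; ``None`` keeps everything.
    crs : projection object, optional
        Must provide ``to_planar(lon, lat)``.  Defaults to the British
        National Grid.

    Returns
    -------
    (records, n_dropped)
        Records whose crime type is in the filter; rows with unparseable
        coordinates are dropped and counted in ``n_dropped``.
    """
    crs = crs or BritishNationalGrid()
    df = pd.read_csv(path, dtype=str)
    if df.empty and df.columns.size == 0:
        logger.warning("crime table %s is empty", path)
        return [], 0
    lookup = _ci_column_lookup(df)
    missing = [c for c in _REQUIRED_CRIME_COLUMNS if c.lower() not in lookup]
    if missing:
        raise SchemaError(f"crime table missing required columns: {missing}")
    if df.empty:
        logger.warning("crime table %s has a header but no rows", path)
        return [], 0

    def col(name, default=""):
        key = name.lower()
        if key in lookup:
            series = df[lookup[key]]
            return series if default is None else series.fillna(default)
        return pd.Series([default] * len(df), index=df.index)

    lon = pd.to_numeric(col("Longitude", None), errors="coerce")
    lat = pd.to_numeric(col("Latitude", None), errors="coerce")
    ok = lon.notna() & lat.notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d crime rows with unparseable coordinates",
                       n_dropped)

    ctype = col("Crime type")
    keep = ok if crime_type_filter is None else ok & ctype.isin(set(crime_type_filter))
    idx = df.index[keep]
    if len(idx) == 0:
        return [], n_dropped

    x, y = crs.to_planar(lon[idx].to_numpy(), lat[idx].to_numpy())
    x = np.atleast_1d(x)
    y = np.atleast_1d(y)

    cid = col("Crime ID")
    month = col("Month")
    rep = col("Reported by")
    fw = col("Falls within")
    lcode = col("LSOA code")
    lname = col("LSOA name")
    outc = col("Last outcome category", None)
    records = [
        CrimeRecord(
            crime_id=str(cid[i]), month=str(month[i]), reported_by=str(rep[i]),
            falls_within=str(fw[i]), x=float(x[j]), y=float(y[j]),
            lsoa_code=str(lcode[i]), lsoa_name=str(lname[i]),
            crime_type=str(ctype[i]),
            outcome=None if outc[i] is None or pd.isna(outc[i]) else str(outc[i]),
        )
        for j, i in enumerate(idx)
    ]
    return records, n_dropped


def read_poi_table(path, column_map=None, crs=None, coords="planar",
                   ) -> tuple[list[PoiRecord], pd.DataFrame]:
    """Read a POI CSV, returning records plus the distinct class hierarchy.

    ``column_map`` maps the logical fields (x, y, name, class_name,
    category, group) to CSV column names; matching is case-insensitive.
    ``coords`` is ``"planar"`` (metres, the default for Ordnance-Survey
    style grid references) or ``"lonlat"`` (projected through ``crs``).

    Raises
    ------
    HierarchyError
        If any class maps to more than one (category, group) pair.
    """
    cmap = dict(DEFAULT_POI_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        return [], pd.DataFrame(columns=["class_name", "category", "group"])
    lookup = _ci_column_lookup(df)
    missing = [v for v in cmap.values() if v.lower() not in lookup]
    if missing:
        raise SchemaError(f"POI table missing required columns: {missing}")
    cols = {k: df[lookup[v.lower()]] for k, v in cmap.items()}

    x = pd.to_numeric(cols["x"], errors="coerce").to_numpy()
    y = pd.to_numeric(cols["y"], errors="coerce").to_numpy()
    if coords == "lonlat":
        crs = crs or BritishNationalGrid()
        x, y = crs.to_planar(x, y)
    elif coords != "planar":
        raise ValueError("coords must be 'planar' or 'lonlat'")

    records = [
        PoiRecord(x=float(x[i]), y=float(y[i]), name=str(cols["name"].iloc[i]),
                  class_name=str(cols["class_name"].iloc[i]),
                  category=str(cols["category"].iloc[i]),
                  group=str(cols["group"].iloc[i]))
        for i in range(len(df))
    ]

    hier = (pd.DataFrame({k: [getattr(r, k) for r in records]
                          for k in ("class_name", "category", "group")})
            .drop_duplicates().sort_values("class_name").reset_index(drop=True))
    bad = hier.groupby("class_name").size()
    offenders = bad[bad > 1].index.tolist()
    if offenders:
        raise HierarchyError(
            f"classes mapped to multiple categories/groups: {offenders}")
    return records, hier


def window_points(points: PointSet, area: StudyArea, pad: float = 0.0) -> PointSet:
    """Keep points inside the padded study square.

    The window is the axis-aligned square of side ``area.side + 2*pad``
    centred on the area centre, with a half-open [min, max) boundary
    convention (a point exactly on the min edge is kept, on the max edge
    dropped) so tiled windows never double-count.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    half = area.side / 2 + pad
    xmin, xmax = area.centre_x - half, area.centre_x + half
    ymin, ymax = area.centre_y - half, area.centre_y + half
    p = points.points
    if len(points) == 0:
        return PointSet(points.label, p)
    keep = ((p[:, 0] >= xmin) & (p[:, 0] < xmax)
            & (p[:, 1] >= ymin) & (p[:, 1] < ymax))
    return PointSet(points.label, p[keep])


def grid_geometry(area: StudyArea) -> np.ndarray:
    """Cell-centre sample coordinates, shape (n_cells_per_side**2, 2).

    Row-major flattening with the row index increasing with y and the
    column index with x: sample ``r * n + c`` sits at
    ``(xmin + (c + 0.5) * cell, ymin + (r + 0.5) * cell)``.  This ordering
    is the contract that basis-matrix columns and flattened crime-density
    vectors align to.
    """
    n = area.n_cells_per_side
    cs = area.cell_size
    centres = (np.arange(n) + 0.5) * cs
    xs = area.xmin + centres
    ys = area.ymin + centres
    xx, yy = np.meshgrid(xs, ys)  # yy varies along axis 0 (rows)
    return np.column_stack([xx.ravel(), yy.ravel()])
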