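"""Rasterization of fishing activity and visitation-series construction.

Fishing pings are discretized onto a rectangular grid (default 30 x 30)
fitted to the extent of the fleet's fishing activity.  Consecutive fishing
pings in one cell collapse into a visit bout; the chronological sequence of
bout cells per vessel is its visitation series, the input to the choice
entropy and patch-residence-time metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from eetolab.errors import ConfigurationError, SchemaError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Rectangular grid tiling an extent with half-open cells.

    Cells are indexed by integer ``(col, row)`` with cell ``(0, 0)`` at the
    minimum corner.  Cells are half-open ``[low, high)`` in both axes except
    that the maximal row and column are closed above, so every point of the
    extent (including the maximum corner) is assignable.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    n_cols: int
    n_rows: int

    def __post_init__(self):
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ConfigurationError("grid extent is degenerate (zero width or height)")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ConfigurationError("grid must have at least one row and column")

    @property
    def cell_width(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_cols

    @property
    def cell_height(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_rows

    @property
    def n_cells(self) -> int:
        return self.n_cols * self.n_rows

    def assign(self, lon, lat):
        """Map points to integer ``(col, row)`` cell indices (vectorized)."""
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        inside = (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )
        if not np.all(inside):
            raise ValueError(
                f"{int((~inside).sum())} point(s) outside the grid extent; clean the pings first"
            )
        col = np.floor((lon - self.lon_min) / self.cell_width).astype(int)
        row = np.floor((lat - self.lat_min) / self.cell_height).astype(int)
        # closed-top convention: the extent maximum belongs to the last cell
        col = np.minimum(col, self.n_cols - 1)
        row = np.minimum(row, self.n_rows - 1)
        return col, row

    def cell_center(self, col, row):
        """Lon/lat of cell centers (vectorized)."""
        col = np.asarray(col)
        row = np.asarray(row)
        lon = self.lon_min + (col + 0.5) * self.cell_width
        lat = self.lat_min + (row + 0.5) * self.cell_height
        return lon, lat

    def cell_id(self, col, row):
        """Flat integer id ``row * n_cols + col``."""
        return np.asarray(row) * self.n_cols + np.asarray(col)


def build_grid(fishing_pings: pd.DataFrame, n: int = 30) -> GridSpec:
    """Fit an ``n x n`` grid to the bounding box of the fleet's fishing pings."""
    if fishing_pings is None or len(fishing_pings) == 0:
        raise ConfigurationError("cannot build a grid from an empty fishing-ping set")
    lon = fishing_pings["lon"].to_numpy()
    lat = fishing_pings["lat"].to_numpy()
    if lon.min() == lon.max() or lat.min() == lat.max():
        raise ConfigurationError("fishing pings span a degenerate (zero-width) extent")
    return GridSpec(
        lon_min=float(lon.min()),
        lon_max=float(lon.max()),
        lat_min=float(lat.min()),
        lat_max=float(lat.max()),
        n_cols=n,
        n_rows=n,
    )


def assign_cells(grid: GridSpec, fishing_pings: pd.DataFrame) -> pd.DataFrame:
    """Attach ``cell_col``/``cell_row`` columns to fishing pings."""
    out = fishing_pings.copy()
    col, row = grid.assign(out["lon"].to_numpy(), out["lat"].to_numpy())
    out["cell_col"] = col
    out["cell_row"] = row
    return out


def build_visitation_series(
    classified_pings: pd.DataFrame,
    grid: GridSpec,
    ping_interval_hours: float = 1.0,
    per_ping: bool = False,
) -> dict:
    """Build each vessel's chronological visitation series.

    Consecutive fishing pings in the same cell form one visit bout; a new
    series element is appended when the fished cell changes or after any
    intervening port visit (so a return to the same cell after a port call
    repeats the element).  Bout duration is ``(last - first ping timestamp)
    + ping_interval``, giving single-ping bouts one interval of residence.

    With ``per_ping=True`` every fishing ping becomes its own element
    (sensitivity mode).

    Returns ``{vessel_id: DataFrame(seq_index, cell_col, cell_row,
    bout_start, bout_end, n_pings, duration_h)}``.  Vessels with zero
    fishing pings map to an empty frame (with a warning).
    """
    needed = ["vessel_id", "timestamp", "lon", "lat", "activity"]
    missing = [c for c in needed if c not in classified_pings.columns]
    if missing:
        raise SchemaError(f"classified ping table is missing columns: {missing}")
    cols = [
        "seq_index",
        "cell_col",
        "cell_row",
        "bout_start",
        "bout_end",
        "n_pings",
        "duration_h",
    ]
    interval = pd.Timedelta(hours=ping_interval_hours)
    series: dict = {}
    df = classified_pings.sort_values(["vessel_id", "timestamp"], kind="mergesort")
    for vid, grp in df.groupby("vessel_id", sort=False):
        act = grp["activity"].to_numpy()
        fishing = act == "fishing"
        if not fishing.any():
            log.warning("vessel %s has no fishing pings; empty visitation series", vid)
            series[vid] = pd.DataFrame(columns=cols)
            continue
        sub = grp.loc[fishing]
        col, row = grid.assign(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        ts = pd.DatetimeIndex(pd.to_datetime(sub["timestamp"], utc=True))
        # index (into grp) of each fishing ping, to detect intervening port visits
        fidx = np.flatnonzero(fishing)
        port_pos = np.flatnonzero(act == "port")
        port_between = np.zeros(len(fidx), dtype=bool)
        if len(port_pos) and len(fidx) > 1:
            # port ping strictly between consecutive fishing pings?
            prev = fidx[:-1]
            nxt = fidx[1:]
            counts = np.searchsorted(port_pos, nxt) - np.searchsorted(port_pos, prev, side="right")
            port_between[1:] = counts > 0
        breaks = [
            k
            for k in range(1, len(fidx))
            if per_ping or col[k] != col[k - 1] or row[k] != row[k - 1] or port_between[k]
        ]
        starts = [0, *breaks]
        ends = [*(k - 1 for k in breaks), len(fidx) - 1]
        bouts = list(zip(starts, ends))
        rows_out = []
        for si, (a, b) in enumerate(bouts):
            dur = (ts[b] - ts[a]) / pd.Timedelta(hours=1) + ping_interval_hours
            rows_out.append(
                {
                    "seq_index": si,
                    "cell_col": int(col[a]),
                    "cell_row": int(row[a]),
                    "bout_start": ts[a],
                    "bout_end": ts[b] + interval,
                    "n_pings": b - a + 1,
                    "duration_h": float(dur),
                }
            )
        series[vid] = pd.DataFrame(rows_out, columns=cols)
    return series


def portfolio_from_series(series: pd.DataFrame) -> pd.DataFrame:
    """Per-cell fishing-ping counts (the vessel's portfolio) from its series."""
    if len(series) == 0:
        return pd.DataFrame(columns=["cell_col", "cell_row", "n_pings"])
    return (
        series.groupby(["cell_col", "cell_row"], as_index=False)["n_pings"].sum().sort_values(
            ["cell_col", "cell_row"], ignore_index=True
        )
    )
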