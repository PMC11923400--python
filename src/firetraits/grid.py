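"""Grid geometry and the fire-event raster container.

The fire history is represented as a regular grid of cells (emulating a
500-m burnt-area product) observed over a fixed window of decimal years.
Each cell carries a sorted list of dated burn events; two events on the
same date in the same cell collapse to one, mirroring the semantics of a
monthly burn-scar product that cannot resolve repeat burns within a date.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["LandscapeSpec", "FireEventRaster"]


@dataclasses.dataclass(frozen=True)
class LandscapeSpec:
    """Geometry and observation window of a gridded fire history.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; at least 1 each.
    cell_size
        Cell edge length in the coordinate units of the occurrence data
        (abstract; the default emulates 500 m expressed in decimal degrees).
    window_start, window_end
        Observation window in decimal years, ``window_end > window_start``.
        The default 22-year window emulates a Nov 2000 - Oct 2022 record.
    origin
        (x, y) of the outer corner of cell (row=0, col=0). Rows advance
        along y, columns along x.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 0.005
    window_start: float = 2000.833
    window_end: float = 2022.833
    origin: tuple[float, float] = (115.0, -38.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("n_rows and n_cols must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not self.window_end > self.window_start:
            raise ValueError("window_end must exceed window_start")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def window_years(self) -> float:
        """Window length T in years."""
        return self.window_end - self.window_start

    def cell_of(self, x, y):
        """Map coordinates to (row, col) with half-open [edge, edge+size) cells.

        Points outside the grid map to (-1, -1).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def cell_center(self, row, col):
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_size
        return x, y


class FireEventRaster:
    """Per-cell dated fire events on a regular grid over a time window.

    Internally events are a table with columns ``row``, ``col``, ``time``
    (decimal years, strictly within the window), sorted by (row, col, time),
    plus a dense (n_rows, n_cols) integer count array kept consistent with
    the table.
    """

    def __init__(self, spec: LandscapeSpec, events: pd.DataFrame | None = None):
        self.spec = spec
        if events is None:
            events = pd.DataFrame({"row": [], "col": [], "time": []})
        events = events.astype({"row": int, "col": int, "time": float})
        if len(events):
            t = events["time"].to_numpy()
            if (t < spec.window_start).any() or (t >= spec.window_end).any():
                raise ValueError("event times must lie within [window_start, window_end)")
            r, c = events["row"].to_numpy(), events["col"].to_numpy()
            if (r < 0).any() or (r >= spec.n_rows).any() or (c < 0).any() or (c >= spec.n_cols).any():
                raise ValueError("event cell indices outside grid")
        # same-date same-cell events are indistinguishable: collapse them
        events = events.drop_duplicates(["row", "col", "time"])
        events = events.sort_values(["row", "col", "time"], kind="mergesort").reset_index(drop=True)
        self.events = events
        counts = np.zeros((spec.n_rows, spec.n_cols), dtype=np.int64)
        if len(events):
            np.add.at(counts, (events["row"].to_numpy(), events["col"].to_numpy()), 1)
        self.counts = counts

    @property
    def total_events(self) -> int:
        return int(self.counts.sum())

    def cell_events(self, row: int, col: int) -> np.ndarray:
        """Sorted event times (decimal years) for one cell."""
        ev = self.events
        mask = (ev["row"] == row) & (ev["col"] == col)
        return ev.loc[mask, "time"].to_numpy()

    def counts_for_cells(self, rows, cols) -> np.ndarray:
        return self.counts[np.asarray(rows, dtype=int), np.asarray(cols, dtype=int)]

    # ---- persistence -------------------------------------------------

    def to_files(self, counts_path: str | Path, events_path: str | Path) -> None:
        """Write counts as NetCDF (grid metadata in attrs) and events as CSV."""
        spec = self.spec
        ds = xr.Dataset(
            {"counts": (("row", "col"), self.counts.astype("int32"))},
            attrs={
                "cell_size": spec.cell_size,
                "window_start": spec.window_start,
                "window_end": spec.window_end,
                "origin_x": spec.origin[0],
                "origin_y": spec.origin[1],
            },
        )
        ds.to_netcdf(counts_path, engine="scipy")
        self.events.to_csv(events_path, index=False)

    @classmethod
    def from_files(cls, counts_path: str | Path, events_path: str | Path) -> "FireEventRaster":
        with xr.open_dataset(counts_path, engine="scipy") as ds:
            a = ds.attrs
            spec = LandscapeSpec(
                n_rows=ds.sizes["row"],
                n_cols=ds.sizes["col"],
                cell_size=float(a["cell_size"]),
                window_start=float(a["window_start"]),
                window_end=float(a["window_end"]),
                origin=(float(a["origin_x"]), float(a["origin_y"])),
            )
            counts = ds["counts"].to_numpy()
        events = pd.read_csv(events_path)
        raster = cls(spec, events)
        if not np.array_equal(raster.counts, counts):
            raise ValueError("event table inconsistent with stored counts")
        return raster
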