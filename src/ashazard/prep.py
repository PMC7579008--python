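"""From raw sample points to the modeling table.

Survey compilations are heavily clustered in space, so concentrations are
first averaged onto the prediction grid (one representative point per
occupied cell, at the cell center), then recoded to a binary exceedance
label at the 10 µg/L guideline — averaging strictly precedes recoding — and
finally joined to the predictor values at each point's cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec, RasterGrid

__all__ = [
    "GUIDELINE_UG_L",
    "ModelingTable",
    "aggregate_to_grid",
    "recode_binary",
    "extract_predictors",
    "build_modeling_table",
]

logger = logging.getLogger(__name__)

GUIDELINE_UG_L = 10.0


@dataclass
class ModelingTable:
    """Aggregated, labeled points joined to predictor values.

    ``frame`` has one row per occupied grid cell with columns ``row``,
    ``col``, ``lon``, ``lat``, ``as_ugL``, ``label`` plus one column per
    predictor.  Categorical predictors are pandas ``Categorical`` columns.
    """

    frame: pd.DataFrame
    predictor_cols: list[str]
    categorical_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in self.predictor_cols if c not in self.frame.columns]
        if missing:
            raise ValueError(f"predictor columns missing from frame: {missing}")
        bad = set(self.categorical_cols) - set(self.predictor_cols)
        if bad:
            raise ValueError(f"categorical columns not among predictors: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.predictor_cols]

    def subset(self, index) -> "ModelingTable":
        return ModelingTable(
            frame=self.frame.loc[index].copy(),
            predictor_cols=list(self.predictor_cols),
            categorical_cols=list(self.categorical_cols),
        )


def _validate_points(points: pd.DataFrame) -> pd.DataFrame:
    required = {"lon", "lat", "as_ugL"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"points table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(points[["lon", "lat"]].to_numpy())):
        raise ValueError("point coordinates must be finite")
    conc = points["as_ugL"].to_numpy(dtype=float)
    if np.any(~np.isfinite(conc)) or np.any(conc < 0):
        raise ValueError("concentrations must be finite and >= 0")
    return points


def aggregate_to_grid(points: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Average concentrations per grid cell (one point per occupied cell).

    Points outside the grid extent are dropped with a logged count.  The
    output point sits at the cell center with the arithmetic-mean
    concentration of the cell's members; rows are ordered canonically by
    (row, col) so the result is invariant to input order.
    """
    if len(points) == 0:
        logger.warning("aggregate_to_grid: empty input, returning empty output")
        return pd.DataFrame(columns=["row", "col", "lon", "lat", "as_ugL"])
    points = _validate_points(points)
    inside = grid.contains(points["lon"].to_numpy(), points["lat"].to_numpy())
    n_dropped = int((~inside).sum())
    if n_dropped:
        logger.info("aggregate_to_grid: dropped %d points outside the grid extent", n_dropped)
    pts = points.loc[inside]
    if len(pts) == 0:
        logger.warning("aggregate_to_grid: no points inside the grid extent")
        return pd.DataFrame(columns=["row", "col", "lon", "lat", "as_ugL"])
    row, col = grid.cell_of(pts["lon"].to_numpy(), pts["lat"].to_numpy())
    grouped = (
        pd.DataFrame({"row": row, "col": col, "as_ugL": pts["as_ugL"].to_numpy(dtype=float)})
        .groupby(["row", "col"], as_index=False)["as_ugL"]
        .mean()
        .sort_values(["row", "col"], kind="stable", ignore_index=True)
    )
    lon, lat = grid.center_of(grouped["row"].to_numpy(), grouped["col"].to_numpy())
    grouped["lon"] = lon
    grouped["lat"] = lat
    return grouped[["row", "col", "lon", "lat", "as_ugL"]]


def recode_binary(concentrations, threshold: float = GUIDELINE_UG_L) -> np.ndarray:
    """Binary exceedance labels: 1 iff concentration > threshold.

    A value exactly at the threshold maps to 0 (the guideline is an
    acceptable limit, so 10 µg/L itself does not exceed it).
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(~np.isfinite(conc)) or np.any(conc < 0):
        raise ValueError("concentrations must be finite and >= 0")
    return (conc > threshold).astype(np.int64)


def extract_predictors(
    points: pd.DataFrame,
    predictors: dict[str, RasterGrid],
    categorical: tuple[str, ...] | list[str] = (),
    threshold: float = GUIDELINE_UG_L,
) -> ModelingTable:
    """Join each point to every predictor value at its location.

    The predictor rasters must be co-registered with each other but need not
    share the aggregation grid; lookup is point-in-cell per raster.  Rows
    hitting nodata (or falling outside the raster extent) in any predictor
    are dropped and counted in the log.  Raises if no rows survive.
    """
    if not predictors:
        raise ValueError("need at least one predictor raster")
    points = _validate_points(points).reset_index(drop=True)
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)

    columns: dict[str, np.ndarray] = {}
    for name, raster in predictors.items():
        columns[name] = raster.values_at(lon, lat)

    values = np.column_stack(list(columns.values()))
    keep = ~np.isnan(values).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "extract_predictors: dropped %d points with nodata or outside the raster extent",
            n_dropped,
        )
    if not keep.any():
        raise ValueError("no points remain after dropping nodata/out-of-extent rows")

    frame = points.loc[keep, [c for c in ("row", "col", "lon", "lat", "as_ugL") if c in points]]
    frame = frame.reset_index(drop=True)
    frame["label"] = recode_binary(frame["as_ugL"].to_numpy(), threshold)
    for name in columns:
        col = columns[name][keep]
        if name in categorical:
            frame[name] = pd.Categorical(col.astype(np.int64))
        else:
            frame[name] = col
    return ModelingTable(
        frame=frame,
        predictor_cols=list(predictors),
        categorical_cols=[c for c in predictors if c in categorical],
    )


def build_modeling_table(
    points: pd.DataFrame,
    grid: GridSpec,
    predictors: dict[str, RasterGrid],
    categorical: tuple[str, ...] | list[str] = (),
    threshold: float = GUIDELINE_UG_L,
) -> ModelingTable:
    """aggregate → extract → recode, in the canonical order."""
    aggregated = aggregate_to_grid(points, grid)
    if len(aggregated) == 0:
        raise ValueError("aggregation produced no points")
    return extract_predictors(aggregated, predictors, categorical, threshold)
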