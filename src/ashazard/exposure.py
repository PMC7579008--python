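"""Hazard maps and population-at-risk estimation.

A probability map is turned into a binary hazard map by thresholding at a
cutoff; population at risk is then the per-cell product

    probability x population x groundwater-use rate (rural or urban)

summed over hazard cells only.  Cells below the cutoff contribute nothing,
which makes the estimate conservative where contamination is localized.
Results are reported per region and in total, as a low-high range across
the two cutoffs (the higher cutoff flags fewer cells, hence the low end).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .grids import RasterGrid, require_coregistered
from .synthetic import Region

__all__ = [
    "ExposureConfig",
    "hazard_map",
    "exposed_population",
    "regional_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExposureConfig:
    """Use rates of untreated groundwater and the pair of hazard cutoffs.

    The default rates are nationwide household estimates: 0.637 of the
    rural and 0.238 of the urban population drink untreated groundwater.
    """

    rural_use_rate: float = 0.637
    urban_use_rate: float = 0.238
    cutoffs: tuple[float, float] = (0.49, 0.55)

    def __post_init__(self) -> None:
        for name, rate in (
            ("rural_use_rate", self.rural_use_rate),
            ("urban_use_rate", self.urban_use_rate),
        ):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if any(not 0 <= c <= 1 for c in self.cutoffs):
            raise ValueError(f"cutoffs must lie in [0, 1], got {self.cutoffs}")


def _check_probabilities(prob: RasterGrid) -> None:
    data = prob.data
    valid = data[~np.isnan(data)]
    if valid.size and (valid.min() < 0 or valid.max() > 1):
        raise ValueError("probability raster has values outside [0, 1]")


def hazard_map(prob: RasterGrid, cutoff: float) -> RasterGrid:
    """Binary raster: 1 iff probability > cutoff; nodata propagates."""
    if not 0 <= cutoff <= 1:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    _check_probabilities(prob)
    data = np.where(np.isnan(prob.data), np.nan, (prob.data > cutoff).astype(float))
    return prob.copy_with(data)


def exposed_population(
    prob: RasterGrid,
    cutoff: float,
    population: RasterGrid,
    urban: RasterGrid,
    config: ExposureConfig = ExposureConfig(),
) -> tuple[float, RasterGrid]:
    """Population at risk above a cutoff, with the per-cell exposure raster.

    Per cell: probability x population x use rate if the cell is hazard
    (probability > cutoff), else 0.  Nodata in the probability raster
    propagates to the exposure raster and contributes nothing to the total.
    """
    require_coregistered(probability=prob, population=population, urban=urban)
    hazard = hazard_map(prob, cutoff)
    rate = np.where(urban.data > 0, config.urban_use_rate, config.rural_use_rate)
    cell = hazard.data * prob.data * population.data * rate
    total = float(np.nansum(cell))
    return total, prob.copy_with(cell)


def _region_masks(grid, regions: list[Region]) -> dict[str, np.ndarray]:
    """Cell-center-in-polygon membership mask per region."""
    lon, lat = grid.cell_centers()
    masks = {}
    for region in regions:
        inside = shapely.contains_xy(region.polygon, lon.ravel(), lat.ravel())
        masks[region.name] = inside.reshape(grid.shape)
        if not inside.any():
            logger.warning("region '%s' covers no grid cells", region.name)
    return masks


def regional_summary(
    prob: RasterGrid,
    population: RasterGrid,
    urban: RasterGrid,
    regions: list[Region],
    config: ExposureConfig = ExposureConfig(),
) -> pd.DataFrame:
    """Per-region and total affected area and population, as cutoff ranges.

    For each region and each of the two configured cutoffs: the percentage
    of the region's non-nodata cells flagged as hazard, and the summed
    exposure.  Columns report the low-high range over the cutoffs; since
    raising the cutoff shrinks the hazard set, the low end comes from the
    higher cutoff.  Regions with no flagged cells report zeros.
    """
    require_coregistered(probability=prob, population=population, urban=urban)
    c_low_end, c_high_end = max(config.cutoffs), min(config.cutoffs)  # low figures from high cutoff
    per_cutoff = {}
    for c in (c_low_end, c_high_end):
        hz = hazard_map(prob, c)
        _, expo = exposed_population(prob, c, population, urban, config)
        per_cutoff[c] = (hz.data, expo.data)

    masks = _region_masks(prob.spec, regions)
    valid = ~np.isnan(prob.data)

    rows = []
    for region in regions:
        mask = masks[region.name]
        n_valid = int((mask & valid).sum())
        entry = {"region": region.name, "n_cells": n_valid}
        for tag, c in (("low", c_low_end), ("high", c_high_end)):
            hz, expo = per_cutoff[c]
            flagged = int(np.nansum(hz[mask & valid]))
            entry[f"pct_area_{tag}"] = 100.0 * flagged / n_valid if n_valid else 0.0
            entry[f"population_{tag}"] = float(np.nansum(expo[mask]))
        rows.append(entry)

    total = {"region": "Total", "n_cells": int(valid.sum())}
    for tag, c in (("low", c_low_end), ("high", c_high_end)):
        hz, expo = per_cutoff[c]
        flagged = int(np.nansum(hz[valid]))
        total[f"pct_area_{tag}"] = 100.0 * flagged / valid.sum() if valid.any() else 0.0
        total[f"population_{tag}"] = float(np.nansum(expo))
    rows.append(total)
    return pd.DataFrame(rows)
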