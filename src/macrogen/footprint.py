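"""Anthropogenic predictors: historical land-use timing and modern footprint.

Two per-unit quantities:

* ``alcc_time`` — the oldest year (BP) at which a cell's anthropogenic
  land-cover-change fraction strictly exceeds a 20% threshold; cells never
  exceeding it score 0 (never substantially modified before
  industrialisation).  The first crossing is the event time even when the
  fraction later dips below the threshold again.
* ``footprint`` — the mean of a static 0–50 human-footprint raster over the
  cells intersecting each unit.

Cell values are aggregated to spatial units by unweighted means, exactly as
for the climate metrics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .climate import aggregate_to_units

ALCC_THRESHOLD = 0.20


def exceedance_time(years_bp, fractions, threshold: float = ALCC_THRESHOLD) -> float:
    """Oldest year BP at which the ALCC fraction strictly exceeds threshold.

    ``years_bp`` must be ordered oldest to youngest (descending BP).
    Returns 0 when the threshold is never exceeded.
    """
    years = np.asarray(years_bp, dtype=float)
    frac = np.asarray(fractions, dtype=float)
    if years.size != frac.size:
        raise ValueError("years and fractions differ in length")
    if years.size > 1 and np.any(np.diff(years) > 0):
        raise ValueError("series must be ordered oldest -> youngest (BP descending)")
    hit = np.nonzero(frac > threshold)[0]
    if hit.size == 0:
        return 0.0
    return float(years[hit[0]])


def exceedance_by_cell(alcc: pd.DataFrame,
                       threshold: float = ALCC_THRESHOLD) -> pd.DataFrame:
    """Exceedance time per cell from a long table (cell_id, year_bp, fraction)."""
    wide = alcc.pivot(index="cell_id", columns="year_bp", values="fraction")
    wide = wide.sort_index(axis=1, ascending=False)  # oldest -> youngest
    exceeded = wide.to_numpy() > threshold
    any_hit = exceeded.any(axis=1)
    first = exceeded.argmax(axis=1)
    years = wide.columns.to_numpy(dtype=float)
    times = np.where(any_hit, years[first], 0.0)
    return pd.DataFrame({"cell_id": wide.index, "alcc_time": times})


def mean_footprint(raster: pd.DataFrame, cell_geoms: dict,
                   units: dict) -> pd.DataFrame:
    """Unweighted mean footprint value over cells intersecting each unit.

    ``raster`` has columns cell_id, value (0-50).  Units intersecting no
    raster cell are omitted.
    """
    metrics = raster.rename(columns={"value": "footprint"})[
        ["cell_id", "footprint"]
    ]
    return aggregate_to_units(metrics, cell_geoms, units,
                              value_cols=("footprint",))


def human_predictors(alcc: pd.DataFrame, raster: pd.DataFrame,
                     cell_geoms: dict, units: dict,
                     threshold: float = ALCC_THRESHOLD) -> pd.DataFrame:
    """Per-unit table (unit_id, alcc_time, footprint)."""
    exc = exceedance_by_cell(alcc, threshold)
    exc_units = aggregate_to_units(exc, cell_geoms, units,
                                   value_cols=("alcc_time",))
    fp_units = mean_footprint(raster, cell_geoms, units)
    return exc_units.merge(fp_units, on="unit_id", how="inner")
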