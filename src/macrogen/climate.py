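"""Centennial climate trends, extreme centuries and local stability metrics.

The procedure mirrors how paleoclimate stability is commonly summarised for
macroecological models:

1. slide a 100-year window (1-year step) along the *global* mean annual
   temperature series and fit a regression line in each window;
2. call a window an *extreme century* when its slope is strictly greater
   than the 90th percentile (linear-interpolation quantile) of all window
   slopes;
3. for every climate grid cell and each extreme century, fit the local
   regression and record the slope ("trend") and the standard deviation of
   the residuals about the local line ("variability");
4. per cell, take the median trend and median variability over extreme
   centuries; per spatial unit, average the medians of the intersecting
   climate cells.

Window regressions default to generalized least squares with AR(1) errors,
estimated by Cochrane–Orcutt iteration (tolerance 1e-8 on rho, max 50
iterations, OLS fallback on non-convergence).  Plain OLS is available via
``method="ols"``.  Fits are vectorised over windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.strtree import STRtree

log = logging.getLogger(__name__)

WINDOW_LENGTH = 100


class InvalidWindowError(ValueError):
    """Requested window does not fit inside the series."""


class NoExtremeCenturiesError(ValueError):
    """No extreme windows supplied to a local-stability computation."""


@dataclass(frozen=True)
class CenturyWindow:
    """One 100-year window: start index, fitted slope, residual SD."""

    start: int
    slope: float
    resid_sd: float


def _ols_on_matrix(W: np.ndarray):
    """OLS slope and residual SD for each row of a window matrix."""
    window = W.shape[1]
    t = np.arange(window, dtype=float)
    tc = t - t.mean()
    stt = float(tc @ tc)
    Wc = W - W.mean(axis=1, keepdims=True)   # centred: avoids cancellation
    slopes = (Wc @ tc) / stt
    resid = Wc - slopes[:, None] * tc[None, :]
    return slopes, np.sqrt((resid * resid).mean(axis=1))


def _co_gls_on_matrix(W: np.ndarray, tol: float = 1e-8, max_iter: int = 50):
    """Cochrane–Orcutt AR(1) GLS per row of a window matrix (vectorised).

    Residual SD is always measured about the fitted line on the original
    (untransformed) scale.  Rows whose rho iteration does not converge fall
    back to their OLS estimates (logged).
    """
    n_win, window = W.shape
    t = np.arange(window, dtype=float)
    ols_slope, _ = _ols_on_matrix(W)
    ols_icept = W.mean(axis=1) - ols_slope * t.mean()

    slope, icept = ols_slope.copy(), ols_icept.copy()
    rho = np.zeros(n_win)
    converged = np.zeros(n_win, dtype=bool)
    active = np.arange(n_win)
    for _ in range(max_iter):
        Wa = W[active]
        resid = Wa - (icept[active, None] + slope[active, None] * t[None, :])
        num = (resid[:, 1:] * resid[:, :-1]).sum(axis=1)
        den = (resid[:, :-1] ** 2).sum(axis=1)
        new_rho = np.divide(num, den, out=np.zeros_like(num), where=den > 0.0)
        new_rho = np.clip(new_rho, -0.98, 0.98)
        done = np.abs(new_rho - rho[active]) < tol
        rho[active] = new_rho
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
        # quasi-differenced regression y*_s = y_s - rho y_{s-1} on (1-rho, t*)
        Wa = W[active]
        ra = rho[active]
        ys = Wa[:, 1:] - ra[:, None] * Wa[:, :-1]
        xs = t[None, 1:] - ra[:, None] * t[None, :-1]
        ones = 1.0 - ra
        m = window - 1
        s11 = m * ones**2
        s1x = ones * xs.sum(axis=1)
        sxx = (xs * xs).sum(axis=1)
        s1y = ones * ys.sum(axis=1)
        sxy = (xs * ys).sum(axis=1)
        det = s11 * sxx - s1x**2
        safe = det > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            slope[active] = np.where(
                safe, (s11 * sxy - s1x * s1y) / det, slope[active])
            a_star = np.where(safe, (sxx * s1y - s1x * sxy) / det, 0.0)
        icept[active] = np.where(
            safe, a_star / np.where(ones == 0, 1.0, ones), icept[active])
    # Treat an iteration stuck near the unit root as non-convergent: the
    # quasi-differenced design degenerates there and the slope is unstable.
    good = converged & (np.abs(rho) < 0.97)
    if not good.all():
        n_bad = int((~good).sum())
        log.info("Cochrane-Orcutt non-convergence in %d window(s); "
                 "falling back to OLS there", n_bad)
        slope = np.where(good, slope, ols_slope)
        icept = np.where(good, icept, ols_icept)
    resid = W - (icept[:, None] + slope[:, None] * t[None, :])
    return slope, np.sqrt((resid**2).mean(axis=1))


def _fit_matrix(W: np.ndarray, method: str):
    if method == "ols":
        return _ols_on_matrix(W)
    if method == "gls_ar1":
        return _co_gls_on_matrix(W)
    raise ValueError(f"unknown method {method!r}")


def window_slopes(values, window: int = WINDOW_LENGTH,
                  method: str = "gls_ar1"):
    """Slope and residual SD for every sliding window of a series."""
    v = np.asarray(values, dtype=float)
    if v.size < window:
        raise InvalidWindowError(
            f"series of length {v.size} shorter than window {window}"
        )
    W = np.lib.stride_tricks.sliding_window_view(v, window)
    return _fit_matrix(W, method)


def window_trend(values, start: int, window: int = WINDOW_LENGTH,
                 method: str = "gls_ar1") -> CenturyWindow:
    """Fit the single window starting at index ``start``."""
    v = np.asarray(values, dtype=float)
    if start < 0 or start + window > v.size:
        raise InvalidWindowError(
            f"window [{start}, {start + window}) outside series of length {v.size}"
        )
    slopes, sds = _fit_matrix(v[start:start + window][None, :], method)
    return CenturyWindow(start=start, slope=float(slopes[0]),
                         resid_sd=float(sds[0]))


def extreme_centuries(global_temp, window: int = WINDOW_LENGTH,
                      q: float = 0.90, method: str = "gls_ar1"):
    """Windows of the global series with slope strictly above the q-quantile.

    The threshold is the linear-interpolation empirical quantile of all
    window slopes; selection uses a strict inequality, so a degenerate
    slope distribution selects nothing.
    """
    slopes, sds = window_slopes(global_temp, window, method)
    threshold = np.quantile(slopes, q)
    # guard the strict comparison against floating-point jitter so that a
    # degenerate (all-equal) slope distribution selects nothing
    tol = 1e-8 * max(np.abs(slopes).max(), 1e-30)
    idx = np.nonzero(slopes > threshold + tol)[0]
    return [CenturyWindow(int(i), float(slopes[i]), float(sds[i]))
            for i in idx]


def local_stability(cell_values, windows, window: int = WINDOW_LENGTH,
                    method: str = "gls_ar1"):
    """Median local trend and residual SD over the extreme windows of a cell.

    Only the requested windows are fit (the extreme centuries identified on
    the global series), not the full sliding set.
    """
    if not windows:
        raise NoExtremeCenturiesError("empty extreme-window set")
    v = np.asarray(cell_values, dtype=float)
    starts = np.asarray([w.start for w in windows], dtype=int)
    if starts.min() < 0 or starts.max() + window > v.size:
        raise InvalidWindowError("extreme window outside the cell series")
    W = v[starts[:, None] + np.arange(window)[None, :]]
    slopes, sds = _fit_matrix(W, method)
    return float(np.median(slopes)), float(np.median(sds))


def stability_by_cell(series: pd.DataFrame, windows,
                      window: int = WINDOW_LENGTH,
                      method: str = "gls_ar1") -> pd.DataFrame:
    """Per-climate-cell median trend/variability for one climate variable.

    ``series`` is long format with columns cell_id, year, value; years in
    ascending time order within each cell.
    """
    if not windows:
        raise NoExtremeCenturiesError("empty extreme-window set")
    wide = series.pivot(index="cell_id", columns="year", values="value")
    wide = wide.sort_index(axis=1)
    vals = wide.to_numpy()
    n_cells, n_years = vals.shape
    starts = np.asarray([w.start for w in windows], dtype=int)
    if starts.min() < 0 or starts.max() + window > n_years:
        raise InvalidWindowError("extreme window outside the cell series")
    # one batched fit over (cell x extreme-window) rows
    idx = starts[:, None] + np.arange(window)[None, :]
    W = vals[:, idx].reshape(n_cells * starts.size, window)
    slopes, sds = _fit_matrix(W, method)
    slopes = slopes.reshape(n_cells, starts.size)
    sds = sds.reshape(n_cells, starts.size)
    return pd.DataFrame(
        {
            "cell_id": wide.index,
            "trend": np.median(slopes, axis=1),
            "variability": np.median(sds, axis=1),
        }
    )


def aggregate_to_units(cell_metrics: pd.DataFrame, cell_geoms: dict,
                       units: dict, value_cols=("trend", "variability")
                       ) -> pd.DataFrame:
    """Unweighted mean of cell metrics over cells intersecting each unit.

    ``cell_geoms`` maps cell_id -> projected polygon; ``units`` maps
    unit_id -> projected polygon.  Units intersecting no climate cell are
    omitted (missing downstream).
    """
    ids = list(cell_metrics["cell_id"])
    geoms = [cell_geoms[c] for c in ids]
    tree = STRtree(geoms)
    vals = cell_metrics.set_index("cell_id")[list(value_cols)]
    rows = []
    for uid, ug in units.items():
        hit = tree.query(ug, predicate="intersects")
        if len(hit) == 0:
            continue
        sub = vals.loc[[ids[int(i)] for i in hit]]
        rows.append((uid, *sub.mean(axis=0).tolist()))
    return pd.DataFrame(rows, columns=["unit_id", *value_cols])
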