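"""Inferential core: data-rich subsetting, OLS/AICc, hierarchical
partitioning with randomisation tests, multimodel inference, and the
spatial diagnostics (Dutilleul's modified t-test, Moran's I).

Hierarchical partitioning follows the classical goodness-of-fit
decomposition: the independent contribution (IC) of a predictor is its R²
increment averaged over all orderings in which predictors can enter the
model (a Shapley value over subsets), and the joint contribution is the
remainder of its simple-regression R².  The ICs of all predictors sum to
the full-model R² exactly.  All-subset R² values are computed from the
correlation matrix, which keeps the 2^p * n_rand model fits of the
randomisation test tractable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.stats as st
import statsmodels.api as sm

log = logging.getLogger(__name__)


class CollinearityError(ValueError):
    """Singular design matrix."""


class DegenerateInputError(ValueError):
    """An input vector has zero variance."""


class NoValidModelsError(ValueError):
    """The candidate model set is empty."""


class TooManyVariablesError(ValueError):
    """Hierarchical partitioning limited to p <= 12 (2^p model fits)."""


# ---------------------------------------------------------------------------
# data-rich subsetting and transforms
# ---------------------------------------------------------------------------

def data_rich_subset(cells: pd.DataFrame, min_coverage: float = 0.07,
                     count_threshold: float | None = None) -> pd.DataFrame:
    """Keep cells that are taxonomically well covered OR sequence rich.

    A cell is retained when ``coverage >= min_coverage`` or its sequence
    count reaches the count threshold, which defaults to one (sample)
    standard deviation of the sequence-count distribution over the *full*
    unfiltered cell set.
    """
    if count_threshold is None:
        count_threshold = float(cells["n_sequences"].std(ddof=1))
        if not np.isfinite(count_threshold):
            count_threshold = float("inf")
    keep = (cells["coverage"] >= min_coverage) | (
        cells["n_sequences"] >= count_threshold
    )
    return cells.loc[keep].copy()


def sqrt_transform(gd):
    """Element-wise square root of GD (grid-scale normalising transform)."""
    arr = np.asarray(gd, dtype=float)
    if np.any(arr < 0):
        raise ValueError("GD values must be non-negative")
    return np.sqrt(arr)


# ---------------------------------------------------------------------------
# OLS with small-sample AIC
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """An OLS fit of sqrt-GD (or GD) on a named predictor subset."""

    variables: tuple
    params: pd.Series           # intercept ("const") plus slopes
    r2: float
    r2_adj: float
    llf: float
    aicc: float
    resid: np.ndarray
    fitted: np.ndarray
    n: int

    @property
    def k(self) -> int:
        """Parameter count for AICc: slopes + intercept + residual variance."""
        return len(self.variables) + 2

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xd = sm.add_constant(X[list(self.variables)], has_constant="add")
        return Xd.to_numpy() @ self.params.reindex(Xd.columns).to_numpy()


def aicc_from_llf(llf: float, n: int, k: int) -> float:
    """Small-sample corrected AIC: -2l + 2K + 2K(K+1)/(n-K-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"n={n} too small for K={k} parameters")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def ols_fit(y, X: pd.DataFrame, variables=None) -> FittedModel:
    """Ordinary least squares with intercept and Gaussian AICc.

    ``X`` is a DataFrame of predictors; ``variables`` optionally restricts
    to a subset (default: all columns).
    """
    if variables is None:
        variables = tuple(X.columns)
    else:
        variables = tuple(variables)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= len(variables) + 2:
        raise ValueError(f"n={n} too small for {len(variables)} predictors")
    Xd = sm.add_constant(X[list(variables)], has_constant="add")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        raise CollinearityError(f"singular design for {variables}")
    res = sm.OLS(y, Xd).fit()
    rss = float(res.ssr)
    # Gaussian maximum log-likelihood with sigma^2 = RSS/n, floored so that
    # an exact fit stays finite (it then wins via the parameter penalty).
    sigma2 = max(rss / n, 1e-300)
    llf = -0.5 * n * (math.log(2 * math.pi) + math.log(sigma2) + 1.0)
    k = len(variables) + 2
    return FittedModel(
        variables=variables,
        params=res.params,
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        llf=llf,
        aicc=aicc_from_llf(llf, n, k),
        resid=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        n=n,
    )


# ---------------------------------------------------------------------------
# all-subset R-squared machinery (shared by HP and its randomisation test)
# ---------------------------------------------------------------------------

def _standardize(y, X):
    """Centre and scale y and the columns of X to unit Euclidean norm."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    if ynorm == 0:
        raise DegenerateInputError("response has zero variance")
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    if np.any(norms == 0):
        raise DegenerateInputError("a predictor has zero variance")
    return Xc / norms, yc / ynorm


def _subset_r2_table(C: np.ndarray, c: np.ndarray) -> np.ndarray:
    """R² for every predictor subset, indexed by bitmask.

    ``C`` is the predictor correlation matrix, ``c`` the predictor-response
    correlations (unit-norm standardisation makes R² = c_S' C_SS^{-1} c_S).
    """
    p = C.shape[0]
    r2 = np.zeros(1 << p)
    for mask in range(1, 1 << p):
        idx = [i for i in range(p) if mask >> i & 1]
        sub = np.ix_(idx, idx)
        try:
            r2[mask] = float(c[idx] @ np.linalg.solve(C[sub], c[idx]))
        except np.linalg.LinAlgError:
            r2[mask] = float(c[idx] @ np.linalg.lstsq(C[sub], c[idx],
                                                      rcond=None)[0])
    return r2


def _shapley_weights(p: int) -> np.ndarray:
    return np.array(
        [math.factorial(s) * math.factorial(p - 1 - s) / math.factorial(p)
         for s in range(p)]
    )


def _ic_from_table(r2: np.ndarray, p: int) -> np.ndarray:
    """Independent contribution of each variable from the all-subset table."""
    w = _shapley_weights(p)
    ic = np.zeros(p)
    for j in range(p):
        bit = 1 << j
        total = 0.0
        for mask in range(1 << p):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            total += w[s] * (r2[mask | bit] - r2[mask])
        ic[j] = total
    return ic


# ---------------------------------------------------------------------------
# hierarchical partitioning
# ---------------------------------------------------------------------------

@dataclass
class HPResult:
    """Per-variable independent and joint contributions."""

    table: pd.DataFrame     # index: variable; ic_raw, joint_raw, ic_pct
    r2_full: float


def hierarchical_partitioning(y, X: pd.DataFrame) -> HPResult:
    """Decompose the full-model R² into per-variable independent contributions.

    IC_raw is the Shapley-averaged R² increment of each variable over all
    entry orders; joint_raw = simple-regression R² minus IC_raw.  IC
    percentages are 100 * IC_raw / sum(IC_raw).
    """
    p = X.shape[1]
    if p > 12:
        raise TooManyVariablesError(f"p={p} > 12")
    U, u = _standardize(y, X)
    C = U.T @ U
    c = U.T @ u
    r2 = _subset_r2_table(C, c)
    ic = _ic_from_table(r2, p)
    simple = np.array([r2[1 << j] for j in range(p)])
    joint = simple - ic
    total = ic.sum()
    pct = 100.0 * ic / total if total > 0 else np.full(p, np.nan)
    table = pd.DataFrame(
        {"ic_raw": ic, "joint_raw": joint, "ic_pct": pct},
        index=list(X.columns),
    )
    return HPResult(table=table, r2_full=float(r2[(1 << p) - 1]))


def _permuted_ics(U, u, C, c, j: int, n_rand: int, rng) -> np.ndarray:
    """IC of variable j under ``n_rand`` permutations of its column.

    Permuting column j leaves every subset not containing j untouched, so
    only the correlations of j with y and with the other predictors change;
    each subset then contributes via the rank-one update
    R²(S+j) - R²(S) = (c_yj - a_S' c_Sj)² / (1 - c_Sj' C_SS^{-1} c_Sj).
    """
    n, p = U.shape
    xj = U[:, j]
    perms = rng.permuted(np.broadcast_to(xj, (n_rand, n)), axis=1).T  # n x R
    Cj = U.T @ perms            # p x R : corr of every predictor with perm j
    cyj = u @ perms             # R
    w = _shapley_weights(p)
    others = [i for i in range(p) if i != j]
    ic = np.zeros(n_rand)
    for r in range(1 << (p - 1)):
        idx = [others[i] for i in range(p - 1) if r >> i & 1]
        s = len(idx)
        if s == 0:
            ic += w[0] * cyj**2
            continue
        sub = np.ix_(idx, idx)
        cho = sla.cho_factor(C[sub])
        a = sla.cho_solve(cho, c[idx])                 # C_SS^-1 c_yS
        G = sla.cho_solve(cho, Cj[idx, :])             # s x R
        num = cyj - a @ Cj[idx, :]
        den = 1.0 - np.einsum("ir,ir->r", Cj[idx, :], G)
        inc = np.where(den > 1e-12, num**2 / np.maximum(den, 1e-12), 0.0)
        ic += w[s] * inc
    return ic


def hp_significance(y, X: pd.DataFrame, n_rand: int = 1000,
                    seed: int | np.random.Generator = 0,
                    q: float = 0.95):
    """Randomisation test of each variable's independent contribution.

    Each column is permuted ``n_rand`` times (others fixed) and its IC
    recomputed; a variable is significant iff its observed IC is strictly
    greater than the 95th percentile of its permuted ICs.

    Returns a DataFrame (index: variable) with observed IC, the permutation
    threshold and the significance flag.
    """
    p = X.shape[1]
    if p > 12:
        raise TooManyVariablesError(f"p={p} > 12")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    U, u = _standardize(y, X)
    C = U.T @ U
    c = U.T @ u
    obs = _ic_from_table(_subset_r2_table(C, c), p)
    rows = []
    for j in range(p):
        perm = _permuted_ics(U, u, C, c, j, n_rand, rng)
        thr = float(np.quantile(perm, q))
        rows.append((obs[j], thr, bool(obs[j] > thr)))
    return pd.DataFrame(rows, columns=["ic_raw", "threshold", "significant"],
                        index=list(X.columns))


def iterative_hp(y, X: pd.DataFrame, n_rand: int = 1000,
                 seed: int | np.random.Generator = 0):
    """Iterative exclusion of insignificant predictors.

    Starting from all columns, repeatedly drop the variable with the
    smallest insignificant IC (ties: the later column, logged) until every
    retained variable is significant.  Returns ``(retained, final_hp,
    history)`` where history is one significance table per iteration; the
    retained list may be empty (flagged in the log) when nothing survives.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    cols = list(X.columns)
    history = []
    while cols:
        sig = hp_significance(y, X[cols], n_rand=n_rand, seed=rng)
        history.append(sig)
        insig = sig.loc[~sig["significant"]]
        if insig.empty:
            break
        lowest = insig["ic_raw"].min()
        ties = [v for v in insig.index if insig.loc[v, "ic_raw"] == lowest]
        drop = ties[-1]  # later column first on ties
        if len(ties) > 1:
            log.info("IC tie among %s; dropping %s", ties, drop)
        cols.remove(drop)
    if not cols:
        log.warning("iterative HP excluded every variable")
        return [], None, history
    return cols, hierarchical_partitioning(y, X[cols]), history


# ---------------------------------------------------------------------------
# multimodel inference
# ---------------------------------------------------------------------------

@dataclass
class ModelSet:
    """Retained candidate models with AICc ranking and Akaike weights."""

    table: pd.DataFrame          # variables, aicc, r2, r2_adj, delta_aicc, weight
    saw: pd.Series               # summed Akaike weight per variable
    models: list = field(default_factory=list)   # FittedModel, same order


def multimodel_inference(y, X: pd.DataFrame, variables=None,
                         r_max: float = 0.7,
                         delta_max: float = 5.0) -> ModelSet:
    """AICc model selection over all subsets of the significant variables.

    Subsets containing a predictor pair with |Pearson r| > ``r_max`` are
    excluded before fitting; models with ΔAICc > ``delta_max`` are dropped
    and Akaike weights renormalised over the survivors.  SAW per variable is
    the sum of weights of retained models containing it.
    """
    if variables is None:
        variables = list(X.columns)
    variables = list(variables)
    if not variables:
        raise NoValidModelsError("no candidate variables")
    corr = X[variables].corr().to_numpy()
    bad_pairs = {
        (variables[i], variables[j])
        for i in range(len(variables)) for j in range(i + 1, len(variables))
        if abs(corr[i, j]) > r_max
    }
    fits = []
    for size in range(1, len(variables) + 1):
        for combo in itertools.combinations(variables, size):
            if any((a, b) in bad_pairs
                   for a, b in itertools.combinations(combo, 2)):
                continue
            fits.append(ols_fit(y, X, combo))
    if not fits:
        raise NoValidModelsError("collinearity filter removed every model")
    aiccs = np.array([f.aicc for f in fits])
    delta = aiccs - aiccs.min()
    keep = delta <= delta_max
    fits = [f for f, k in zip(fits, keep) if k]
    delta = delta[keep]
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    order = np.argsort(delta, kind="stable")
    fits = [fits[i] for i in order]
    delta, w = delta[order], w[order]
    table = pd.DataFrame(
        {
            "variables": [f.variables for f in fits],
            "aicc": [f.aicc for f in fits],
            "r2": [f.r2 for f in fits],
            "r2_adj": [f.r2_adj for f in fits],
            "delta_aicc": delta,
            "weight": w,
        }
    )
    saw = pd.Series(0.0, index=variables)
    for f, wi in zip(fits, w):
        for v in f.variables:
            saw[v] += wi
    return ModelSet(table=table, saw=saw, models=fits)


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------

@dataclass
class SpatialWeights:
    """Row-standardised neighbour weights for n spatial units."""

    n: int
    neighbors: list              # per-unit array of neighbour indices
    W: sp.csr_matrix             # row-standardised
    islands: list = field(default_factory=list)


def build_weights(coords=None, polygons=None, scheme: str = "knn",
                  k: int = 4) -> SpatialWeights:
    """kNN (projected centroids) or contiguity (shared boundary) weights.

    kNN uses Euclidean distance with ties broken by unit order; contiguity
    links polygons sharing any boundary point.  Rows are standardised to sum
    to one; polygons with no neighbour become islands with an empty row.
    """
    if scheme == "knn":
        pts = np.asarray(coords, dtype=float)
        n = pts.shape[0]
        if n <= k:
            raise ValueError(f"need more than k={k} units, got {n}")
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        order_ids = np.broadcast_to(np.arange(n), (n, n))
        neighbors = []
        for i in range(n):
            idx = np.lexsort((order_ids[i], d[i]))[:k]
            neighbors.append(np.sort(idx))
    elif scheme == "contiguity":
        from shapely.strtree import STRtree

        geoms = list(polygons)
        n = len(geoms)
        tree = STRtree(geoms)
        neighbors = []
        for i, g in enumerate(geoms):
            hit = [int(j) for j in tree.query(g, predicate="intersects")
                   if int(j) != i]
            neighbors.append(np.array(sorted(hit), dtype=int))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    rows, cols, vals = [], [], []
    islands = []
    for i, nb in enumerate(neighbors):
        if len(nb) == 0:
            islands.append(i)
            continue
        rows.extend([i] * len(nb))
        cols.extend(nb.tolist())
        vals.extend([1.0 / len(nb)] * len(nb))
    if islands:
        log.warning("%d island unit(s) with no neighbours", len(islands))
    W = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return SpatialWeights(n=n, neighbors=neighbors, W=W, islands=islands)


def morans_i(values, weights: SpatialWeights, n_sims: int = 10000,
             seed: int | np.random.Generator = 0) -> dict:
    """Global Moran's I with a two-sided permutation test.

    I = (n/S0) z'Wz / z'z with z the centred values; the permutation p-value
    is two-sided around the null expectation E[I] = -1/(n-1) and uses the
    +1 correction.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    z = v - v.mean()
    denom = float(z @ z)
    if denom == 0:
        raise DegenerateInputError("values have zero variance")
    W = weights.W
    s0 = float(W.sum())
    i_obs = n / s0 * float(z @ (W @ z)) / denom
    e_i = -1.0 / (n - 1)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    idx = rng.permuted(np.broadcast_to(np.arange(n), (n_sims, n)), axis=1)
    zp = z[idx]                                   # n_sims x n
    wz = (W @ zp.T)                               # n x n_sims
    i_perm = n / s0 * np.einsum("sn,ns->s", zp, wz) / denom
    p = (1.0 + np.sum(np.abs(i_perm - e_i) >= abs(i_obs - e_i))) / (n_sims + 1.0)
    return {"I": i_obs, "EI": e_i, "p": float(p)}


def modified_ttest(x, y, coords, n_classes: int = 13) -> dict:
    """Dutilleul/Clifford-Richardson modified t-test of spatial association.

    The Pearson correlation of two variables observed at the same locations
    is tested with an effective sample size M-hat deflated by the product of
    the two variables' spatial autocorrelations, estimated over equal-width
    distance classes spanning (0, max pairwise distance].  The statistic
    F = (M-2) r² / (1-r²) is referred to F(1, M-2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pts = np.asarray(coords, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"need n >= 10, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    sx2 = float(xc @ xc) / n
    sy2 = float(yc @ yc) / n
    r = float(xc @ yc) / math.sqrt(float(xc @ xc) * float(yc @ yc))

    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    iu = np.triu_indices(n, 1)
    dp = d[iu]
    dmax = dp.max()
    if dmax == 0:
        raise ValueError("all coordinates coincide")
    cls = np.minimum((dp / dmax * n_classes).astype(int), n_classes - 1)
    px = xc[iu[0]] * xc[iu[1]]
    py = yc[iu[0]] * yc[iu[1]]
    acc = 0.0
    for kcls in range(n_classes):
        m = cls == kcls
        cnt = int(m.sum())
        if cnt == 0:
            continue
        rho_x = (px[m].mean()) / sx2
        rho_y = (py[m].mean()) / sy2
        acc += 2.0 * cnt * rho_x * rho_y   # ordered pairs
    v = (n + acc) / n**2
    if v <= 0:
        v = 1.0 / n
    m_hat = 1.0 + 1.0 / v
    df = m_hat - 2.0
    if df <= 0:
        return {"r": r, "ess": m_hat, "F": float("nan"), "p": 1.0}
    fstat = df * r**2 / max(1.0 - r**2, 1e-300)
    p = float(st.f.sf(fstat, 1, df))
    return {"r": r, "ess": m_hat, "F": fstat, "p": p}
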