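"""Synthetic test world with known ground truth.

Every input the pipeline consumes can be generated here: a dated Yule
phylogeny, circular species ranges, star-genealogy sequence alignments with
sampling coordinates, AR(1)-plus-trend annual climate series, anthropogenic
land-cover-change curves and a static human-footprint raster, and a GD
response constructed as a linear function of the predictors on the
square-root scale.

Design notes:

* Sequences evolve on a *star* genealogy — each of n sequences mutates
  independently from one random ancestral sequence, each site with
  probability p to a uniformly chosen different base.  Two lineages then
  differ at a site with probability ``2p(1-p) + (2/3)p^2``, which gives the
  per-species nucleotide diversity a closed-form expectation used as an
  analytic oracle.
* Ranges are 64-gon approximations of circles of a given radius drawn on
  the Behrmann equal-area plane, so their planar area is within ~0.2% of
  pi r^2.
* All randomness derives from one root seed through
  ``numpy.random.SeedSequence(root_seed, spawn_key=(component, index))``;
  each component (tree, ranges, per-species sequences, climate, footprint,
  response) has a fixed component id, so partial reruns reproduce exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, asdict

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .filters import GeoSequence, RangePolygon
from .projection import behrmann_forward, behrmann_inverse

# Component ids of the seed-derivation rule.
_TREE, _RANGES, _SEQUENCES, _CLIMATE, _FOOTPRINT, _RESPONSE = range(6)

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for the synthetic world.

    Defaults emulate a desk-scale version of a global mammal assemblage
    survey: tens of species with mitochondrial-marker-length alignments,
    per-site diversity around 1%, continental-scale circular ranges, and
    a few centuries-resolving millennia of annual climate.
    """

    n_species: int = 40
    seq_len: int = 800                    # bp, mitochondrial-marker scale
    n_seq_per_species: int = 12
    per_lineage_mut_prob: float = 0.01    # per-site, per lineage
    birth_rate: float = 0.1               # Yule births per My
    map_extent: tuple = (-60.0, 60.0, -40.0, 40.0)   # lon_min, lon_max, lat_min, lat_max
    range_radius_km: float = 1500.0
    n_trees: int = 10                     # posterior sample size
    climate_cell_deg: float = 2.5         # climate grid resolution (degrees)
    n_years: int = 600
    climate_trend: float = 0.01           # degC per year (global component)
    prec_trend: float = 0.5               # mm/yr per year
    ar_coef: float = 0.5
    noise_sd: float = 0.5                 # degC innovation SD
    prec_noise_sd: float = 20.0           # mm/yr innovation SD
    betas: tuple | None = None            # sqrt-scale response coefficients
    response_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1 or self.seq_len < 1 or self.n_seq_per_species < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.per_lineage_mut_prob < 0.75:
            raise ValueError("per_lineage_mut_prob must be in [0, 0.75)")
        if not abs(self.ar_coef) < 1.0:
            raise ValueError("|ar_coef| must be < 1")


def rng_for(seed: int, component: int, index: int = 0) -> np.random.Generator:
    """Derive a component generator from the root seed (documented rule)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(component, index))
    )


def species_label(i: int) -> str:
    return f"S{i:04d}"


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def _yule(n_species: int, birth_rate: float, rng) -> dendropy.Tree:
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    py_rng = random.Random(int(rng.integers(0, 2**31 - 1)))
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=py_rng,
    )
    # The simulator stops exactly at the n-th birth, leaving the two newest
    # tips with zero-length branches; run the clock on to the time of the
    # next (uncommitted) birth so every branch is positive and the tree
    # stays ultrametric.
    extra = float(rng.exponential(1.0 / (birth_rate * n_species)))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
        leaf.taxon.label = species_label(i)
    return tree


def simulate_tree(n_species: int, birth_rate: float,
                  seed: int) -> dendropy.Tree:
    """Ultrametric Yule tree with ``n_species`` extant tips (My branch lengths)."""
    return _yule(n_species, birth_rate, rng_for(seed, _TREE))


def simulate_posterior(n_species: int, birth_rate: float, seed: int,
                       n_trees: int = 10) -> list:
    """A 'posterior sample': independent Yule trees on the same tip labels."""
    return [_yule(n_species, birth_rate, rng_for(seed, _TREE, t))
            for t in range(n_trees)]


# ---------------------------------------------------------------------------
# ranges
# ---------------------------------------------------------------------------

def _circle_ring(lon: float, lat: float, radius_m: float,
                 n_vertices: int = 64) -> list:
    """64-gon circle of given planar radius around a lon/lat centre."""
    cx, cy = behrmann_forward(lon, lat)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    xs = cx + radius_m * np.cos(theta)
    ys = cy + radius_m * np.sin(theta)
    lons, lats = behrmann_inverse(xs, ys)
    ring = list(zip(lons.tolist(), lats.tolist()))
    ring.append(ring[0])
    return ring


def simulate_ranges(tips, extent, radius_km: float, seed: int,
                    n_decoys: int = 0) -> list:
    """One circular range per species, centred uniformly in the extent.

    Optionally appends ``n_decoys`` extra polygons carrying excluded
    presence/origin codes ({3,6}/{3,4}) for exercising the range filter.
    """
    tips = list(tips)
    if not tips:
        raise ValueError("empty tip list")
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    rng = rng_for(seed, _RANGES)
    lon_min, lon_max, lat_min, lat_max = extent
    polys = []
    for sp in tips:
        lon = float(rng.uniform(lon_min, lon_max))
        lat = float(rng.uniform(lat_min, lat_max))
        polys.append(
            RangePolygon(species_id=sp,
                         rings=[_circle_ring(lon, lat, radius_km * 1000.0)],
                         presence=1, origin=1)
        )
    bad_codes = [(3, 1), (6, 1), (1, 3), (1, 4)]
    for d in range(n_decoys):
        sp = tips[d % len(tips)]
        lon = float(rng.uniform(lon_min, lon_max))
        lat = float(rng.uniform(lat_min, lat_max))
        presence, origin = bad_codes[d % len(bad_codes)]
        polys.append(
            RangePolygon(species_id=sp,
                         rings=[_circle_ring(lon, lat, radius_km * 1000.0)],
                         presence=presence, origin=origin)
        )
    return polys


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _sample_point_in_polygon(poly, rng) -> tuple:
    """Uniform lon/lat point inside a shapely polygon by rejection sampling."""
    from shapely.geometry import Point

    minx, miny, maxx, maxy = poly.bounds
    for _ in range(10_000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if poly.covers(Point(x, y)):
            return float(x), float(y)
    raise RuntimeError("rejection sampling failed; degenerate polygon?")


def simulate_sequences(species_id: str, ancestral_len: int, p: float,
                       n: int, seed: int, species_index: int = 0,
                       range_poly: RangePolygon | None = None,
                       extent=( -60.0, 60.0, -40.0, 40.0)) -> list:
    """Star-genealogy alignment of ``n`` sequences for one species.

    Each sequence derives independently from one random ancestral sequence;
    each site mutates with probability ``p`` to a uniformly chosen different
    base.  Sampling coordinates are uniform inside the species' range
    polygon (or the map extent when no range is supplied).
    """
    if not 0.0 <= p < 0.75:
        raise ValueError("p must be in [0, 0.75)")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = rng_for(seed, _SEQUENCES, species_index)
    anc = rng.integers(0, 4, size=ancestral_len)
    mut = rng.random((n, ancestral_len)) < p
    shift = rng.integers(1, 4, size=(n, ancestral_len))
    seqs = np.where(mut, (anc[None, :] + shift) % 4, anc[None, :])

    if range_poly is not None:
        from shapely.geometry import Polygon

        poly = Polygon(range_poly.rings[0])
        pts = [_sample_point_in_polygon(poly, rng) for _ in range(n)]
    else:
        lon_min, lon_max, lat_min, lat_max = extent
        pts = [(float(rng.uniform(lon_min, lon_max)),
                float(rng.uniform(lat_min, lat_max))) for _ in range(n)]
    out = []
    for i in range(n):
        bases = "".join(_BASES[b] for b in seqs[i])
        lon, lat = pts[i]
        out.append(
            GeoSequence(sequence_id=f"{species_id}_{i:03d}",
                        species_id=species_id, bases=bases,
                        lon=lon, lat=lat)
        )
    return out


def expected_pi(p: float) -> float:
    """Closed-form E[Pi] under the two-lineage star model."""
    return 2.0 * p * (1.0 - p) + (2.0 / 3.0) * p * p


# ---------------------------------------------------------------------------
# climate and footprint
# ---------------------------------------------------------------------------

def climate_grid(extent, cell_deg: float = 10.0):
    """Regular lon/lat climate grid covering the extent.

    Returns ``(cell_ids, cell_geoms)`` with projected shapely boxes (the
    Behrmann projection maps lon/lat rectangles to rectangles exactly).
    """
    from shapely.geometry import box

    lon_min, lon_max, lat_min, lat_max = extent
    lons = np.arange(lon_min, lon_max, cell_deg)
    lats = np.arange(lat_min, lat_max, cell_deg)
    ids, geoms = [], {}
    for i, lo in enumerate(lons):
        for j, la in enumerate(lats):
            cid = f"C{i:03d}_{j:03d}"
            x0, y0 = behrmann_forward(lo, la)
            x1, y1 = behrmann_forward(min(lo + cell_deg, lon_max),
                                      min(la + cell_deg, lat_max))
            ids.append(cid)
            geoms[cid] = box(float(x0), float(y0), float(x1), float(y1))
    return ids, geoms


def simulate_climate(cells, trend, ar_coef: float, noise_sd: float,
                     n_years: int, seed: int, component_index: int = 0):
    """Trend + AR(1) annual series per cell and their unweighted global mean.

    ``trend`` may be a scalar (shared) or one value per cell.  Returns
    ``(long_df, global_series)`` where the long table has columns cell_id,
    year, value with year = 0..n_years-1 in ascending time order.
    """
    cells = list(cells)
    if n_years < 100:
        raise ValueError("n_years must be >= 100 (one century window)")
    if not abs(ar_coef) < 1.0:
        raise ValueError("|ar_coef| must be < 1")
    trends = np.broadcast_to(np.asarray(trend, dtype=float), (len(cells),))
    sds = np.broadcast_to(np.asarray(noise_sd, dtype=float), (len(cells),))
    rng = rng_for(seed, _CLIMATE, component_index)
    t = np.arange(n_years, dtype=float)
    if np.all(sds == 0):
        eps = np.zeros((len(cells), n_years))
    else:
        innov = sds[:, None] * rng.standard_normal((len(cells), n_years))
        eps = np.empty_like(innov)
        eps[:, 0] = innov[:, 0] / np.sqrt(1.0 - ar_coef**2)
        for s in range(1, n_years):   # AR recursion, vectorised over cells
            eps[:, s] = ar_coef * eps[:, s - 1] + innov[:, s]
    series = trends[:, None] * t[None, :] + eps
    long_df = pd.DataFrame(
        {
            "cell_id": np.repeat(cells, n_years),
            "year": np.tile(np.arange(n_years), len(cells)),
            "value": series.ravel(),
        }
    )
    global_series = series.mean(axis=0)
    return long_df, global_series


def simulate_footprint(cells, n_years_bp: int, seed: int):
    """ALCC logistic-growth curves and a static footprint value per cell.

    Returns ``(alcc_df, footprint_df)``: the ALCC table has columns
    cell_id, year_bp (8000 -> 100 scaled to ``n_years_bp``), fraction; the
    footprint table has cell_id, value in [0, 50].
    """
    cells = list(cells)
    rng = rng_for(seed, _FOOTPRINT)
    years = np.linspace(n_years_bp, 100, max(n_years_bp // 100, 2))
    fmax = rng.uniform(0.0, 0.6, size=len(cells))
    t0 = rng.uniform(100, n_years_bp, size=len(cells))
    rate = rng.uniform(0.001, 0.01, size=len(cells))
    # logistic growth toward the present, cell-specific onset and ceiling
    frac = fmax[:, None] / (1.0 + np.exp(-rate[:, None] * (t0[:, None] - years[None, :])))
    alcc = pd.DataFrame(
        {
            "cell_id": np.repeat(cells, years.size),
            "year_bp": np.tile(years, len(cells)),
            "fraction": frac.ravel(),
        }
    )
    fp = pd.DataFrame(
        {"cell_id": cells, "value": rng.uniform(0.0, 50.0, size=len(cells))}
    )
    return alcc, fp


# ---------------------------------------------------------------------------
# response
# ---------------------------------------------------------------------------

def simulate_response(predictors, betas, noise_sd: float, seed: int):
    """GD response as a linear model on the square-root scale.

    ``y = b0 + X b + N(0, noise_sd^2)`` and ``GD = y^2``, so the pipeline's
    square-root transform recovers an exactly linear model.  ``betas`` has
    the intercept first, then one coefficient per predictor column.

    Returns ``(gd, sqrt_scale_y)`` as arrays aligned with the rows.
    """
    X = np.asarray(predictors, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if betas.size != X.shape[1] + 1:
        raise ValueError(
            f"betas length {betas.size} != n_predictors + 1 = {X.shape[1] + 1}"
        )
    rng = rng_for(seed, _RESPONSE)
    y = betas[0] + X @ betas[1:]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=X.shape[0])
    return y**2, y


def config_truth(config: SimConfig) -> dict:
    """Ground-truth record written next to generated worlds."""
    d = asdict(config)
    d["expected_pi"] = expected_pi(config.per_lineage_mut_prob)
    return d
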