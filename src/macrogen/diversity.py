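"""Nucleotide diversity per species and assemblage genetic diversity (GD).

Within a species, nucleotide diversity is the average proportion of
differing sites over all valid pairwise sequence comparisons::

    Pi = (1 / n_valid_pairs) * sum_{i<j} k_ij / m_ij

where ``m_ij`` counts alignment positions at which both sequences carry an
unambiguous base (A/C/G/T; gaps and N are skipped) and ``k_ij`` counts those
positions where the bases differ.  A pair is valid only when the two
sequences overlap in at least 50% of the unambiguous length of the longer
sequence; invalid pairs are excluded from numerator and denominator alike
rather than counted as zero differences.

Assemblage GD for a spatial unit is then the plain average of the defined
Pi values over the species sampled in that unit::

    GD_t = (1/S) * sum_p Pi_p

Species with fewer than two sequences in a unit contribute nothing (Pi is
undefined for them, not zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree

from .projection import GridSpec

# Base encoding: A/C/G/T -> 0..3, anything non-informative -> 255.
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lower case


class AlignmentError(ValueError):
    """Sequences in one comparison have unequal aligned lengths."""


class InsufficientSequencesError(ValueError):
    """Fewer than two sequences available for a species."""


class EmptyAssemblageError(ValueError):
    """No species with a defined Pi in a spatial unit."""


@dataclass(frozen=True)
class PairwiseComparison:
    """Counts for one pairwise sequence comparison."""

    k: int        # differing sites among shared comparable sites
    m: int        # shared comparable (both A/C/G/T) sites
    valid: bool   # overlap >= 50% of the longer sequence's informative length


@dataclass(frozen=True)
class AssemblageGD:
    """Assemblage genetic diversity and bookkeeping for one spatial unit."""

    unit_id: object
    gd: float
    n_species_with_pi: int
    n_sequences: int
    taxonomic_coverage: float  # NaN when the range-derived species list is empty


def encode(bases: str) -> np.ndarray:
    """Encode an aligned sequence as uint8 codes (255 = gap/N)."""
    return _LUT[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]


def pairwise_diff(seq_i: str, seq_j: str) -> PairwiseComparison:
    """Count shared comparable sites and differences for one pair."""
    a, b = encode(seq_i), encode(seq_j)
    if a.shape != b.shape:
        raise AlignmentError(
            f"aligned lengths differ: {len(seq_i)} vs {len(seq_j)}"
        )
    ok = (a != 255) & (b != 255)
    m = int(ok.sum())
    k = int((ok & (a != b)).sum())
    l_long = max(int((a != 255).sum()), int((b != 255).sum()))
    valid = m >= 0.5 * l_long
    return PairwiseComparison(k=k, m=m, valid=valid)


def _pi_from_codes(codes: np.ndarray) -> float:
    """Vectorised Pi over all pairs of rows of an encoded alignment.

    Returns NaN when no valid pair exists.
    """
    n = codes.shape[0]
    informative = codes != 255
    info_len = informative.sum(axis=1)
    ratios = []
    for i in range(n - 1):
        ok = informative[i] & informative[i + 1:]
        m = ok.sum(axis=1)
        k = (ok & (codes[i] != codes[i + 1:])).sum(axis=1)
        l_long = np.maximum(info_len[i], info_len[i + 1:])
        valid = (m >= 0.5 * l_long) & (m > 0)
        if valid.any():
            ratios.append(k[valid] / m[valid])
    if not ratios:
        return float("nan")
    allr = np.concatenate(ratios)
    return float(allr.mean())


def species_pi(records) -> float:
    """Nucleotide diversity for one species' aligned sequences.

    ``records`` is a sequence of :class:`~macrogen.filters.GeoSequence` or of
    plain base strings.  Returns NaN (with the pair bookkeeping intact) when
    no pair passes the overlap rule.  Raises for n < 2.
    """
    bases = [r if isinstance(r, str) else r.bases for r in records]
    if len(bases) < 2:
        raise InsufficientSequencesError(
            f"need >= 2 sequences, got {len(bases)}"
        )
    lengths = {len(b) for b in bases}
    if len(lengths) > 1:
        raise AlignmentError(f"unequal aligned lengths: {sorted(lengths)}")
    codes = np.vstack([encode(b) for b in bases])
    return _pi_from_codes(codes)


def assemblage_gd(pis, unit_id=None, n_sequences: int = 0,
                  n_range_species: int | None = None) -> AssemblageGD:
    """Average defined per-species Pi values into one assemblage GD value."""
    vals = np.asarray([p for p in pis if np.isfinite(p)], dtype=float)
    if vals.size == 0:
        raise EmptyAssemblageError(f"no defined Pi in unit {unit_id!r}")
    coverage = float("nan")
    if n_range_species is not None and n_range_species > 0:
        coverage = vals.size / n_range_species
    return AssemblageGD(
        unit_id=unit_id,
        gd=float(vals.mean()),
        n_species_with_pi=int(vals.size),
        n_sequences=int(n_sequences),
        taxonomic_coverage=coverage,
    )


def assign_to_grid(lon, lat, grid: GridSpec | None = None):
    """Map lon/lat to half-open grid cell ids ``(col, row)``."""
    return (grid or GridSpec()).cell_of(lon, lat)


def _range_species_per_unit(range_polys, unit_geoms, unit_ids):
    """Species whose usable range intersects each unit polygon (projected)."""
    out = {uid: set() for uid in unit_ids}
    if not range_polys:
        return out
    geoms = [p.projected() for p in range_polys]
    tree = STRtree(geoms)
    for uid, ug in zip(unit_ids, unit_geoms):
        for idx in tree.query(ug, predicate="intersects"):
            out[uid].add(range_polys[int(idx)].species_id)
    return out


def _assign_units(records, units):
    """Yield (unit_id, record) pairs under the grid or region-polygon scheme."""
    if isinstance(units, GridSpec):
        for r in records:
            yield units.cell_of(r.lon, r.lat), r
    else:
        # units: mapping region_id -> lon/lat shapely Polygon; first match in
        # sorted id order wins on shared boundaries.
        items = sorted(units.items())
        for r in records:
            pt = Point(r.lon, r.lat)
            for rid, poly in items:
                if poly.covers(pt):
                    yield rid, r
                    break


def gd_surface(records, units, range_polys=None) -> pd.DataFrame:
    """Assemblage GD for every spatial unit holding computable data.

    ``units`` is either a :class:`GridSpec` (grid-cell grain) or a mapping of
    region id to lon/lat shapely polygon (region grain).  ``range_polys``
    (usable :class:`~macrogen.filters.RangePolygon`) supply the range-derived
    species list used for taxonomic coverage; without them coverage is NaN.

    Returns a DataFrame with columns unit_id, gd, n_species, n_sequences,
    coverage.  Units without any species holding >= 2 sequences are omitted.
    """
    grouped: dict[object, dict[str, list]] = {}
    for uid, r in _assign_units(records, units):
        grouped.setdefault(uid, {}).setdefault(r.species_id, []).append(r)

    range_sets = None
    if range_polys:
        if isinstance(units, GridSpec):
            ids = list(grouped)
            geoms = [units.cell_polygon(*uid) for uid in ids]
        else:
            ids = list(grouped)
            from .projection import project_ring
            from shapely.geometry import Polygon as _P
            geoms = [
                _P(project_ring(list(units[uid].exterior.coords)))
                for uid in ids
            ]
        range_sets = _range_species_per_unit(range_polys, geoms, ids)

    rows = []
    for uid, by_sp in grouped.items():
        pis = []
        n_seq = 0
        for sp, recs in by_sp.items():
            n_seq += len(recs)
            if len(recs) < 2:
                continue
            pis.append(species_pi(recs))
        defined = [p for p in pis if np.isfinite(p)]
        if not defined:
            continue
        n_range = len(range_sets[uid]) if range_sets is not None else None
        agd = assemblage_gd(defined, unit_id=uid, n_sequences=n_seq,
                            n_range_species=n_range)
        rows.append(
            (uid, agd.gd, agd.n_species_with_pi, agd.n_sequences,
             agd.taxonomic_coverage)
        )
    return pd.DataFrame(
        rows, columns=["unit_id", "gd", "n_species", "n_sequences", "coverage"]
    )
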