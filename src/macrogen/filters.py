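"""Sequence-quality and spatial filters applied before any diversity maths.

Three rules, in order:

1. drop sequences containing IUPAC ambiguity letters (R, Y, S, W, K, M, B,
   D, H, V, U); gaps ``-`` and unknown ``N`` survive this stage because the
   pairwise comparison itself skips those positions;
2. drop range polygons coded "possibly extant" (presence 3), "presence
   uncertain" (presence 6), "introduced" (origin 3) or "vagrant" (origin 4);
3. drop sequences lying further than one grid-cell edge (385.9451 km) from
   the usable range polygons of their species, measured on the Behrmann
   plane; species with no usable range are dropped and logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from shapely.geometry import Point, Polygon

from .projection import RANGE_FILTER_MAX_DIST, project_ring

#: IUPAC ambiguity letters whose presence disqualifies a sequence.
AMBIGUITY_CODES = frozenset("RYSWKMBDHVU")

#: Characters an aligned sequence may contain after ambiguity removal.
CLEAN_ALPHABET = frozenset("ACGT-N")

_IUPAC = AMBIGUITY_CODES | CLEAN_ALPHABET


class MalformedSequenceError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


class NoRangeError(ValueError):
    """A species has no usable range polygon."""


@dataclass(frozen=True)
class GeoSequence:
    """One aligned mtDNA sequence with species identity and sampling point."""

    sequence_id: str
    species_id: str
    bases: str
    lon: float
    lat: float

    def __post_init__(self):
        if not -180.0 <= self.lon <= 180.0 or not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"invalid coordinates for {self.sequence_id}")


@dataclass
class RangePolygon:
    """A species range polygon with IUCN-style presence/origin codes.

    ``rings`` holds the exterior ring (and optional holes) as lists of
    (lon, lat) vertex pairs.  The shapely geometry on the projected plane is
    built lazily and cached.
    """

    species_id: str
    rings: list
    presence: int = 1
    origin: int = 1
    _projected: Polygon | None = field(default=None, repr=False, compare=False)

    def projected(self) -> Polygon:
        if self._projected is None:
            shell = project_ring(self.rings[0])
            holes = [project_ring(r) for r in self.rings[1:]]
            self._projected = Polygon(shell, holes)
        return self._projected


def has_ambiguity(bases: str) -> bool:
    up = bases.upper()
    bad = set(up) - _IUPAC
    if bad:
        raise MalformedSequenceError(
            f"characters outside the IUPAC alphabet: {sorted(bad)}"
        )
    return any(c in AMBIGUITY_CODES for c in up)


def remove_ambiguous(records):
    """Return only sequences free of IUPAC ambiguity letters, unchanged."""
    return [r for r in records if not has_ambiguity(r.bases)]


def usable_polygons(polys):
    """Keep polygons with presence not in {3, 6} and origin not in {3, 4}."""
    return [
        p for p in polys if p.presence not in (3, 6) and p.origin not in (3, 4)
    ]


def point_to_range_distance(lon, lat, polys) -> float:
    """Minimum planar distance (m) from a point to a species' range polygons.

    Returns 0.0 when the point lies inside or on the boundary of any
    polygon.  All polygons must belong to the same species.
    """
    if not polys:
        raise NoRangeError("no range polygons supplied")
    species = {p.species_id for p in polys}
    if len(species) > 1:
        raise ValueError(f"polygons from multiple species: {sorted(species)}")
    from .projection import behrmann_forward

    x, y = behrmann_forward(lon, lat)
    pt = Point(float(x), float(y))
    dist = float("inf")
    for p in polys:
        geom = p.projected()
        if geom.covers(pt):
            return 0.0
        dist = min(dist, pt.distance(geom))
    return dist


def apply_synonyms(records, synonyms: dict):
    """Map sequence taxa onto accepted species names.

    ``synonyms`` maps old_name -> accepted_name; species absent from the
    table keep their name.  Taxa that collapse onto one accepted species are
    thereby merged for all downstream steps.
    """
    if not synonyms:
        return list(records)
    out = []
    for r in records:
        acc = synonyms.get(r.species_id, r.species_id)
        if acc == r.species_id:
            out.append(r)
        else:
            out.append(
                GeoSequence(r.sequence_id, acc, r.bases, r.lon, r.lat)
            )
    return out


def filter_by_range(records, polys, max_dist: float = RANGE_FILTER_MAX_DIST):
    """Keep sequences within ``max_dist`` metres of their species' usable range.

    ``polys`` may contain unusable polygons; they are excluded here.
    Returns ``(kept, log)`` where ``log`` is a DataFrame of rejected
    sequences with reasons ``no_range`` or ``too_far``.
    """
    by_species: dict[str, list] = {}
    for p in usable_polygons(polys):
        by_species.setdefault(p.species_id, []).append(p)
    kept, log = [], []
    for r in records:
        sp_polys = by_species.get(r.species_id)
        if not sp_polys:
            log.append((r.sequence_id, "no_range"))
            continue
        d = point_to_range_distance(r.lon, r.lat, sp_polys)
        if d > max_dist:
            log.append((r.sequence_id, "too_far"))
        else:
            kept.append(r)
    return kept, pd.DataFrame(log, columns=["sequence_id", "reason"])


def apply_filters(records, polys, max_dist: float = RANGE_FILTER_MAX_DIST,
                  synonyms: dict | None = None):
    """Run the full filter chain; returns ``(kept, rejection_log)``.

    The log records one row per rejected sequence with reason in
    ``{ambiguity, no_range, too_far}``.
    """
    records = apply_synonyms(records, synonyms or {})
    clean, amb_log = [], []
    for r in records:
        if has_ambiguity(r.bases):
            amb_log.append((r.sequence_id, "ambiguity"))
        else:
            clean.append(r)
    kept, range_log = filter_by_range(clean, polys, max_dist=max_dist)
    log = pd.concat(
        [pd.DataFrame(amb_log, columns=["sequence_id", "reason"]), range_log],
        ignore_index=True,
    )
    return kept, log
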