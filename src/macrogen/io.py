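"""Readers and writers for the pipeline's on-disk formats.

Sequence data travel as per-species aligned FASTA plus one coordinates CSV
(sequence_id, species_id, lon, lat); ranges as a GeoJSON FeatureCollection
with species_id/presence/origin properties; trees as (multi-)Newick;
climate, ALCC and footprint tables as long-format CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .filters import GeoSequence, RangePolygon


def write_sequences(records, out_dir: Path) -> None:
    """Per-species aligned FASTA under ``sequences/`` plus coordinates.csv."""
    out_dir = Path(out_dir)
    seq_dir = out_dir / "sequences"
    seq_dir.mkdir(parents=True, exist_ok=True)
    by_species: dict[str, list] = {}
    for r in records:
        by_species.setdefault(r.species_id, []).append(r)
    for sp, recs in sorted(by_species.items()):
        SeqIO.write(
            [SeqRecord(Seq(r.bases), id=r.sequence_id, description="")
             for r in recs],
            seq_dir / f"{sp}.fasta", "fasta",
        )
    pd.DataFrame(
        [(r.sequence_id, r.species_id, r.lon, r.lat) for r in records],
        columns=["sequence_id", "species_id", "lon", "lat"],
    ).to_csv(out_dir / "coordinates.csv", index=False)


def read_sequences(out_dir: Path) -> list:
    out_dir = Path(out_dir)
    coords = pd.read_csv(out_dir / "coordinates.csv").set_index("sequence_id")
    records = []
    for fasta in sorted((out_dir / "sequences").glob("*.fasta")):
        for rec in SeqIO.parse(fasta, "fasta"):
            row = coords.loc[rec.id]
            records.append(
                GeoSequence(rec.id, str(row["species_id"]), str(rec.seq),
                            float(row["lon"]), float(row["lat"]))
            )
    return records


def write_ranges(polys, path: Path) -> None:
    features = []
    for p in polys:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[float(x), float(y)] for x, y in ring]
                        for ring in p.rings
                    ],
                },
                "properties": {
                    "species_id": p.species_id,
                    "presence": p.presence,
                    "origin": p.origin,
                },
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_ranges(path: Path) -> list:
    data = json.loads(Path(path).read_text())
    polys = []
    for feat in data["features"]:
        props = feat["properties"]
        rings = [
            [(float(x), float(y)) for x, y in ring]
            for ring in feat["geometry"]["coordinates"]
        ]
        polys.append(
            RangePolygon(species_id=props["species_id"], rings=rings,
                         presence=int(props["presence"]),
                         origin=int(props["origin"]))
        )
    return polys


def write_trees(trees, path: Path) -> None:
    # one newick per line; trees may carry distinct taxon namespaces
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick"))


def read_trees(path: Path) -> list:
    return list(dendropy.TreeList.get(path=str(path), schema="newick"))


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str))
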