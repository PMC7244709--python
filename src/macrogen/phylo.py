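"""Species richness and Faith's phylogenetic diversity per spatial unit.

Species richness (SR) counts the species whose (usable) ranges intersect a
unit *and* that appear as tips in the dated phylogeny, so that SR and PD are
computed over the same species pool.  Faith's PD is the total branch length
of the minimal subtree connecting the selected tips.  By default the subtree
is rooted at the tips' most recent common ancestor — branches between the
MRCA and the tree root are not counted, and a single-tip set returns that
tip's terminal branch length.  Set ``include_root=True`` for the
root-inclusive convention used by some other implementations.

Branch lengths are in millions of years; PD per unit is averaged over a
posterior sample of trees when several are supplied.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd
from shapely.strtree import STRtree


class EmptyTipSetError(ValueError):
    """None of the requested species occur in the tree."""


def _tip_nodes(tree: dendropy.Tree, species) -> list:
    wanted = set(species)
    return [lf for lf in tree.leaf_node_iter() if lf.taxon.label in wanted]


def _mrca(tips) -> object:
    """Most recent common ancestor of a set of leaf nodes.

    Walks parent pointers only, so the tree is never rerooted or otherwise
    mutated (the seed node acts as the root).
    """
    paths = []
    for t in tips:
        path = []
        node = t
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths.append(path)
    candidate_ids = set(id(n) for n in paths[0])
    for path in paths[1:]:
        candidate_ids &= {id(n) for n in path}
    for node in paths[0]:  # leaf -> root order: first shared node is the MRCA
        if id(node) in candidate_ids:
            return node
    raise RuntimeError("tips do not share an ancestor")


def faith_pd(tree: dendropy.Tree, species, include_root: bool = False) -> float:
    """Faith's phylogenetic diversity of a species set on one dated tree.

    Sums the edge lengths on the union of paths from each matched tip up to
    the MRCA of the matched tips (plus MRCA-to-root edges when
    ``include_root``).  Polytomies are handled naturally by the path union.
    """
    tips = _tip_nodes(tree, species)
    if not tips:
        raise EmptyTipSetError("no requested species found among tree tips")
    if len(tips) == 1:
        node = tips[0]
        # Root-inclusive: count the whole tip-to-root path below; otherwise
        # the convention is the tip's terminal branch alone.
        pd_val = 0.0 if include_root else (node.edge.length or 0.0)
    else:
        mrca = _mrca(tips)
        visited = set()
        pd_val = 0.0
        for t in tips:
            node = t
            while node is not mrca and id(node) not in visited:
                visited.add(id(node))
                pd_val += node.edge.length or 0.0
                node = node.parent_node
        node = mrca
    if include_root:
        while node.parent_node is not None:
            pd_val += node.edge.length or 0.0
            node = node.parent_node
    return pd_val


def mean_pd(trees, species, include_root: bool = False) -> float:
    """Arithmetic mean of :func:`faith_pd` over a posterior sample of trees."""
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree list")
    return float(
        np.mean([faith_pd(t, species, include_root=include_root)
                 for t in trees])
    )


def species_in_unit(polys, unit_geom) -> set:
    """Species whose range polygons intersect a unit polygon.

    Both the ranges and the unit must be on the projected plane; a boundary
    touch counts as intersection.
    """
    out = set()
    for p in polys:
        if p.projected().intersects(unit_geom):
            out.add(p.species_id)
    return out


def unit_diversity(polys, units: dict, trees,
                   include_root: bool = False) -> pd.DataFrame:
    """SR and posterior-mean PD for every unit.

    ``units`` maps unit_id -> projected shapely polygon.  Returns a DataFrame
    with columns unit_id, sr, pd (NaN where no range species matches the
    tree) and species (frozenset of range species in the unit).
    """
    trees = list(trees)
    if not trees:
        raise ValueError("empty tree list")
    tip_labels = {lf.taxon.label for lf in trees[0].leaf_node_iter()}

    ids = list(units)
    geoms = [units[u] for u in ids]
    range_sets = {u: set() for u in ids}
    if polys:
        tree_index = STRtree([p.projected() for p in polys])
        for u, g in zip(ids, geoms):
            for idx in tree_index.query(g, predicate="intersects"):
                range_sets[u].add(polys[int(idx)].species_id)

    rows = []
    for u in ids:
        in_tree = range_sets[u] & tip_labels
        if in_tree:
            pd_val = mean_pd(trees, in_tree, include_root=include_root)
        else:
            pd_val = float("nan")
        rows.append((u, len(in_tree), pd_val, frozenset(range_sets[u])))
    return pd.DataFrame(rows, columns=["unit_id", "sr", "pd", "species"])
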