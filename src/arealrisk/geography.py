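"""Area adjacency: queen contiguity, isolate repair, GAL and GeoJSON I/O.

The conditional-autoregressive prior used by the smoothing models needs a
symmetric 0/1 neighbourhood structure over the study areas in which every
area has at least one neighbour.  This module builds that structure from
planar polygons under first-order "queen" contiguity (areas are neighbours
if their boundaries share any point, edge or corner), repairs isolated
areas — typically islands — by manual grouping or nearest-centroid linking,
and round-trips the structure through the plain-text GAL weights format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

__all__ = [
    "AreaGraph",
    "build_queen_adjacency",
    "repair_isolates",
    "read_gal",
    "write_gal",
    "read_geojson_polygons",
    "write_geojson_polygons",
    "centroids_frame",
]


@dataclass(frozen=True)
class AreaGraph:
    """Symmetric adjacency over labelled areas.

    ``neighbours[i]`` is the frozenset of indices adjacent to area ``i``
    (omega_ij = 1).  Centroids are planar (x, y) in arbitrary units and may be
    absent when the graph was read from a pure weights file.
    """

    area_ids: tuple[str, ...]
    neighbours: tuple[frozenset[int], ...]
    centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        if n == 0:
            raise ValueError("AreaGraph needs at least one area")
        if len(set(self.area_ids)) != n:
            raise ValueError("duplicate area labels")
        if len(self.neighbours) != n:
            raise ValueError("neighbours length does not match area_ids")
        for i, nb in enumerate(self.neighbours):
            if i in nb:
                raise ValueError(f"self-loop at area {self.area_ids[i]}")
            for j in nb:
                if not (0 <= j < n):
                    raise ValueError("neighbour index out of range")
                if i not in self.neighbours[j]:
                    raise ValueError(
                        f"asymmetric adjacency: {self.area_ids[i]} lists "
                        f"{self.area_ids[j]} but not vice versa"
                    )
        if self.centroids is not None:
            c = np.asarray(self.centroids, dtype=float)
            if c.shape != (n, 2):
                raise ValueError("centroids must have shape (n_areas, 2)")
            object.__setattr__(self, "centroids", c)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbours])

    def isolates(self) -> list[int]:
        return [i for i, nb in enumerate(self.neighbours) if not nb]

    def index(self, area_id: str) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise KeyError(f"unknown area id {area_id!r}") from None

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (m, 2) array with i < j."""
        out = [(i, j) for i, nb in enumerate(self.neighbours) for j in nb if i < j]
        return np.array(out, dtype=int).reshape(-1, 2)

    def n_components(self) -> int:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(map(tuple, self.edges()))
        return nx.number_connected_components(g)

    def adjacency_matrix(self):
        """Sparse CSR omega with omega_ij = 1 iff i, j adjacent."""
        from scipy import sparse

        e = self.edges()
        n = self.n_areas
        if len(e) == 0:
            return sparse.csr_matrix((n, n))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )

    def colour_classes(self) -> list[np.ndarray]:
        """Greedy proper colouring: index sets with no internal edges.

        Areas in one class are conditionally independent under the CAR prior,
        so single-site MCMC updates may be applied to a whole class at once.
        """
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(map(tuple, self.edges()))
        colouring = nx.greedy_color(g, strategy="largest_first")
        n_colours = max(colouring.values()) + 1 if colouring else 1
        classes = [[] for _ in range(n_colours)]
        for node, c in colouring.items():
            classes[c].append(node)
        return [np.array(sorted(c), dtype=int) for c in classes if c]


def _as_polygon_items(
    polygons: Mapping[str, BaseGeometry] | Iterable[tuple[str, BaseGeometry]],
) -> list[tuple[str, BaseGeometry]]:
    if isinstance(polygons, Mapping):
        items = list(polygons.items())
    else:
        items = list(polygons)
    if not items:
        raise ValueError("empty polygon input")
    labels = [lab for lab, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate polygon labels")
    return items


def build_queen_adjacency(
    polygons: Mapping[str, BaseGeometry] | Iterable[tuple[str, BaseGeometry]],
) -> AreaGraph:
    """First-order queen contiguity: neighbours share at least one boundary
    point (edge or corner).  Isolated polygons are retained with empty
    neighbour sets.
    """
    items = _as_polygon_items(polygons)
    labels = [lab for lab, _ in items]
    geoms = [geom for _, geom in items]
    n = len(items)
    nb: list[set[int]] = [set() for _ in range(n)]
    tree = STRtree(geoms)
    for i, geom in enumerate(geoms):
        for j in tree.query(geom, predicate="intersects"):
            j = int(j)
            if j != i:
                nb[i].add(j)
                nb[j].add(i)
    centroids = np.array([[g.centroid.x, g.centroid.y] for g in geoms])
    return AreaGraph(tuple(labels), tuple(frozenset(s) for s in nb), centroids)


def repair_isolates(
    graph: AreaGraph,
    manual_links: Sequence[tuple[str, str]] | None = None,
) -> tuple[AreaGraph, list[tuple[str, str]]]:
    """Ensure every area has at least one neighbour.

    ``manual_links`` (pairs of area ids) are applied first, in both
    directions; any remaining isolate is then linked to the area with the
    nearest centroid (ties broken by area-id order).  Existing links are never
    removed.  Returns the repaired graph and the log of links added.
    """
    nb = [set(s) for s in graph.neighbours]
    added: list[tuple[str, str]] = []
    for a, b in manual_links or []:
        i, j = graph.index(a), graph.index(b)
        if i == j:
            raise ValueError(f"manual link from {a!r} to itself")
        if j not in nb[i]:
            nb[i].add(j)
            nb[j].add(i)
            added.append((a, b))
    remaining = [i for i in range(graph.n_areas) if not nb[i]]
    if remaining:
        if graph.centroids is None:
            raise ValueError("cannot repair isolates without centroids")
        if graph.n_areas < 2:
            raise ValueError("cannot repair isolates in a single-area graph")
        c = graph.centroids
        for i in remaining:
            if nb[i]:
                continue  # resolved by an earlier isolate linking to it
            d = np.hypot(c[:, 0] - c[i, 0], c[:, 1] - c[i, 1])
            d[i] = np.inf
            # argmin returns the first minimiser, i.e. earliest area_id order
            j = int(np.argmin(d))
            nb[i].add(j)
            nb[j].add(i)
            added.append((graph.area_ids[i], graph.area_ids[j]))
    repaired = AreaGraph(
        graph.area_ids, tuple(frozenset(s) for s in nb), graph.centroids
    )
    return repaired, added


def write_gal(graph: AreaGraph) -> str:
    """Serialize the neighbour structure in the GAL weights dialect:
    a header with the area count, then per area a line ``id n`` followed by a
    line of the n neighbour ids.
    """
    lines = [str(graph.n_areas)]
    for i, aid in enumerate(graph.area_ids):
        nb = sorted(graph.neighbours[i])
        lines.append(f"{aid} {len(nb)}")
        lines.append(" ".join(graph.area_ids[j] for j in nb))
    return "\n".join(lines) + "\n"


def read_gal(text: str) -> AreaGraph:
    """Parse a GAL weights file; rejects unknown ids and asymmetric listings.

    The returned graph carries no centroids.
    """
    tokens_by_line = [ln.split() for ln in text.splitlines() if ln.strip()]
    if not tokens_by_line:
        raise ValueError("empty GAL input")
    header = tokens_by_line[0]
    try:
        n = int(header[0])
    except (ValueError, IndexError):
        raise ValueError("GAL header must start with the area count") from None
    area_ids: list[str] = []
    raw: dict[str, list[str]] = {}
    pos = 1
    for _ in range(n):
        if pos >= len(tokens_by_line):
            raise ValueError("truncated GAL file")
        head = tokens_by_line[pos]
        if len(head) != 2:
            raise ValueError(f"malformed GAL record header: {' '.join(head)!r}")
        aid, k_str = head
        k = int(k_str)
        if aid in raw:
            raise ValueError(f"duplicate area id {aid!r}")
        if k == 0:
            nbs: list[str] = []
            pos += 1
        else:
            if pos + 1 >= len(tokens_by_line):
                raise ValueError("truncated GAL file")
            nbs = tokens_by_line[pos + 1]
            if len(nbs) != k:
                raise ValueError(
                    f"area {aid!r} declares {k} neighbours but lists {len(nbs)}"
                )
            pos += 2
        area_ids.append(aid)
        raw[aid] = nbs
    index = {aid: i for i, aid in enumerate(area_ids)}
    nb: list[frozenset[int]] = []
    for aid in area_ids:
        ids = raw[aid]
        unknown = [x for x in ids if x not in index]
        if unknown:
            raise ValueError(f"neighbour id(s) {unknown} not in header set")
        nb.append(frozenset(index[x] for x in ids))
    for i, s in enumerate(nb):
        for j in s:
            if i not in nb[j]:
                raise ValueError(
                    f"asymmetric GAL file: {area_ids[i]} lists {area_ids[j]} "
                    "but not vice versa"
                )
    return AreaGraph(tuple(area_ids), tuple(nb), None)


def read_geojson_polygons(text: str) -> list[tuple[str, BaseGeometry]]:
    """Read a GeoJSON FeatureCollection of (multi)polygons keyed by the
    ``area_id`` property."""
    obj = json.loads(text)
    if obj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = []
    for feat in obj.get("features", []):
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise ValueError("feature missing 'area_id' property")
        geom = shapely_shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"unsupported geometry type {geom.geom_type}")
        out.append((str(props["area_id"]), geom))
    if not out:
        raise ValueError("no features in GeoJSON input")
    return out


def write_geojson_polygons(
    polygons: Iterable[tuple[str, BaseGeometry]],
    properties: Mapping[str, Mapping[str, object]] | None = None,
) -> str:
    """Write polygons (optionally with extra per-area properties) as a
    GeoJSON FeatureCollection."""
    feats = []
    for aid, geom in polygons:
        props: dict[str, object] = {"area_id": aid}
        if properties is not None and aid in properties:
            props.update(properties[aid])
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": shapely_mapping(geom),
            }
        )
    return json.dumps({"type": "FeatureCollection", "features": feats})


def centroids_frame(graph: AreaGraph):
    """Centroid table (area_id, x, y) for CSV export."""
    import pandas as pd

    if graph.centroids is None:
        raise ValueError("graph has no centroids")
    return pd.DataFrame(
        {
            "area_id": list(graph.area_ids),
            "x": graph.centroids[:, 0],
            "y": graph.centroids[:, 1],
        }
    )
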