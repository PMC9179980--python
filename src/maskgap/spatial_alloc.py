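"""Change-of-support: store points -> Voronoi service areas -> villages.

Each store's daily customer count is first attached to its Voronoi cell
(the set of locations nearer to that store than to any other), clipped to
the study region. Counts are then reallocated onto village polygons by
area-weighted areal interpolation under the homogeneous-density assumption:
a village receives from each cell the cell's count times the fraction of
the cell's area that the village overlaps. When the villages tile the
region this conserves the total count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

# overlay slivers below this area (m^2) are treated as empty
SLIVER_AREA = 1e-9


@dataclass
class VoronoiSurface:
    """One clipped Voronoi cell per (deduplicated) store, with its count."""

    cells: list  # shapely polygons
    counts: np.ndarray  # avg daily customers per cell
    points: np.ndarray  # generating store locations, shape (k, 2)


def build_voronoi(stores: pd.DataFrame, region: Polygon) -> VoronoiSurface:
    """Voronoi service areas for stores inside `region`.

    ``stores`` needs columns (x, y, avg_daily_customers). Stores at exactly
    duplicated locations are collapsed with their counts summed before
    tessellation. A single store yields the whole region as its cell.
    """
    if len(stores) == 0:
        raise ValueError("no stores to tessellate")
    pts = stores[["x", "y"]].to_numpy(dtype=float)
    for p in pts:
        if not region.covers(Point(p)):
            raise ValueError(f"store at {tuple(p)} lies outside the study region")

    counts = stores["avg_daily_customers"].to_numpy(dtype=float)
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    merged = np.zeros(len(uniq))
    np.add.at(merged, inverse, counts)

    if len(uniq) == 1:
        return VoronoiSurface(cells=[region], counts=merged, points=uniq)

    diagram = voronoi_diagram(
        MultiPoint([Point(p) for p in uniq]), envelope=region.buffer(region.length)
    )
    raw = list(diagram.geoms)
    tree = STRtree(raw)
    cells = []
    for p in uniq:
        pt = Point(p)
        idx = list(tree.query(pt, predicate="intersects")) or [tree.nearest(pt)]
        best = min(idx, key=lambda i: raw[i].centroid.distance(pt))
        cells.append(raw[best].intersection(region))
    return VoronoiSurface(cells=cells, counts=merged, points=uniq)


def areal_interpolate(surface: VoronoiSurface, villages: pd.DataFrame) -> pd.DataFrame:
    """Area-weighted reallocation of cell counts onto village polygons.

    Adds to ``villages`` the columns ``Y_frac`` (the fractional interpolated
    count) and ``Y`` (rounded to the nearest integer, half to even, for the
    count likelihoods downstream). A degenerate zero-area cell donates its
    whole count to the village containing its generator point.
    """
    villages = villages.reset_index(drop=True).copy()
    polys = list(villages["geometry"])
    tree = STRtree(polys)
    y = np.zeros(len(villages))
    for cell, count, pt in zip(surface.cells, surface.counts, surface.points):
        if count == 0:
            continue
        if cell.area <= SLIVER_AREA:
            hits = tree.query(Point(pt), predicate="intersects")
            if len(hits):
                y[min(hits)] += count
            continue
        for j in tree.query(cell, predicate="intersects"):
            inter = cell.intersection(polys[j]).area
            if inter > SLIVER_AREA:
                y[j] += count * inter / cell.area
    villages["Y_frac"] = y
    villages["Y"] = np.round(y).astype(np.int64)
    return villages


def count_stores_in_village(stores: pd.DataFrame, villages: pd.DataFrame) -> np.ndarray:
    """Number of store points inside each village polygon.

    A store on a shared boundary is assigned to the single village whose
    ``village_id`` sorts first, so the total over a tiling equals the number
    of in-region stores.
    """
    polys = list(villages["geometry"])
    ids = villages["village_id"].to_numpy()
    tree = STRtree(polys)
    counts = np.zeros(len(villages), dtype=np.int64)
    for _, st in stores.iterrows():
        pt = Point(st["x"], st["y"])
        hits = tree.query(pt, predicate="intersects")
        if len(hits) == 0:
            continue
        winner = min(hits, key=lambda j: str(ids[j]))
        counts[winner] += 1
    return counts
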