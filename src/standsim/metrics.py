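"""Landscape output indicators: age-class composition, patch size
distributions, edge proportions of old-forest patches, and incidence-function
(Hanski) connectivity aggregated on a 10×10 km grid.

Patches are connected components of the stand adjacency graph restricted to
an age predicate.  For distance calculations every patch is approximated as a
circle around its area-weighted centroid with radius √(S/π); the
incidence-function term for a neighboring patch at edge-to-edge distance *d*
(km) with area *S* (m²) is exp(−a·d)·S^b with a = b = 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, box as _box
from shapely.ops import unary_union

from .core import (
    Intensity,
    LandscapeState,
    OwnerType,
    RestrictionZone,
    Stand,
    stand_age,
)


@dataclass(frozen=True)
class ConnectivityParams:
    a: float = 0.5                 # distance decay, per km
    b: float = 0.5                 # area exponent
    search_radius: float = 10_000.0   # m, edge-to-edge neighborhood
    grid_cell: float = 10_000.0       # m

    def __post_init__(self):
        if self.a <= 0 or self.b < 0 or self.search_radius <= 0:
            raise ValueError("need a > 0, b >= 0, search_radius > 0")


@dataclass(frozen=True)
class Patch:
    """A connected group of same-age-class stands."""

    id: int
    stand_ids: frozenset[int]
    area: float                    # m², sum of member areas
    centroid: tuple[float, float]  # area-weighted member centroid

    @property
    def radius(self) -> float:
        """Equivalent circular radius √(S/π), meters."""
        return math.sqrt(self.area / math.pi)


# ---------------------------------------------------------------------------
# Age-class composition
# ---------------------------------------------------------------------------

def _stratum(stand: Stand, state: LandscapeState, stratifier: str) -> str:
    if stratifier == "zone":
        if stand.restriction_zone is RestrictionZone.STRICT:
            return "strict"
        if stand.restriction_zone is RestrictionZone.UNRESTRICTED:
            return "production"
        return "restricted"
    unit = state.units[stand.unit_id]
    if stratifier == "ownership":
        return unit.owner_type.value
    if stratifier == "management":
        if unit.owner_type is OwnerType.STATE:
            return "state"
        return "intensive" if unit.intensity is Intensity.INT else "non-intensive"
    raise ValueError(f"unknown stratifier {stratifier!r}")


def age_class_composition(state: LandscapeState,
                          class_edges: Sequence[float],
                          stratifier: str | None = None) -> pd.DataFrame:
    """Area share per age class (rows = strata, columns = classes).

    ``class_edges`` [20, 80] gives classes [0, 20), [20, 80), [80, ∞);
    shares sum to 1 within every stratum.
    """
    edges = list(class_edges)
    labels = ([f"[0,{edges[0]})"]
              + [f"[{a},{b})" for a, b in zip(edges, edges[1:])]
              + [f">={edges[-1]}"])
    areas: dict[str, np.ndarray] = {}
    for st in state.stands.values():
        stratum = ("all" if stratifier is None
                   else _stratum(st, state, stratifier))
        row = areas.setdefault(stratum, np.zeros(len(labels)))
        row[int(np.digitize(stand_age(st), edges))] += st.area
    out = pd.DataFrame.from_dict(areas, orient="index", columns=labels)
    return out.div(out.sum(axis=1), axis=0).sort_index()


# ---------------------------------------------------------------------------
# Patches
# ---------------------------------------------------------------------------

def age_below(threshold: float) -> Callable[[Stand], bool]:
    return lambda st: stand_age(st) < threshold


def age_at_least(threshold: float) -> Callable[[Stand], bool]:
    return lambda st: stand_age(st) >= threshold


def build_patches(state: LandscapeState,
                  predicate: Callable[[Stand], bool]) -> list[Patch]:
    """Group neighboring predicate-satisfying stands into patches (connected
    components of the adjacency graph restricted to those stands)."""
    member_ids = [sid for sid in sorted(state.stands)
                  if predicate(state.stands[sid])]
    g = nx.Graph()
    g.add_nodes_from(member_ids)
    member_set = set(member_ids)
    for sid in member_ids:
        for nid in state.stands[sid].neighbor_ids:
            if nid in member_set:
                g.add_edge(sid, nid)
    patches = []
    for pid, comp in enumerate(sorted(nx.connected_components(g),
                                      key=lambda c: min(c))):
        area = sum(state.stands[sid].area for sid in comp)
        cx = sum(state.stands[sid].area * state.stands[sid].centroid[0]
                 for sid in comp) / area
        cy = sum(state.stands[sid].area * state.stands[sid].centroid[1]
                 for sid in comp) / area
        patches.append(Patch(pid, frozenset(comp), area, (cx, cy)))
    return patches


def patch_size_distribution(patches: Iterable[Patch],
                            bins: Sequence[float] = (10_000.0, 100_000.0)
                            ) -> pd.DataFrame:
    """Total patch area per size bin; bin totals sum to the total patch area."""
    edges = list(bins)
    labels = ([f"<{edges[0]:g}"]
              + [f"[{a:g},{b:g})" for a, b in zip(edges, edges[1:])]
              + [f">={edges[-1]:g}"])
    totals = np.zeros(len(labels))
    counts = np.zeros(len(labels), dtype=int)
    for p in patches:
        k = int(np.digitize(p.area, edges))
        totals[k] += p.area
        counts[k] += 1
    return pd.DataFrame({"size_bin": labels, "total_area_m2": totals,
                         "n_patches": counts})


# ---------------------------------------------------------------------------
# Edge areas
# ---------------------------------------------------------------------------

class GeometryUnavailable(RuntimeError):
    """Raised when a metric needs polygon geometry the landscape lacks."""


def edge_area(state: LandscapeState, patches: Sequence[Patch],
              edge_distance: float = 30.0,
              young_age: float = 20.0) -> pd.DataFrame:
    """Per-patch edge area: the part of the patch within ``edge_distance`` of
    clear-cuts or early-successional stands (age ≤ ``young_age``).

    Requires polygon geometry; adjacency-only landscapes raise
    :class:`GeometryUnavailable`.
    """
    if any(state.stands[sid].geometry is None
           for p in patches for sid in p.stand_ids):
        raise GeometryUnavailable(
            "edge areas need polygon geometry; this landscape is adjacency-only")
    young_geoms = [st.geometry for st in state.stands.values()
                   if stand_age(st) <= young_age]
    if young_geoms and any(g is None for g in young_geoms):
        raise GeometryUnavailable(
            "edge areas need polygon geometry; this landscape is adjacency-only")
    young_buffer = (unary_union(young_geoms).buffer(edge_distance)
                    if young_geoms else None)
    rows = []
    for p in patches:
        geom = unary_union([state.stands[sid].geometry for sid in p.stand_ids])
        edge = geom.intersection(young_buffer).area if young_buffer is not None else 0.0
        rows.append({"patch_id": p.id, "area_m2": p.area, "edge_m2": edge,
                     "edge_proportion": edge / p.area if p.area > 0 else 0.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def hanski_term(S: float, d: float, params: ConnectivityParams) -> float:
    """One incidence-function contribution: exp(−a·d)·S^b, with the
    neighboring patch area ``S`` in m² and distance ``d`` in km."""
    if S < 0 or d < 0:
        raise ValueError("area and distance must be non-negative")
    return math.exp(-params.a * d) * S ** params.b


def _edge_to_edge_km(p: Patch, q: Patch) -> float:
    center = math.dist(p.centroid, q.centroid)
    return max(0.0, center - p.radius - q.radius) / 1000.0


def patch_connectivity(focal: Patch, patches: Sequence[Patch],
                       params: ConnectivityParams | None = None) -> float:
    """Incidence-function connectivity of the focal patch: the sum of terms
    over all *other* patches within the search radius, circular edge-to-edge
    distances."""
    if params is None:
        params = ConnectivityParams()
    total = 0.0
    for q in patches:
        if q.id == focal.id:
            continue
        d = _edge_to_edge_km(focal, q)
        if d * 1000.0 <= params.search_radius:
            total += hanski_term(q.area, d, params)
    return total


def all_patch_connectivities(patches: Sequence[Patch],
                             params: ConnectivityParams | None = None
                             ) -> dict[int, float]:
    """Connectivity for every patch, using a KD-tree to restrict candidate
    neighbor pairs before the exact circular edge-to-edge filter."""
    if params is None:
        params = ConnectivityParams()
    if not patches:
        return {}
    centers = np.array([p.centroid for p in patches])
    radii = np.array([p.radius for p in patches])
    tree = cKDTree(centers)
    rmax = radii.max()
    out = {p.id: 0.0 for p in patches}
    for i, p in enumerate(patches):
        reach = params.search_radius + p.radius + rmax
        for j in tree.query_ball_point(centers[i], r=reach):
            if j == i:
                continue
            q = patches[j]
            d = _edge_to_edge_km(p, q)
            if d * 1000.0 <= params.search_radius:
                out[p.id] += hanski_term(q.area, d, params)
    return out


def grid_connectivity(patches: Sequence[Patch],
                      params: ConnectivityParams | None = None,
                      bounds: tuple[float, float, float, float] | None = None,
                      aggregate: str = "mean") -> pd.DataFrame:
    """Connectivity on a regular grid, each patch entering the cells it
    overlaps (circular footprint) with weight = its area inside the cell.

    ``aggregate='mean'`` gives the area-weighted mean of the patch indices
    per cell (default); ``'sum'`` gives the area-weighted sum.  Cells with no
    patch get 0.
    """
    if params is None:
        params = ConnectivityParams()
    if aggregate not in ("mean", "sum"):
        raise ValueError("aggregate must be 'mean' or 'sum'")
    indices = all_patch_connectivities(patches, params)
    if bounds is None:
        if not patches:
            return pd.DataFrame(columns=["cell_x", "cell_y", "connectivity",
                                         "patch_area_m2"])
        xs = [p.centroid[0] for p in patches]
        ys = [p.centroid[1] for p in patches]
        rmax = max(p.radius for p in patches)
        bounds = (min(xs) - rmax, min(ys) - rmax, max(xs) + rmax, max(ys) + rmax)
    x0, y0, x1, y1 = bounds
    cell = params.grid_cell
    nx_ = max(1, math.ceil((x1 - x0) / cell))
    ny_ = max(1, math.ceil((y1 - y0) / cell))
    wsum = np.zeros((ny_, nx_))
    wisum = np.zeros((ny_, nx_))
    for p in patches:
        circle = Point(p.centroid).buffer(p.radius, quad_segs=64)
        cx0, cy0, cx1, cy1 = circle.bounds
        i0 = max(0, int((cx0 - x0) // cell))
        i1 = min(nx_ - 1, int((cx1 - x0) // cell))
        j0 = max(0, int((cy0 - y0) // cell))
        j1 = min(ny_ - 1, int((cy1 - y0) // cell))
        for j in range(j0, j1 + 1):
            for i in range(i0, i1 + 1):
                cell_box = _box(x0 + i * cell, y0 + j * cell,
                                x0 + (i + 1) * cell, y0 + (j + 1) * cell)
                overlap = circle.intersection(cell_box).area
                if overlap <= 0:
                    continue
                # scale the circular overlap back to true patch area units
                w = p.area * overlap / circle.area
                wsum[j, i] += w
                wisum[j, i] += w * indices[p.id]
    rows = []
    for j in range(ny_):
        for i in range(nx_):
            if wsum[j, i] > 0:
                value = (wisum[j, i] / wsum[j, i] if aggregate == "mean"
                         else wisum[j, i])
            else:
                value = 0.0
            rows.append({"cell_x": i, "cell_y": j, "connectivity": value,
                         "patch_area_m2": wsum[j, i]})
    return pd.DataFrame(rows)
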