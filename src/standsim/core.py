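"""Domain types for the stand-level forest landscape simulator.

The atomic spatial unit is the forest *stand*: a relatively homogeneous forest
patch subject to a single management decision.  Stands are grouped into
*cadastral units* (estates) — the ownership parcels on which private harvest
willingness is decided.  A :class:`LandscapeState` holds the full mutable
world: stands, units, the calendar year and an append-only harvest event log.

All coordinates are planar metric (projected) coordinates; distances are in
meters and areas in square meters throughout.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from shapely import wkt as _wkt
from shapely.geometry import Polygon, mapping as _geo_mapping, shape as _geo_shape
from shapely.strtree import STRtree

SHARE_TOL = 1e-9


class RestrictionZone(str, Enum):
    """Legal protection category of a stand."""

    UNRESTRICTED = "unrestricted"
    STRICT = "strict"
    CLASS_A = "classA"
    CLASS_B = "classB"
    WATERBODY = "waterbody"


class SiteType(str, Enum):
    """Collapsed site-type catalogue: only the classes that drive rules."""

    ALVAR = "alvar"
    BOG = "bog"
    MINERAL = "mineral"
    OTHER = "other"


class ManagementType(str, Enum):
    NO_MANAGEMENT = "no_management"
    ALVAR = "alvar"
    LIMITED = "limited"
    RIPARIAN = "riparian"
    BOG = "bog"
    GENERAL = "general"


class OwnerType(str, Enum):
    STATE = "state"
    PHYSICAL = "physical"
    JURIDICAL = "juridical"


class Intensity(str, Enum):
    INT = "INT"
    NONINT = "nonINT"
    NOT_APPLICABLE = "not_applicable"


class RegenerationMode(str, Enum):
    PLANTED = "planted"
    NATURAL = "natural"


@dataclass(slots=True)
class SpeciesComponent:
    """One tree species entry of a stand layer.

    ``share`` is the fraction of the layer's growing stock held by the
    species (shares of a layer sum to 1); ``age`` is in years and stays
    integer-valued across annual steps; ``stock`` is standing volume in m³.
    """

    species: str
    share: float
    age: float
    stock: float | None = None


@dataclass(slots=True)
class Stand:
    id: int
    area: float                      # m², constant through time
    centroid: tuple[float, float]    # planar metric coordinates
    neighbor_ids: set[int]
    unit_id: int
    restriction_zone: RestrictionZone
    site_type: SiteType
    productivity_class: int
    upper_layer: list[SpeciesComponent]
    second_layer: list[SpeciesComponent] = field(default_factory=list)
    regeneration_mode: RegenerationMode = RegenerationMode.NATURAL
    registered: bool = True
    hpi: bool = False                # within the settlement buffer
    years_since_clearcut: int | None = None
    similar_stand_ids: tuple[int | None, int | None] = (None, None)  # (natural, planted)
    geometry: Polygon | None = None


@dataclass(slots=True)
class CadastralUnit:
    id: int
    owner_type: OwnerType
    intensity: Intensity
    stand_ids: list[int]


@dataclass(slots=True)
class HarvestEvent:
    stand_id: int
    year: int
    event: str                       # clearcut | registered | intensity_change
    area_m2: float


@dataclass
class LandscapeState:
    """The full mutable simulation world."""

    year: int
    stands: dict[int, Stand]
    units: dict[int, CadastralUnit]
    events: list[HarvestEvent] = field(default_factory=list)
    rng_seed: int | None = None
    extent: tuple[float, float] | None = None  # (width, height) in m, if known

    def copy(self) -> "LandscapeState":
        return copy.deepcopy(self)

    @property
    def total_area(self) -> float:
        return sum(s.area for s in self.stands.values())

    def log(self, stand_id: int, event: str, area: float) -> None:
        self.events.append(HarvestEvent(stand_id, self.year, event, area))


# ---------------------------------------------------------------------------
# Core stand-level operations
# ---------------------------------------------------------------------------

def weighted_stand_age(layer: Sequence[SpeciesComponent]) -> float:
    """Share-weighted mean age of a layer.

    Raises ``ValueError`` on an empty layer ("no overstory").
    """
    if not layer:
        raise ValueError("no overstory: cannot compute weighted age of an empty layer")
    return sum(c.share * c.age for c in layer)


def stand_age(stand: Stand) -> float:
    """Weighted upper-layer age; 0.0 for a stand with no described overstory."""
    if not stand.upper_layer:
        return 0.0
    return weighted_stand_age(stand.upper_layer)


def assign_management_type(stand: Stand) -> ManagementType:
    """Management type from restriction zone and site type, in priority order.

    Priority (first match wins): strict protection → no management; alvar
    site → alvar; limited-management class A/B → limited; waterbody
    restriction → riparian; bog site → bog; otherwise general.  E.g. a bog
    stand inside a waterbody restriction belongs to the riparian type.
    """
    zone = RestrictionZone(stand.restriction_zone)
    site = SiteType(stand.site_type)
    if zone is RestrictionZone.STRICT:
        return ManagementType.NO_MANAGEMENT
    if site is SiteType.ALVAR:
        return ManagementType.ALVAR
    if zone in (RestrictionZone.CLASS_A, RestrictionZone.CLASS_B):
        return ManagementType.LIMITED
    if zone is RestrictionZone.WATERBODY:
        return ManagementType.RIPARIAN
    if site is SiteType.BOG:
        return ManagementType.BOG
    return ManagementType.GENERAL


def validate_landscape(state: LandscapeState) -> list[str]:
    """Check all structural invariants; violations are returned, not raised."""
    out: list[str] = []
    for sid, st in state.stands.items():
        if st.area <= 0:
            out.append(f"stand {sid}: non-positive area {st.area}")
        if sid in st.neighbor_ids:
            out.append(f"stand {sid}: self-adjacency")
        for nid in st.neighbor_ids:
            nb = state.stands.get(nid)
            if nb is None:
                out.append(f"stand {sid}: unknown neighbor {nid}")
            elif sid not in nb.neighbor_ids:
                out.append(f"stand {sid}: asymmetric adjacency with {nid}")
        for name, layer in (("upper", st.upper_layer), ("second", st.second_layer)):
            if layer:
                tot = sum(c.share for c in layer)
                if abs(tot - 1.0) > 1e-6:
                    out.append(f"stand {sid}: {name}-layer shares sum to {tot:.6f}")
                for c in layer:
                    if c.age < 0:
                        out.append(f"stand {sid}: negative age in {name} layer")
        try:
            RestrictionZone(st.restriction_zone)
            SiteType(st.site_type)
        except ValueError as exc:  # pragma: no cover - constructed inputs
            out.append(f"stand {sid}: {exc}")
        unit = state.units.get(st.unit_id)
        if unit is None:
            out.append(f"stand {sid}: unknown unit {st.unit_id}")
        elif sid not in unit.stand_ids:
            out.append(f"stand {sid}: unit {st.unit_id} does not list it")
    seen: dict[int, int] = {}
    for uid, unit in state.units.items():
        for sid in unit.stand_ids:
            if sid in seen:
                out.append(f"stand {sid}: listed by units {seen[sid]} and {uid}")
            seen[sid] = uid
            if sid not in state.stands:
                out.append(f"unit {uid}: unknown stand {sid}")
    return out


# ---------------------------------------------------------------------------
# Serialization: CSV (with WKT geometry) and GeoJSON
# ---------------------------------------------------------------------------

def _encode_layer(layer: Sequence[SpeciesComponent]) -> str:
    parts = []
    for c in layer:
        stock = "" if c.stock is None else repr(float(c.stock))
        parts.append(f"{c.species}:{c.share!r}:{c.age!r}:{stock}")
    return ";".join(parts)


def _decode_layer(text: str) -> list[SpeciesComponent]:
    if not text or text != text:  # NaN guard
        return []
    out = []
    for part in str(text).split(";"):
        sp, share, age, stock = part.split(":")
        out.append(SpeciesComponent(sp, float(share), float(age),
                                    float(stock) if stock else None))
    return out


def stands_to_frame(state: LandscapeState) -> pd.DataFrame:
    rows = []
    for st in state.stands.values():
        rows.append({
            "id": st.id,
            "area_m2": st.area,
            "centroid_x": st.centroid[0],
            "centroid_y": st.centroid[1],
            "neighbor_ids": " ".join(str(i) for i in sorted(st.neighbor_ids)),
            "unit_id": st.unit_id,
            "restriction_zone": st.restriction_zone.value,
            "site_type": st.site_type.value,
            "productivity_class": st.productivity_class,
            "upper_layer": _encode_layer(st.upper_layer),
            "second_layer": _encode_layer(st.second_layer),
            "regeneration_mode": st.regeneration_mode.value,
            "registered": st.registered,
            "hpi": st.hpi,
            "years_since_clearcut": (
                "" if st.years_since_clearcut is None else st.years_since_clearcut),
            "natural_ref": ("" if st.similar_stand_ids[0] is None
                            else st.similar_stand_ids[0]),
            "planted_ref": ("" if st.similar_stand_ids[1] is None
                            else st.similar_stand_ids[1]),
            "geometry_wkt": "" if st.geometry is None else st.geometry.wkt,
        })
    return pd.DataFrame(rows).sort_values("id").reset_index(drop=True)


def units_to_frame(state: LandscapeState) -> pd.DataFrame:
    rows = [{
        "id": u.id,
        "owner_type": u.owner_type.value,
        "intensity": u.intensity.value,
        "stand_ids": " ".join(str(i) for i in u.stand_ids),
    } for u in state.units.values()]
    return pd.DataFrame(rows).sort_values("id").reset_index(drop=True)


def _opt_int(value) -> int | None:
    if value is None or value == "" or value != value:
        return None
    return int(float(value))


def frames_to_state(stands_df: pd.DataFrame, units_df: pd.DataFrame,
                    year: int = 2022) -> LandscapeState:
    stands: dict[int, Stand] = {}
    for row in stands_df.itertuples(index=False):
        nbrs = {int(t) for t in str(row.neighbor_ids).split()} if str(
            row.neighbor_ids).strip() else set()
        geom = None
        geo_txt = getattr(row, "geometry_wkt", "")
        if isinstance(geo_txt, str) and geo_txt.strip():
            geom = _wkt.loads(geo_txt)
        stands[int(row.id)] = Stand(
            id=int(row.id),
            area=float(row.area_m2),
            centroid=(float(row.centroid_x), float(row.centroid_y)),
            neighbor_ids=nbrs,
            unit_id=int(row.unit_id),
            restriction_zone=RestrictionZone(row.restriction_zone),
            site_type=SiteType(row.site_type),
            productivity_class=int(row.productivity_class),
            upper_layer=_decode_layer(row.upper_layer),
            second_layer=_decode_layer(row.second_layer),
            regeneration_mode=RegenerationMode(row.regeneration_mode),
            registered=bool(row.registered),
            hpi=bool(row.hpi),
            years_since_clearcut=_opt_int(row.years_since_clearcut),
            similar_stand_ids=(_opt_int(row.natural_ref), _opt_int(row.planted_ref)),
            geometry=geom,
        )
    units = {}
    for row in units_df.itertuples(index=False):
        units[int(row.id)] = CadastralUnit(
            id=int(row.id),
            owner_type=OwnerType(row.owner_type),
            intensity=Intensity(row.intensity),
            stand_ids=[int(t) for t in str(row.stand_ids).split()],
        )
    return LandscapeState(year=year, stands=stands, units=units)


def save_landscape_csv(state: LandscapeState, stands_path, units_path) -> None:
    stands_to_frame(state).to_csv(stands_path, index=False)
    units_to_frame(state).to_csv(units_path, index=False)


def load_landscape_csv(stands_path, units_path, year: int = 2022) -> LandscapeState:
    stands_df = pd.read_csv(stands_path, keep_default_na=False)
    units_df = pd.read_csv(units_path, keep_default_na=False)
    return frames_to_state(stands_df, units_df, year=year)


def save_landscape_geojson(state: LandscapeState, path) -> None:
    """Write stands as a GeoJSON FeatureCollection (polygon geometry required)."""
    features = []
    for st in sorted(state.stands.values(), key=lambda s: s.id):
        if st.geometry is None:
            raise ValueError(f"stand {st.id} has no polygon geometry")
        props = {
            "id": st.id, "unit_id": st.unit_id,
            "restriction_zone": st.restriction_zone.value,
            "site_type": st.site_type.value,
            "productivity_class": st.productivity_class,
            "upper_layer": _encode_layer(st.upper_layer),
            "second_layer": _encode_layer(st.second_layer),
            "regeneration_mode": st.regeneration_mode.value,
            "registered": st.registered, "hpi": st.hpi,
            "years_since_clearcut": st.years_since_clearcut,
            "natural_ref": st.similar_stand_ids[0],
            "planted_ref": st.similar_stand_ids[1],
        }
        features.append({"type": "Feature", "properties": props,
                         "geometry": _geo_mapping(st.geometry)})
    units = [{"id": u.id, "owner_type": u.owner_type.value,
              "intensity": u.intensity.value, "stand_ids": u.stand_ids}
             for u in sorted(state.units.values(), key=lambda u: u.id)]
    doc = {"type": "FeatureCollection", "features": features,
           "metadata": {"year": state.year, "rng_seed": state.rng_seed,
                        "units": units}}
    with open(path, "w") as fh:
        json.dump(doc, fh)


def polygon_adjacency(geoms: Mapping[int, Polygon]) -> dict[int, set[int]]:
    """Shared-boundary adjacency: two polygons are neighbors when they touch
    along a boundary segment of positive length (corner contact is not
    adjacency)."""
    ids = sorted(geoms)
    tree = STRtree([geoms[i] for i in ids])
    adj: dict[int, set[int]] = {i: set() for i in ids}
    for pos, sid in enumerate(ids):
        g = geoms[sid]
        for other_pos in tree.query(g, predicate="touches"):
            oid = ids[other_pos]
            if oid == sid:
                continue
            if g.intersection(geoms[oid]).length > 0:
                adj[sid].add(oid)
                adj[oid].add(sid)
    return adj


def load_landscape_geojson(path, year: int | None = None) -> LandscapeState:
    """Read a GeoJSON stand layer; area, centroid and adjacency come from the
    polygon geometry."""
    with open(path) as fh:
        doc = json.load(fh)
    geoms: dict[int, Polygon] = {}
    props: dict[int, dict] = {}
    for feat in doc["features"]:
        p = feat["properties"]
        sid = int(p["id"])
        geoms[sid] = _geo_shape(feat["geometry"])
        props[sid] = p
    adj = polygon_adjacency(geoms)
    stands = {}
    for sid, p in props.items():
        g = geoms[sid]
        stands[sid] = Stand(
            id=sid, area=g.area, centroid=(g.centroid.x, g.centroid.y),
            neighbor_ids=adj[sid], unit_id=int(p["unit_id"]),
            restriction_zone=RestrictionZone(p["restriction_zone"]),
            site_type=SiteType(p["site_type"]),
            productivity_class=int(p["productivity_class"]),
            upper_layer=_decode_layer(p["upper_layer"]),
            second_layer=_decode_layer(p["second_layer"]),
            regeneration_mode=RegenerationMode(p["regeneration_mode"]),
            registered=bool(p["registered"]), hpi=bool(p["hpi"]),
            years_since_clearcut=_opt_int(p.get("years_since_clearcut")),
            similar_stand_ids=(_opt_int(p.get("natural_ref")),
                               _opt_int(p.get("planted_ref"))),
            geometry=g,
        )
    meta = doc.get("metadata", {})
    units = {int(u["id"]): CadastralUnit(
        id=int(u["id"]), owner_type=OwnerType(u["owner_type"]),
        intensity=Intensity(u["intensity"]),
        stand_ids=[int(i) for i in u["stand_ids"]]) for u in meta.get("units", [])}
    return LandscapeState(year=year if year is not None else int(meta.get("year", 2022)),
                          stands=stands, units=units,
                          rng_seed=meta.get("rng_seed"))


def events_to_frame(events: Iterable[HarvestEvent]) -> pd.DataFrame:
    return pd.DataFrame([{"stand_id": e.stand_id, "year": e.year,
                          "event": e.event, "area_m2": e.area_m2}
                         for e in events],
                        columns=["stand_id", "year", "event", "area_m2"])
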