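"""Seeded generator of synthetic landscapes with the statistical structure of
the Estonian stand system: a perturbed rectangular tessellation of stands,
contiguous multi-stand cadastral units, spatially clustered protection zoning
(≈12.9 % strict / 12.3 % restricted), alvar and bog site blobs, mixed
state/physical/juridical ownership, settlement-proximity flags and a
clustered unregistered fraction awaiting land-reform completion.

Also produces synthetic per-stand canopy-height percentile summaries for
exercising the registry-update clear-cut detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import box as _box

from .core import (
    CadastralUnit,
    Intensity,
    LandscapeState,
    OwnerType,
    RegenerationMode,
    RestrictionZone,
    SiteType,
    SpeciesComponent,
    Stand,
)
from .registry import stand_expected_height


def _default_species_pool() -> dict[str, float]:
    return {"pine": 0.35, "spruce": 0.30, "birch": 0.35}


@dataclass
class SynthParams:
    """Parameters of the synthetic landscape generator.

    Defaults emulate the modeled Estonian forest land: mean stand area
    ≈ 1.15 ha (2.3 Mha over ~2 M stands), 12.9 % strictly protected and
    12.3 % restricted-management stands, alvar/bog site prevalences, and a
    10 % unregistered fraction.
    """

    n_stands: int = 1000
    extent: tuple[float, float] | None = None      # (width, height) m
    mean_stand_area: float = 11_500.0              # m²
    fraction_strict: float = 0.129
    fraction_restricted: float = 0.123             # waterbody + class A/B
    fraction_waterbody: float = 0.051              # subset of restricted
    prevalence_alvar: float = 0.020
    prevalence_bog: float = 0.136
    state_fraction: float = 0.5                    # of cadastral units
    juridical_fraction: float = 0.33               # of private units
    mean_stands_per_unit: float = 4.0
    age_shape: float = 2.2                         # gamma age distribution
    age_scale: float = 25.0                        # years
    species_pool: dict[str, float] = field(default_factory=_default_species_pool)
    planted_fraction: float = 0.25
    second_layer_prob: float = 0.30                # for stands aged >= 60
    settlement_density_km2: float = 0.1
    hpi_distance: float = 1000.0                   # m
    fraction_unregistered: float = 0.10
    blob_size_range: tuple[int, int] = (10, 40)    # stands per zoning blob
    seed: int = 0

    def __post_init__(self):
        fracs = (self.fraction_strict, self.fraction_restricted,
                 self.fraction_waterbody, self.prevalence_alvar,
                 self.prevalence_bog, self.state_fraction,
                 self.juridical_fraction, self.fraction_unregistered)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if self.fraction_strict + self.fraction_restricted > 1.0:
            raise ValueError("strict + restricted fractions exceed 1")
        if self.fraction_waterbody > self.fraction_restricted:
            raise ValueError("waterbody fraction exceeds the restricted fraction")
        if self.n_stands < 1:
            raise ValueError("n_stands must be positive")
        if self.mean_stands_per_unit > self.n_stands:
            raise ValueError("mean unit size exceeds the number of stands")


# ---------------------------------------------------------------------------
# Tessellation
# ---------------------------------------------------------------------------

def _jittered_breaks(n: int, length: float, rng, jitter: float = 0.3) -> np.ndarray:
    """n+1 strictly increasing breaks over [0, length] with perturbed
    interior boundaries (exact tiling is preserved)."""
    base = np.linspace(0.0, length, n + 1)
    if n > 1:
        step = length / n
        base[1:-1] += rng.uniform(-jitter, jitter, size=n - 1) * step
    return base


def _tessellate(params: SynthParams, rng):
    n = params.n_stands
    if params.extent is None:
        side = math.sqrt(n * params.mean_stand_area)
        extent = (side, side)
    else:
        extent = tuple(params.extent)
    width, height = extent
    nx = max(1, int(round(math.sqrt(n))))
    ny = max(1, math.ceil(n / nx))
    row_counts = [nx] * (ny - 1) + [n - nx * (ny - 1)]
    ybreaks = _jittered_breaks(ny, height, rng)
    rects = []          # (x0, y0, x1, y1) per stand id
    rows = []           # list of lists of stand ids
    sid = 0
    for r, m in enumerate(row_counts):
        xbreaks = _jittered_breaks(m, width, rng)
        row = []
        for c in range(m):
            rects.append((xbreaks[c], ybreaks[r], xbreaks[c + 1], ybreaks[r + 1]))
            row.append(sid)
            sid += 1
        rows.append(row)
    # adjacency: consecutive within a row; across rows where x-intervals
    # overlap with positive length
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for row in rows:
        for a, b in zip(row, row[1:]):
            adj[a].add(b)
            adj[b].add(a)
    for lower, upper in zip(rows, rows[1:]):
        for a in lower:
            ax0, _, ax1, _ = rects[a]
            for b in upper:
                bx0, _, bx1, _ = rects[b]
                if min(ax1, bx1) - max(ax0, bx0) > 1e-9:
                    adj[a].add(b)
                    adj[b].add(a)
    return extent, rects, adj


def _grow_blobs(n: int, target: int, adj: dict[int, set[int]],
                available: set[int], rng, size_range: tuple[int, int]) -> set[int]:
    """Assign ``target`` stands to spatially clustered blobs grown by BFS
    through ``available`` stands; returns the assigned set."""
    assigned: set[int] = set()
    pool = sorted(available)
    while len(assigned) < target and pool:
        seed = pool[int(rng.integers(len(pool)))]
        if seed in assigned:
            pool = sorted(set(pool) - assigned)
            continue
        want = min(int(rng.integers(size_range[0], size_range[1] + 1)),
                   target - len(assigned))
        frontier = [seed]
        blob: set[int] = set()
        while frontier and len(blob) < want:
            cur = frontier.pop(0)
            if cur in assigned or cur in blob or cur not in available:
                continue
            blob.add(cur)
            for nb in sorted(adj[cur]):
                if nb in available and nb not in assigned and nb not in blob:
                    frontier.append(nb)
        assigned |= blob
        pool = sorted(set(pool) - assigned)
    return assigned


def _grow_units(adj: dict[int, set[int]], n: int, mean_size: float, rng):
    """Contiguous cadastral units of ~mean_size stands covering every stand."""
    unassigned = set(range(n))
    units: list[list[int]] = []
    while unassigned:
        pool = sorted(unassigned)
        seed = pool[int(rng.integers(len(pool)))]
        k = max(1, 1 + int(rng.poisson(max(mean_size - 1.0, 0.0))))
        members = []
        frontier = [seed]
        while frontier and len(members) < k:
            cur = frontier.pop(0)
            if cur not in unassigned:
                continue
            members.append(cur)
            unassigned.discard(cur)
            for nb in sorted(adj[cur]):
                if nb in unassigned:
                    frontier.append(nb)
        units.append(members)
    return units


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------

def generate_landscape(params: SynthParams) -> LandscapeState:
    """Build a complete, validated synthetic landscape (deterministic in the
    seed: the same parameters give a bit-identical landscape)."""
    rng = np.random.default_rng(params.seed)
    n = params.n_stands
    extent, rects, adj = _tessellate(params, rng)

    # --- protection zoning as clustered blobs ---
    all_ids = set(range(n))
    strict_ids = _grow_blobs(n, round(params.fraction_strict * n), adj,
                             all_ids, rng, params.blob_size_range)
    restricted_ids = _grow_blobs(n, round(params.fraction_restricted * n), adj,
                                 all_ids - strict_ids, rng, params.blob_size_range)
    p_wb = (params.fraction_waterbody / params.fraction_restricted
            if params.fraction_restricted > 0 else 0.0)
    zones: dict[int, RestrictionZone] = {}
    for sid in range(n):
        if sid in strict_ids:
            zones[sid] = RestrictionZone.STRICT
        elif sid in restricted_ids:
            if rng.random() < p_wb:
                zones[sid] = RestrictionZone.WATERBODY
            else:
                zones[sid] = (RestrictionZone.CLASS_A if rng.random() < 0.5
                              else RestrictionZone.CLASS_B)
        else:
            zones[sid] = RestrictionZone.UNRESTRICTED

    # --- site types as clustered blobs, independent of zoning ---
    alvar_ids = _grow_blobs(n, round(params.prevalence_alvar * n), adj,
                            all_ids, rng, params.blob_size_range)
    bog_ids = _grow_blobs(n, round(params.prevalence_bog * n), adj,
                          all_ids - alvar_ids, rng, params.blob_size_range)

    # --- cadastral units and ownership ---
    unit_members = _grow_units(adj, n, params.mean_stands_per_unit, rng)
    owners = []
    for _ in unit_members:
        if rng.random() < params.state_fraction:
            owners.append(OwnerType.STATE)
        elif rng.random() < params.juridical_fraction:
            owners.append(OwnerType.JURIDICAL)
        else:
            owners.append(OwnerType.PHYSICAL)

    # --- settlements and the heightened-public-interest buffer ---
    area_km2 = extent[0] * extent[1] / 1e6
    n_settle = int(round(params.settlement_density_km2 * area_km2))
    settlements = (rng.uniform((0, 0), extent, size=(n_settle, 2))
                   if n_settle > 0 else np.empty((0, 2)))
    settle_tree = cKDTree(settlements) if n_settle > 0 else None

    # --- unregistered stands, spatially clustered ---
    unregistered = _grow_blobs(n, round(params.fraction_unregistered * n), adj,
                               all_ids, rng, params.blob_size_range)

    species_names = sorted(params.species_pool)
    species_probs = np.array([params.species_pool[s] for s in species_names])
    species_probs = species_probs / species_probs.sum()

    stands: dict[int, Stand] = {}
    for sid in range(n):
        x0, y0, x1, y1 = rects[sid]
        area = (x1 - x0) * (y1 - y0)
        centroid = ((x0 + x1) / 2.0, (y0 + y1) / 2.0)
        age = float(np.clip(round(rng.gamma(params.age_shape, params.age_scale)),
                            1, 200))
        dom = species_names[int(rng.choice(len(species_names), p=species_probs))]
        vol = 4.0 * min(age, 100.0) * area / 10_000.0   # m³, a crude yield proxy
        if rng.random() < 0.55:
            other = species_names[int(rng.choice(len(species_names), p=species_probs))]
            if other == dom:
                layer = [SpeciesComponent(dom, 1.0, age, vol)]
            else:
                dshare = float(rng.uniform(0.6, 0.9))
                layer = [SpeciesComponent(dom, dshare, age, dshare * vol),
                         SpeciesComponent(other, 1.0 - dshare, age,
                                          (1.0 - dshare) * vol)]
        else:
            layer = [SpeciesComponent(dom, 1.0, age, vol)]
        second: list[SpeciesComponent] = []
        if age >= 60 and rng.random() < params.second_layer_prob:
            second = [SpeciesComponent("spruce", 1.0, float(round(age / 3.0)),
                                       0.15 * vol)]
        hpi = bool(settle_tree is not None and
                   settle_tree.query(centroid)[0] <= params.hpi_distance)
        stands[sid] = Stand(
            id=sid, area=area, centroid=centroid, neighbor_ids=set(adj[sid]),
            unit_id=-1, restriction_zone=zones[sid],
            site_type=(SiteType.ALVAR if sid in alvar_ids
                       else SiteType.BOG if sid in bog_ids else SiteType.MINERAL),
            productivity_class=int(rng.choice([1, 2, 3], p=[0.3, 0.5, 0.2])),
            upper_layer=layer, second_layer=second,
            regeneration_mode=(RegenerationMode.PLANTED
                               if rng.random() < params.planted_fraction
                               else RegenerationMode.NATURAL),
            registered=sid not in unregistered, hpi=hpi,
            geometry=_box(x0, y0, x1, y1),
        )

    units: dict[int, CadastralUnit] = {}
    for uid, (members, owner) in enumerate(zip(unit_members, owners)):
        units[uid] = CadastralUnit(
            id=uid, owner_type=owner,
            intensity=(Intensity.NOT_APPLICABLE if owner is OwnerType.STATE
                       else Intensity.NONINT),
            stand_ids=sorted(members))
        for sid in members:
            stands[sid].unit_id = uid

    _assign_similar_refs(stands)
    return LandscapeState(year=2022, stands=stands, units=units,
                          rng_seed=params.seed, extent=extent)


def _assign_similar_refs(stands: dict[int, Stand]) -> None:
    """Nearest neighboring stand of each regeneration mode, used as the
    composition reference for post-harvest regeneration transitions."""
    for mode, slot in ((RegenerationMode.NATURAL, 0), (RegenerationMode.PLANTED, 1)):
        members = [st for st in stands.values() if st.regeneration_mode is mode]
        if not members:
            continue
        tree = cKDTree([m.centroid for m in members])
        for st in stands.values():
            k = 2 if st.regeneration_mode is mode else 1
            _, idx = tree.query(st.centroid, k=k)
            pick = int(np.atleast_1d(idx)[-1])
            if pick < len(members) and members[pick].id != st.id:
                ref = members[pick].id
            elif len(members) > 1:
                ref = members[0].id if members[0].id != st.id else members[1].id
            else:
                ref = None
            refs = list(st.similar_stand_ids)
            refs[slot] = ref
            st.similar_stand_ids = tuple(refs)


# ---------------------------------------------------------------------------
# Canopy summaries (registry-update test fixture)
# ---------------------------------------------------------------------------

def generate_canopy_summaries(state: LandscapeState, noise_sd: float,
                              seed: int,
                              secretly_cut: Iterable[int] = (),
                              scan_years: dict[int, int] | None = None
                              ) -> pd.DataFrame:
    """Per-stand canopy-height percentile summaries (p50, p90, scan year).

    Uncut stands get a median near their expected height with the 90th
    percentile slightly above; stands in ``secretly_cut`` get a near-ground
    median with sparse tall retention returns (high p90), which the
    registry-update detector is built to separate.
    """
    rng = np.random.default_rng(seed)
    cut = set(secretly_cut)
    if scan_years is None:
        from .registry import default_scan_years
        scan_years = default_scan_years(state)
    rows = []
    for sid in sorted(state.stands):
        st = state.stands[sid]
        expected = stand_expected_height(st)
        if sid in cut:
            p90 = max(0.7 * expected, 12.0) + abs(rng.normal(0.0, noise_sd))
            cap = 0.45 * min(p90, expected) if expected > 0 else 0.45 * p90
            p50 = float(np.clip(abs(rng.normal(1.0, noise_sd)), 0.0, cap))
        else:
            p50 = float(np.clip(expected + rng.normal(0.0, noise_sd),
                                0.75 * expected, None))
            p90 = 1.15 * expected + abs(rng.normal(0.0, noise_sd))
            # an intact canopy has a narrow height distribution: keep the
            # spread well inside the detector's unevenness region
            p90 = min(p90, max(1.3 * expected, 1.4 * p50))
            p90 = max(p90, p50)
        rows.append({"stand_id": sid, "p50": p50, "p90": p90,
                     "scan_year": scan_years.get(sid, 2021)})
    return pd.DataFrame(rows)
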