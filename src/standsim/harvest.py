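"""The annual clear-cutting decision and permitting machinery.

A clear-cut happens when two questions are both answered yes: does the owner
*want* to harvest this year (a stochastic willingness decided per cadastral
unit for private land, per stand for state land under partial restrictions),
and is the cut *allowed* (stand age above the legal felling-maturity age, and
an adjacency criterion: the candidate stand plus all connected recent
clear-cuts must stay within a management-type-specific total cutover area).

Because every executed cut changes what its neighbors are allowed to do, the
within-year process is strictly sequential — stands A and B can each be
permissible on their own while cutting A forbids cutting B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import box as _box

from .core import (
    CadastralUnit,
    Intensity,
    LandscapeState,
    ManagementType,
    OwnerType,
    RegenerationMode,
    RestrictionZone,
    SpeciesComponent,
    Stand,
    assign_management_type,
    stand_age,
)
from .succession import (
    MaturityTable,
    advance_ages,
    maturity_age,
    transfer_all_second_layers,
)

#: Private permitting order of one annual iteration (poorly regenerating and
#: most constrained types first).
MANAGEMENT_SEQUENCE = (
    ManagementType.ALVAR,
    ManagementType.RIPARIAN,
    ManagementType.LIMITED,
    ManagementType.BOG,
    ManagementType.GENERAL,
)


def _default_area_limits() -> dict[ManagementType, float]:
    return {
        ManagementType.ALVAR: 20_000.0,
        ManagementType.RIPARIAN: 20_000.0,
        ManagementType.BOG: 50_000.0,
        ManagementType.GENERAL: 70_000.0,
    }


@dataclass
class HarvestParams:
    """All tunables of the harvest decision machinery.

    Defaults are the REAL-scenario parameterization: yearly base clear-cutting
    probabilities by management intensity and restriction class, the linear
    age adjustment (base probability doubles 20 years past maturity, capped at
    1), per-management-type total cutover area limits, the limited-management
    5-year neighbor quiet period, and the state-forest quota machinery.
    """

    cutprob_int: float = 0.385
    cutprob_nonint: float = 0.055
    cutprob_state: float = 1.0
    cutprob_class_a_private: float = 0.2
    cutprob_class_b_private: float = 0.1
    cutprob_state_ab: float = 0.05
    doubling_horizon: float = 20.0
    #: Age-adjustment horizon for restriction class A/B stands.  ``None``
    #: means the ordinary doubling horizon applies.
    restricted_doubling_horizon: float | None = None
    clearcut_age_threshold: float = 6.0
    area_limits: dict[ManagementType, float] = field(default_factory=_default_area_limits)
    limited_quiet_period: int = 5
    state_quota: float = 120_000_000.0          # m²/yr
    state_cluster_radius: float = 1_000.0       # m
    state_maturity_offset: float = 10.0         # years past maturity
    hpi_maturity_offset: float = 20.0           # years, near settlements
    regen_transition_prob: float = 0.05
    second_layer_rate: float = 0.01
    maturity: MaturityTable = field(default_factory=MaturityTable)

    def __post_init__(self):
        for name in ("cutprob_int", "cutprob_nonint", "cutprob_state",
                     "cutprob_class_a_private", "cutprob_class_b_private",
                     "cutprob_state_ab", "regen_transition_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if any(v <= 0 for v in self.area_limits.values()):
            raise ValueError("area limits must be positive")


# ---------------------------------------------------------------------------
# Willingness
# ---------------------------------------------------------------------------

def age_adjusted_probability(base: float, years_past_maturity: float,
                             horizon: float = 20.0) -> float:
    """Linear age adjustment of a yearly base cutting probability.

    Zero below maturity; afterwards the base grows linearly so that exceeding
    maturity by ``horizon`` years doubles it, capped at 1.
    """
    if not 0.0 <= base <= 1.0:
        raise ValueError(f"base must be in [0, 1], got {base}")
    if years_past_maturity < 0:
        return 0.0
    return min(1.0, base * (1.0 + years_past_maturity / horizon))


def application_probability(adjusted: Iterable[float]) -> float:
    """Unit-level application probability: equal-weight mean over the stands
    with non-zero age-adjusted probability (zero-probability stands get zero
    weight); 0 when no stand qualifies."""
    nonzero = [p for p in adjusted if p > 0]
    return sum(nonzero) / len(nonzero) if nonzero else 0.0


def stand_base_probability(stand: Stand, unit: CadastralUnit,
                           params: HarvestParams,
                           nonint_base: float | None = None) -> float:
    """Base yearly cutting probability of a private stand.

    Restriction class A/B stands use their own base probabilities but never
    above the unit's unrestricted base; strictly protected stands are 0.
    """
    zone = stand.restriction_zone
    if zone is RestrictionZone.STRICT:
        return 0.0
    if unit.intensity is Intensity.INT:
        unit_base = params.cutprob_int
    else:
        unit_base = params.cutprob_nonint if nonint_base is None else nonint_base
    if zone is RestrictionZone.CLASS_A:
        return min(params.cutprob_class_a_private, unit_base)
    if zone is RestrictionZone.CLASS_B:
        return min(params.cutprob_class_b_private, unit_base)
    return unit_base


def adjusted_stand_probability(stand: Stand, unit: CadastralUnit,
                               params: HarvestParams,
                               nonint_base: float | None = None) -> float:
    if not stand.registered or not stand.upper_layer:
        return 0.0
    base = stand_base_probability(stand, unit, params, nonint_base)
    if base == 0.0:
        return 0.0
    ypm = stand_age(stand) - maturity_age(stand, params.maturity)
    horizon = params.doubling_horizon
    if stand.restriction_zone in (RestrictionZone.CLASS_A, RestrictionZone.CLASS_B) \
            and params.restricted_doubling_horizon is not None:
        horizon = params.restricted_doubling_horizon
    return age_adjusted_probability(base, ypm, horizon)


def unit_application_probability(unit: CadastralUnit, state: LandscapeState,
                                 params: HarvestParams,
                                 nonint_base: float | None = None) -> float:
    """Probability that a private owner applies for a permit this year."""
    if unit.owner_type is OwnerType.STATE:
        raise ValueError(
            f"unit {unit.id} is state-owned; state harvest is quota-driven, "
            "not application-driven")
    return application_probability(
        adjusted_stand_probability(state.stands[sid], unit, params, nonint_base)
        for sid in unit.stand_ids)


@dataclass
class Willingness:
    """Outcome of the annual willingness draws."""

    applications: dict[int, list[int]]    # unit id → eligible applied stand ids
    state_ab_willing: set[int]            # state class-A/B stand ids willing


def draw_willingness(state: LandscapeState, params: HarvestParams,
                     rng: np.random.Generator,
                     nonint_base: float | None = None) -> Willingness:
    """One Bernoulli draw per private unit (success → the owner applies for
    all its eligible stands) and one per state class-A/B stand."""
    applications: dict[int, list[int]] = {}
    state_ab: set[int] = set()
    for uid in sorted(state.units):
        unit = state.units[uid]
        if unit.owner_type is OwnerType.STATE:
            for sid in sorted(unit.stand_ids):
                st = state.stands[sid]
                if st.restriction_zone in (RestrictionZone.CLASS_A,
                                           RestrictionZone.CLASS_B) and st.registered:
                    if rng.random() < params.cutprob_state_ab:
                        state_ab.add(sid)
            continue
        eligible = [sid for sid in sorted(unit.stand_ids)
                    if adjusted_stand_probability(state.stands[sid], unit,
                                                  params, nonint_base) > 0]
        p = application_probability(
            adjusted_stand_probability(state.stands[sid], unit, params, nonint_base)
            for sid in unit.stand_ids)
        if p > 0 and rng.random() < p:
            applications[uid] = eligible
    return Willingness(applications, state_ab)


# ---------------------------------------------------------------------------
# Permitting
# ---------------------------------------------------------------------------

def _young_cluster(stand: Stand, state: LandscapeState, threshold: float,
                   candidate_area: float | None = None) -> tuple[set[int], float]:
    """Flood-fill the connected cutover cluster the candidate would form:
    the candidate (counted as if already cut) plus every stand younger than
    ``threshold`` reachable through young stands."""
    members = {stand.id}
    area = stand.area if candidate_area is None else candidate_area
    frontier = [stand.id]
    while frontier:
        sid = frontier.pop()
        for nid in state.stands[sid].neighbor_ids:
            if nid in members:
                continue
            nb = state.stands.get(nid)
            if nb is not None and stand_age(nb) < threshold:
                members.add(nid)
                area += nb.area
                frontier.append(nid)
    return members, area


def clearcut_cluster_area(stand: Stand, state: LandscapeState,
                          threshold: float = 6.0) -> float:
    """Total cutover area the stand would form if cut now: its own area plus
    all connected clear-cut (age < threshold) stand areas, including
    neighbors-of-neighbors."""
    return _young_cluster(stand, state, threshold)[1]


@dataclass(frozen=True)
class PermitDecision:
    status: str                       # allowed | denied | allowed_two_step
    reason: str = ""
    cluster_area: float = 0.0

    @property
    def allowed(self) -> bool:
        return self.status == "allowed"


def permit_clearcut(stand: Stand, state: LandscapeState,
                    params: HarvestParams) -> PermitDecision:
    """Apply the management-type-specific allowance rule to a candidate cut.

    General and bog types limit the connected cutover cluster to 7 / 5 ha,
    with an exemption for a single stand that is by itself larger than the
    limit (but no young neighbors may be attached).  Alvar and riparian types
    limit the cluster to 2 ha; larger stands are cut in two steps.  Limited
    management only requires that no neighboring stand was clear-cut within
    the last 5 years.
    """
    mgmt = assign_management_type(stand)
    if mgmt is ManagementType.NO_MANAGEMENT:
        raise RuntimeError(
            f"stand {stand.id} is strictly protected; a permit request for it "
            "must be unreachable")
    if mgmt is ManagementType.LIMITED:
        for nid in stand.neighbor_ids:
            nb = state.stands.get(nid)
            if nb is not None and nb.years_since_clearcut is not None \
                    and nb.years_since_clearcut < params.limited_quiet_period:
                return PermitDecision(
                    "denied",
                    f"neighbor {nid} clear-cut {nb.years_since_clearcut} years ago")
        return PermitDecision("allowed")
    limit = params.area_limits[mgmt]
    members, cluster = _young_cluster(stand, state, params.clearcut_age_threshold)
    if mgmt in (ManagementType.ALVAR, ManagementType.RIPARIAN):
        if stand.area > limit:
            return PermitDecision("allowed_two_step", cluster_area=cluster)
        if cluster <= limit:
            return PermitDecision("allowed", cluster_area=cluster)
        return PermitDecision(
            "denied", f"cutover cluster {cluster:.0f} m² exceeds {limit:.0f} m²",
            cluster_area=cluster)
    # bog / general
    if cluster <= limit:
        return PermitDecision("allowed", cluster_area=cluster)
    if stand.area > limit and members == {stand.id}:
        return PermitDecision("allowed", cluster_area=cluster)  # single-stand exemption
    return PermitDecision(
        "denied", f"cutover cluster {cluster:.0f} m² exceeds {limit:.0f} m²",
        cluster_area=cluster)


def _split_geometry(stand: Stand, first_area: float):
    """Split the stand polygon into two parts with the given first-part area
    by a straight cut perpendicular to the longer bounding-box axis."""
    geom = stand.geometry
    if geom is None:
        return None, None
    x0, y0, x1, y1 = geom.bounds
    frac = first_area / stand.area
    vertical = (x1 - x0) >= (y1 - y0)
    lo, hi = (x0, x1) if vertical else (y0, y1)
    for _ in range(60):  # bisection on the cut-line position
        mid = 0.5 * (lo + hi)
        part = geom.intersection(
            _box(x0, y0, mid, y1) if vertical else _box(x0, y0, x1, mid))
        if part.area < frac * stand.area:
            lo = mid
        else:
            hi = mid
    cut = 0.5 * (lo + hi)
    first = geom.intersection(_box(x0, y0, cut, y1) if vertical
                              else _box(x0, y0, x1, cut))
    rest = geom.difference(first)
    return first, rest


def split_two_step(stand: Stand, state: LandscapeState,
                   limit: float) -> tuple[Stand, Stand]:
    """Partition an over-limit alvar/riparian stand into two child stands.

    The first child (to be cut now) gets ``min(limit, area/2)``; both children
    inherit the parent's neighbors, are adjacent to each other, and replace
    the parent in the landscape and in its cadastral unit.
    """
    if stand.area <= limit:
        raise ValueError(f"stand {stand.id} does not exceed the limit; no split")
    first_area = min(limit, stand.area / 2.0)
    rest_area = stand.area - first_area
    new_id = max(state.stands) + 1
    ids = (new_id, new_id + 1)
    g_first, g_rest = _split_geometry(stand, first_area)
    side = math.sqrt(stand.area) / 4.0
    children = []
    for cid, area, geom, dx in zip(ids, (first_area, rest_area),
                                   (g_first, g_rest), (-side, side)):
        centroid = ((geom.centroid.x, geom.centroid.y) if geom is not None
                    else (stand.centroid[0] + dx, stand.centroid[1]))
        child = replace(
            stand, id=cid, area=area, centroid=centroid,
            neighbor_ids=set(stand.neighbor_ids), geometry=geom,
            upper_layer=[SpeciesComponent(c.species, c.share, c.age, c.stock)
                         for c in stand.upper_layer],
            second_layer=[SpeciesComponent(c.species, c.share, c.age, c.stock)
                          for c in stand.second_layer])
        children.append(child)
    children[0].neighbor_ids.add(ids[1])
    children[1].neighbor_ids.add(ids[0])
    for nid in stand.neighbor_ids:
        nb = state.stands[nid]
        nb.neighbor_ids.discard(stand.id)
        nb.neighbor_ids.update(ids)
    del state.stands[stand.id]
    for child in children:
        state.stands[child.id] = child
    unit = state.units[stand.unit_id]
    unit.stand_ids = [sid for sid in unit.stand_ids if sid != stand.id] + list(ids)
    return children[0], children[1]


def execute_clearcut(stand: Stand, state: LandscapeState, params: HarvestParams,
                     rng: np.random.Generator) -> LandscapeState:
    """Carry out a permitted cut: ages reset to 0, second layer removed, and
    with the regeneration transition probability the stand flips between
    planted and natural regeneration, taking the composition of its stored
    similar stand of the target mode."""
    if stand.restriction_zone is RestrictionZone.STRICT:
        raise RuntimeError(f"stand {stand.id} is strictly protected")
    if rng.random() < params.regen_transition_prob:
        target = (RegenerationMode.NATURAL
                  if stand.regeneration_mode is RegenerationMode.PLANTED
                  else RegenerationMode.PLANTED)
        ref_id = stand.similar_stand_ids[0 if target is RegenerationMode.NATURAL else 1]
        ref = state.stands.get(ref_id) if ref_id is not None else None
        if ref is not None and ref.upper_layer:
            stand.upper_layer = [SpeciesComponent(c.species, c.share, 0.0, 0.0)
                                 for c in ref.upper_layer]
        else:
            for c in stand.upper_layer:
                c.age = 0.0
                c.stock = 0.0
        stand.regeneration_mode = target
    else:
        for c in stand.upper_layer:
            c.age = 0.0
            c.stock = 0.0
    stand.second_layer = []
    stand.years_since_clearcut = 0
    state.log(stand.id, "clearcut", stand.area)
    return state


OnCut = Callable[[int, LandscapeState], None] | None


def _attempt_cut(stand: Stand, state: LandscapeState, params: HarvestParams,
                 rng: np.random.Generator, on_cut: OnCut = None) -> float:
    """Permit and, if allowed, execute one candidate cut; returns the area cut
    (handles the two-step split of over-limit alvar/riparian stands)."""
    decision = permit_clearcut(stand, state, params)
    if decision.status == "allowed":
        execute_clearcut(stand, state, params, rng)
        if on_cut is not None:
            on_cut(stand.id, state)
        return stand.area
    if decision.status == "allowed_two_step":
        limit = params.area_limits[assign_management_type(stand)]
        first_area = min(limit, stand.area / 2.0)
        # the first child would form this cutover cluster
        _, cluster = _young_cluster(stand, state, params.clearcut_age_threshold,
                                    candidate_area=first_area)
        if cluster > limit:
            return 0.0
        first, _rest = split_two_step(stand, state, limit)
        execute_clearcut(first, state, params, rng)
        if on_cut is not None:
            on_cut(first.id, state)
        return first.area
    return 0.0


# ---------------------------------------------------------------------------
# State forest harvest
# ---------------------------------------------------------------------------

def _state_eligible(state: LandscapeState, params: HarvestParams,
                    state_ab_willing: set[int]) -> list[Stand]:
    out = []
    for uid in sorted(state.units):
        unit = state.units[uid]
        if unit.owner_type is not OwnerType.STATE:
            continue
        for sid in sorted(unit.stand_ids):
            st = state.stands[sid]
            if not st.registered or not st.upper_layer:
                continue
            zone = st.restriction_zone
            if zone is RestrictionZone.STRICT:
                continue
            if zone in (RestrictionZone.CLASS_A, RestrictionZone.CLASS_B):
                if sid not in state_ab_willing:
                    continue
            elif params.cutprob_state < 1.0:
                continue  # unrestricted state stands willing iff cutprob 1
            offset = (params.hpi_maturity_offset if st.hpi
                      else params.state_maturity_offset)
            if stand_age(st) - maturity_age(st, params.maturity) >= offset:
                out.append(st)
    return out


def state_forest_harvest(state: LandscapeState, params: HarvestParams,
                         rng: np.random.Generator,
                         state_ab_willing: set[int] | frozenset[int] = frozenset(),
                         on_cut: OnCut = None) -> LandscapeState:
    """Quota-driven state harvest: repeatedly cut the largest harvestable
    cluster (eligible state stands within the 1-km radius of the top-scoring
    focal stand) until the yearly felling quota is met or nothing remains.
    Every member cut still passes the ordinary per-stand permit rules."""
    cut_total = 0.0
    blocked: set[int] = set()
    willing = set(state_ab_willing)
    while cut_total < params.state_quota:
        eligible = [st for st in _state_eligible(state, params, willing)
                    if st.id not in blocked]
        if not eligible:
            break
        pts = np.array([st.centroid for st in eligible])
        tree = cKDTree(pts)
        groups = tree.query_ball_point(pts, r=params.state_cluster_radius)
        scores = [sum(eligible[j].area for j in grp) for grp in groups]
        best = int(np.argmax(scores))
        members = sorted((eligible[j] for j in groups[best]),
                         key=lambda s: (-s.area, s.id))
        cut_here = 0.0
        for st in members:
            cut_here += _attempt_cut(st, state, params, rng, on_cut)
            if cut_total + cut_here >= params.state_quota:
                break
        cut_total += cut_here
        if cut_here == 0.0:
            blocked.add(eligible[best].id)
    return state


# ---------------------------------------------------------------------------
# The annual iteration and multi-year scenarios
# ---------------------------------------------------------------------------

def run_year(state: LandscapeState, config, rng: np.random.Generator,
             on_cut: OnCut = None) -> LandscapeState:
    """One annual iteration.

    Order: scenario drivers (ownership conversion, land-reform registration,
    market-trend interpolation of the non-intensive base probability) →
    willingness draws → private permitting in the five-type sequence (units in
    seeded random order, stands within a unit and type largest first, each
    executed cut constraining the next) → state forest harvest → aging and
    second-layer transfer.
    """
    from . import scenario as _scenario  # deferred: scenario imports this module

    params: HarvestParams = config.params
    nonint_base = _scenario.apply_annual_drivers(state, config, rng)
    will = draw_willingness(state, params, rng, nonint_base)
    cut_this_year: set[int] = set()
    for mtype in MANAGEMENT_SEQUENCE:
        unit_ids = sorted(will.applications)
        order = rng.permutation(len(unit_ids))
        for k in order:
            uid = unit_ids[int(k)]
            stands = [state.stands[sid] for sid in will.applications[uid]
                      if sid in state.stands and sid not in cut_this_year
                      and assign_management_type(state.stands[sid]) is mtype]
            for st in sorted(stands, key=lambda s: (-s.area, s.id)):
                if _attempt_cut(st, state, params, rng, on_cut) > 0:
                    cut_this_year.add(st.id)
    state_forest_harvest(state, params, rng, will.state_ab_willing, on_cut)
    advance_ages(state)
    transfer_all_second_layers(state, params.second_layer_rate)
    return state


def annual_summary(state: LandscapeState) -> dict:
    """Default per-year snapshot: age-class area shares and the year's cut."""
    total = old80 = old100 = young20 = strict_area = restricted_area = 0.0
    for st in state.stands.values():
        a = stand_age(st)
        total += st.area
        if a >= 80:
            old80 += st.area
        if a >= 100:
            old100 += st.area
        if a < 20:
            young20 += st.area
        if st.restriction_zone is RestrictionZone.STRICT:
            strict_area += st.area
        elif st.restriction_zone is not RestrictionZone.UNRESTRICTED:
            restricted_area += st.area
    year_cut = sum(e.area_m2 for e in state.events
                   if e.event == "clearcut" and e.year == state.year - 1)
    return {
        "year": state.year,
        "share_old80": old80 / total,
        "share_old100": old100 / total,
        "share_young20": young20 / total,
        "strict_area": strict_area,
        "restricted_area": restricted_area,
        "cut_area": year_cut,
    }


@dataclass
class ScenarioResult:
    """Per-seed annual trajectories plus across-seed summaries."""

    trajectories: dict[int, pd.DataFrame]
    final_states: dict[int, LandscapeState]

    def summary(self) -> pd.DataFrame:
        """Across-seed median / min / max of every metric, per year."""
        stacked = pd.concat(self.trajectories.values())
        grouped = stacked.groupby("year")
        out = grouped.median().add_suffix("_median")
        out = out.join(grouped.min().add_suffix("_min"))
        out = out.join(grouped.max().add_suffix("_max"))
        return out.reset_index()


def run_scenario(initial: LandscapeState, config, n_years: int | None = None,
                 seeds: Sequence[int] = (1,),
                 snapshot_fn: Callable[[LandscapeState], Mapping] = annual_summary,
                 keep_states: bool = True,
                 on_cut: OnCut = None) -> ScenarioResult:
    """Run independent seeded replicates of a scenario.

    Each replicate deep-copies the initial landscape, assigns management
    intensities with its own random stream, optionally adds the simulated
    extra clear-cuts of starting condition *b*, and iterates ``run_year``.
    """
    from . import registry as _registry
    from . import scenario as _scenario

    if n_years is None:
        n_years = config.end_year - config.start_year + 1
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    trajectories: dict[int, pd.DataFrame] = {}
    finals: dict[int, LandscapeState] = {}
    for seed in seeds:
        rng = np.random.default_rng(seed)
        st = initial.copy()
        st.rng_seed = seed
        _scenario.assign_intensity(st.units, config, rng)
        if getattr(config, "simulated_extra_clearcuts", False):
            _registry.simulate_missing_clearcuts(
                st, _registry.DecayRates(), rng=rng, maturity=config.params.maturity)
        rows = []
        for _ in range(n_years):
            run_year(st, config, rng, on_cut)
            rows.append(dict(snapshot_fn(st)))
        trajectories[seed] = pd.DataFrame(rows)
        if keep_states:
            finals[seed] = st
    return ScenarioResult(trajectories, finals)


def cumulative_cut_probability(base: float, n_years: int,
                               horizon: float = 20.0) -> float:
    """Probability that an unconstrained stand is cut within ``n_years`` of
    maturation: 1 − Π_{t=0}^{n−1} (1 − min(1, base·(1 + t/horizon)))."""
    surv = 1.0
    for t in range(n_years):
        surv *= 1.0 - age_adjusted_probability(base, t, horizon)
    return 1.0 - surv
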