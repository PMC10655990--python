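"""Scenario presets and time-varying socioeconomic drivers.

Six named scenarios differ in how the starting condition is handled
(recorded clear-cuts only, *a*, or with simulated extra clear-cuts added,
*b*), whether non-intensively managed private estates keep converting to
intensive management (ownership change), whether market pressure ramps the
non-intensive base cutting probability up over time, and whether the
adjacency limits are enforced loosely (20 % larger in GOV).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import Intensity, LandscapeState, OwnerType
from .harvest import HarvestParams
from .succession import maturity_age
from .core import stand_age

SCENARIO_NAMES = ("DEFa", "DEFb", "MODa", "MODb", "GOV", "REAL")


@dataclass
class ScenarioConfig:
    """One scenario's full parameterization (single source of tunables)."""

    name: str = "REAL"
    start_year: int = 2022
    end_year: int = 2050
    params: HarvestParams = field(default_factory=HarvestParams)
    p_int_juridical: float = 0.95
    p_int_physical: float = 0.35
    conversion_rate: float = 0.028        # yearly, 0 in DEF/GOV
    area_limit_multiplier: float = 1.0    # 1.2 in GOV (limits pre-scaled)
    nonint_cutprob_2050: float | None = 0.13   # REAL market-pressure endpoint
    simulated_extra_clearcuts: bool = True     # starting condition b
    land_reform_completion_year: int = 2050

    def __post_init__(self):
        if self.area_limit_multiplier < 1.0:
            raise ValueError("area limit multiplier must be >= 1")
        if self.nonint_cutprob_2050 is not None \
                and self.nonint_cutprob_2050 < self.params.cutprob_nonint:
            raise ValueError("2050 endpoint must not be below the base probability")


def build_scenario(name: str, **overrides) -> ScenarioConfig:
    """Construct a named scenario preset; keyword overrides are applied last."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    params = HarvestParams()
    cfg = ScenarioConfig(name=name, params=params)
    if name in ("DEFa", "MODa"):
        params.cutprob_int = 0.35
        params.cutprob_nonint = 0.05
        cfg.simulated_extra_clearcuts = False
    if name in ("DEFa", "DEFb", "GOV"):
        cfg.conversion_rate = 0.0
    if name != "REAL":
        cfg.nonint_cutprob_2050 = None
    if name == "GOV":
        cfg.area_limit_multiplier = 1.2
        params.area_limits = {k: 1.2 * v for k, v in params.area_limits.items()}
    for key, value in overrides.items():
        if hasattr(cfg, key):
            setattr(cfg, key, value)
        elif hasattr(params, key):
            setattr(params, key, value)
        else:
            raise ValueError(f"unknown configuration field {key!r}")
    return cfg


def assign_intensity(units: Mapping[int, object], config: ScenarioConfig,
                     rng: np.random.Generator) -> Mapping[int, object]:
    """Initialization-time draw of management intensity per private unit:
    intensive with the owner-type prior; state units are not applicable."""
    priors = {OwnerType.JURIDICAL: config.p_int_juridical,
              OwnerType.PHYSICAL: config.p_int_physical}
    for uid in sorted(units):
        unit = units[uid]
        if unit.owner_type is OwnerType.STATE:
            unit.intensity = Intensity.NOT_APPLICABLE
        else:
            unit.intensity = (Intensity.INT
                              if rng.random() < priors[unit.owner_type]
                              else Intensity.NONINT)
    return units


def _has_mature_stand(unit, state: LandscapeState, config: ScenarioConfig) -> bool:
    table = config.params.maturity
    for sid in unit.stand_ids:
        st = state.stands[sid]
        if st.upper_layer and stand_age(st) >= maturity_age(st, table):
            return True
    return False


def convert_ownership(state: LandscapeState, config: ScenarioConfig,
                      rng: np.random.Generator) -> LandscapeState:
    """Yearly ownership/intensity shift: a seeded sample of the eligible
    non-intensive private units (those holding at least one mature stand)
    flips to intensive management; the count is the conversion rate times the
    eligible pool, rounded half-even."""
    if config.conversion_rate <= 0:
        return state
    eligible = [uid for uid in sorted(state.units)
                if state.units[uid].owner_type is not OwnerType.STATE
                and state.units[uid].intensity is Intensity.NONINT
                and _has_mature_stand(state.units[uid], state, config)]
    n = round(config.conversion_rate * len(eligible))
    if n <= 0:
        return state
    chosen = rng.choice(len(eligible), size=n, replace=False)
    for k in sorted(int(i) for i in chosen):
        unit = state.units[eligible[k]]
        unit.intensity = Intensity.INT
        for sid in unit.stand_ids:
            state.log(sid, "intensity_change", state.stands[sid].area)
    return state


def include_unregistered(state: LandscapeState, year: int,
                         config: ScenarioConfig,
                         rng: np.random.Generator | None = None) -> LandscapeState:
    """Land-reform completion: the same number of currently unregistered
    stands becomes registered (harvestable) every year so that all forest
    land is included by the completion year."""
    if not hasattr(state, "_initial_unregistered"):
        state._initial_unregistered = sum(
            1 for st in state.stands.values() if not st.registered)
        state._registered_so_far = 0
    n0 = state._initial_unregistered
    if n0 == 0:
        return state
    span = max(1, config.land_reform_completion_year - config.start_year)
    k = min(span, max(0, year - config.start_year) + 1)
    target = n0 if k >= span else round(n0 * k / span)
    need = target - state._registered_so_far
    if need <= 0:
        return state
    pool = [sid for sid in sorted(state.stands)
            if not state.stands[sid].registered]
    if rng is not None and len(pool) > need:
        idx = sorted(int(i) for i in rng.choice(len(pool), size=need, replace=False))
        pick = [pool[i] for i in idx]
    else:
        pick = pool[:need]
    for sid in pick:
        state.stands[sid].registered = True
        state.log(sid, "registered", state.stands[sid].area)
    state._registered_so_far += len(pick)
    return state


def interpolate_nonint_cutprob(year: int, config: ScenarioConfig) -> float:
    """Linear market-pressure ramp of the non-intensive base probability from
    its start-year value to the 2050 endpoint (REAL scenario only)."""
    base = config.params.cutprob_nonint
    if config.nonint_cutprob_2050 is None:
        return base
    frac = (year - config.start_year) / (config.end_year - config.start_year)
    frac = min(1.0, max(0.0, frac))
    return base + frac * (config.nonint_cutprob_2050 - base)


def apply_annual_drivers(state: LandscapeState, config: ScenarioConfig,
                         rng: np.random.Generator) -> float:
    """Start-of-year scenario updates; returns this year's non-intensive base
    cutting probability."""
    convert_ownership(state, config, rng)
    include_unregistered(state, state.year, config, rng)
    return interpolate_nonint_cutprob(state.year, config)


def config_to_dict(config: ScenarioConfig) -> dict:
    """Flat serializable view of a scenario configuration (for manifests)."""
    p = config.params
    d = {k: v for k, v in vars(config).items() if k != "params"}
    d["params"] = {k: (dict({m.value: a for m, a in v.items()})
                       if k == "area_limits" else v)
                   for k, v in vars(p).items() if k != "maturity"}
    return copy.deepcopy(d)
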