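"""Pre-simulation registry refresh.

Stand registries lag behind reality: owners clear-cut and postpone renewing
the stand description.  This module (1) detects unrecorded clear-cuts from
per-stand canopy-height percentile summaries, (2) extrapolates the time decay
of the detection rate to add the clear-cuts that even the newest scans miss,
and (3) imputes missing overstory compositions from similar neighboring
stands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    LandscapeState,
    RegenerationMode,
    RestrictionZone,
    SpeciesComponent,
    Stand,
    stand_age,
)
from .succession import MaturityTable, maturity_age

#: Synthetic height-growth parameters: asymptotic height (m) by species and
#: productivity class (1 = best), with a saturating Chapman-Richards form.
#: Documented stand-in — the operational height model is registry-specific.
DEFAULT_HEIGHT_ASYMPTOTE = {
    ("pine", 1): 31.0, ("pine", 2): 27.0, ("pine", 3): 23.0,
    ("spruce", 1): 33.0, ("spruce", 2): 29.0, ("spruce", 3): 25.0,
    ("birch", 1): 28.0, ("birch", 2): 25.0, ("birch", 3): 22.0,
}
HEIGHT_RATE = 0.03       # 1/years
HEIGHT_SHAPE = 1.3


def expected_height(species: str, age: float, productivity_class: int,
                    asymptotes: dict | None = None) -> float:
    """Expected stand height (m) from species, age and site productivity.

    Monotone increasing and saturating in age; 0 at age 0.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    table = DEFAULT_HEIGHT_ASYMPTOTE if asymptotes is None else asymptotes
    try:
        hmax = table[(species, int(productivity_class))]
    except KeyError:
        raise KeyError(f"unknown species/productivity: "
                       f"({species!r}, {productivity_class})") from None
    return hmax * (1.0 - math.exp(-HEIGHT_RATE * age)) ** HEIGHT_SHAPE


def stand_expected_height(stand: Stand) -> float:
    """Expected height of the dominant (largest-share) overstory species."""
    if not stand.upper_layer:
        return 0.0
    dom = max(stand.upper_layer, key=lambda c: (c.share, c.species))
    return expected_height(dom.species, dom.age, stand.productivity_class)


@dataclass(frozen=True)
class CanopySummary:
    """Per-stand canopy height percentile summary from one lidar scan."""

    stand_id: int
    p50: float       # m, 50th percentile of canopy height
    p90: float       # m
    scan_year: int

    def __post_init__(self):
        if not 0 <= self.p50 <= self.p90:
            raise ValueError(
                f"stand {self.stand_id}: need 0 <= p50 <= p90, "
                f"got p50={self.p50}, p90={self.p90}")


def _default_rates() -> dict[int, float]:
    return {2021: 0.084, 2020: 0.076, 2019: 0.068}


@dataclass(frozen=True)
class DecayRates:
    """Additional (unrecorded) clear-cut rate by lidar scan year: older scans
    have had less chance to catch recent cuts."""

    rates: dict[int, float] = field(default_factory=_default_rates)

    def __post_init__(self):
        for year, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate for {year} must be in [0, 1], got {r}")

    @property
    def slope(self) -> float:
        """Fitted linear trend of the rate per year of scan recency."""
        years = sorted(self.rates)
        if len(years) < 2:
            return 0.0
        return float(np.polyfit(years, [self.rates[y] for y in years], 1)[0])


def detect_clearcut(summary: CanopySummary, expected: float,
                    unevenness_threshold: float = 0.7,
                    eps: float = 1e-9) -> bool:
    """Clear-cut detection from canopy percentiles.

    Rule 1: the median canopy height is less than half of both the 90th
    percentile and the expected stand height (most returns are ground or
    regrowth under sparse tall retention trees).  Rule 2: the height
    distribution is very uneven — the relative spread between the 50th and
    90th percentile exceeds a configurable threshold (partially cut stands).
    """
    rule1 = summary.p50 < 0.5 * summary.p90 and summary.p50 < 0.5 * expected
    rule2 = (summary.p90 - summary.p50) / max(summary.p90, eps) > unevenness_threshold
    return bool(rule1 or rule2)


def default_scan_years(state: LandscapeState) -> dict[int, int]:
    """Regional scan-year assignment: west-to-east thirds of the landscape
    map to scan years 2019, 2020 and 2021 (scanning proceeds by region)."""
    xs = np.array([st.centroid[0] for st in state.stands.values()])
    lo, hi = xs.min(), xs.max()
    width = max(hi - lo, 1.0)
    out = {}
    for sid, st in state.stands.items():
        frac = (st.centroid[0] - lo) / width
        out[sid] = 2019 + min(2, int(frac * 3))
    return out


def simulate_missing_clearcuts(state: LandscapeState,
                               rates: DecayRates | None = None,
                               rng: np.random.Generator | None = None,
                               scan_years: dict[int, int] | None = None,
                               partial_year_fraction: float = 0.5,
                               maturity: MaturityTable | None = None) -> LandscapeState:
    """Add the clear-cuts that the newest available scans still miss.

    The linear trend of the per-scan-year additional clear-cut rates is
    extrapolated to the target date: stands scanned in older years carry the
    full rate gap to the newest scan year, and all stands carry a partial-year
    term (``slope × partial_year_fraction``) for cuts made after the newest
    scans.  The implied count per scan-year region is drawn from the mature,
    registered, non-strict stands and those are flagged clear-cut (age 0)
    before the first simulated year.
    """
    if rates is None:
        rates = DecayRates()
    if rng is None:
        rng = np.random.default_rng(0)
    if maturity is None:
        maturity = MaturityTable()
    if scan_years is None:
        scan_years = default_scan_years(state)
    latest = max(rates.rates)
    partial = rates.slope * partial_year_fraction
    groups: dict[int, list[int]] = {}
    for sid in sorted(state.stands):
        groups.setdefault(scan_years.get(sid, latest), []).append(sid)
    for year, sids in sorted(groups.items()):
        shortfall = (rates.rates[latest] - rates.rates.get(year, rates.rates[latest])
                     ) + partial
        n_extra = int(round(shortfall * len(sids)))
        if n_extra <= 0:
            continue
        candidates = [sid for sid in sids
                      if _eligible_for_simulated_cut(state.stands[sid], maturity)]
        n_extra = min(n_extra, len(candidates))
        if n_extra == 0:
            continue
        idx = rng.choice(len(candidates), size=n_extra, replace=False)
        for k in sorted(int(i) for i in idx):
            st = state.stands[candidates[k]]
            for c in st.upper_layer:
                c.age = 0.0
                c.stock = 0.0
            st.second_layer = []
            st.years_since_clearcut = 0
            state.log(st.id, "clearcut", st.area)
    return state


def _eligible_for_simulated_cut(stand: Stand, maturity: MaturityTable) -> bool:
    if not stand.registered or not stand.upper_layer:
        return False
    if stand.restriction_zone is RestrictionZone.STRICT:
        return False
    return stand_age(stand) >= maturity_age(stand, maturity)


def impute_missing_composition(stand: Stand, donors: list[Stand],
                               rng: np.random.Generator,
                               k_nearest: int = 5) -> Stand:
    """Fill a missing overstory from a similar registered stand.

    Similarity = same site type, nearest centroid (a seeded-random pick among
    the ``k_nearest`` closest such donors).  The regeneration mode is drawn
    0.2 artificial (planted) / 0.8 natural.  Stands that already have a
    composition are returned unchanged.
    """
    if stand.upper_layer:
        return stand
    pool = [d for d in donors if d.upper_layer and d.id != stand.id]
    same_site = [d for d in pool if d.site_type == stand.site_type]
    if same_site:
        pool = same_site
    if not pool:
        raise ValueError(f"stand {stand.id}: empty donor pool")
    pool.sort(key=lambda d: (math.dist(d.centroid, stand.centroid), d.id))
    near = pool[:k_nearest]
    donor = near[int(rng.integers(len(near)))]
    stand.upper_layer = [SpeciesComponent(c.species, c.share, c.age, c.stock)
                         for c in donor.upper_layer]
    stand.regeneration_mode = (RegenerationMode.PLANTED if rng.random() < 0.2
                               else RegenerationMode.NATURAL)
    return stand
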