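"""Annual aging, second-layer dynamics, and felling-maturity evaluation.

The legal minimum felling age is a matrix over species composition and site
productivity class.  The statutory matrix itself is not shipped; a clearly
synthetic default is provided and any real matrix can be supplied as a CSV
(``species, productivity_class, min_age``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.spatial import cKDTree

from .core import LandscapeState, SpeciesComponent, Stand, stand_age, weighted_stand_age

#: Synthetic default minimum felling ages (years) by species and productivity
#: class (1 = best site).  NOT the statutory values — a stand-in with the same
#: monotone structure: better sites mature for felling earlier.
DEFAULT_MATURITY = {
    ("pine", 1): 90, ("pine", 2): 100, ("pine", 3): 110,
    ("spruce", 1): 80, ("spruce", 2): 90, ("spruce", 3): 100,
    ("birch", 1): 60, ("birch", 2): 70, ("birch", 3): 80,
}


@dataclass(frozen=True)
class MaturityTable:
    """Minimum felling age lookup, (species, productivity_class) → years.

    For mixed stands the stand-level maturity age is the stock-share-weighted
    mean of the per-species entries at the stand's productivity class (the
    statutory mixing rule for mixed compositions is not public; this weighting
    is a documented, configurable choice).
    """

    entries: dict[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_MATURITY))

    def __post_init__(self):
        for key, age in self.entries.items():
            if age <= 0:
                raise ValueError(f"maturity entry {key} must be positive, got {age}")

    def lookup(self, species: str, productivity_class: int) -> float:
        try:
            return self.entries[(species, int(productivity_class))]
        except KeyError:
            raise KeyError(
                f"no maturity entry for species={species!r}, "
                f"productivity_class={productivity_class}") from None

    @classmethod
    def from_csv(cls, path) -> "MaturityTable":
        df = pd.read_csv(path)
        return cls({(r.species, int(r.productivity_class)): float(r.min_age)
                    for r in df.itertuples(index=False)})

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [{"species": sp, "productivity_class": pc, "min_age": age}
             for (sp, pc), age in sorted(self.entries.items())]
        ).to_csv(path, index=False)


def maturity_age(stand: Stand, table: MaturityTable) -> float:
    """Stand-level minimum felling age: share-weighted over the upper layer."""
    if not stand.upper_layer:
        raise ValueError(f"stand {stand.id}: no overstory, maturity age undefined")
    return sum(c.share * table.lookup(c.species, stand.productivity_class)
               for c in stand.upper_layer)


def years_past_maturity(stand: Stand, table: MaturityTable) -> float:
    """Weighted stand age minus maturity age (negative below maturity)."""
    return weighted_stand_age(stand.upper_layer) - maturity_age(stand, table)


def advance_ages(state: LandscapeState) -> LandscapeState:
    """One year of aging: every layer component +1 year; the
    years-since-clear-cut counter advances where set.  In place."""
    for st in state.stands.values():
        for c in st.upper_layer:
            c.age += 1
        for c in st.second_layer:
            c.age += 1
        if st.years_since_clearcut is not None:
            st.years_since_clearcut += 1
    state.year += 1
    return state


def transfer_second_layer(stand: Stand, rate: float = 0.01) -> Stand:
    """Move ``rate`` of each second-layer component's stock into the overstory.

    The second layer itself is retained unchanged (its stock is not depleted);
    the overstory gains matching components (created at the second-layer
    component's age when absent) and its shares are renormalized by stock.
    Stands without stock bookkeeping or without a second layer are returned
    unchanged.
    """
    if rate == 0 or not stand.second_layer:
        return stand
    if any(c.stock is None for c in stand.second_layer) or any(
            c.stock is None for c in stand.upper_layer):
        return stand
    upper = {c.species: c for c in stand.upper_layer}
    for sec in stand.second_layer:
        added = rate * sec.stock
        if added == 0:
            continue
        comp = upper.get(sec.species)
        if comp is None:
            comp = SpeciesComponent(sec.species, 0.0, sec.age, 0.0)
            stand.upper_layer.append(comp)
            upper[sec.species] = comp
        comp.stock += added
    total = sum(c.stock for c in stand.upper_layer)
    if total > 0:
        for c in stand.upper_layer:
            c.share = c.stock / total
    return stand


def transfer_all_second_layers(state: LandscapeState, rate: float = 0.01) -> LandscapeState:
    for st in state.stands.values():
        transfer_second_layer(st, rate)
    return state


def apply_second_layer_rules(state: LandscapeState,
                             donor_radius: float = 1000.0) -> LandscapeState:
    """One-time initialization of second layers from registry-style age rules.

    Stands younger than 60 years are deemed to lack a second layer (any
    recorded one is dropped); stands older than 90 without one are deemed not
    to produce one; 60–90-year-old stands without one are assigned a copy of
    the second layer of the nearest >90-year-old stand within 1 km that has
    one (no donor → no second layer).  Idempotent.
    """
    donors = [st for st in state.stands.values()
              if st.upper_layer and stand_age(st) > 90 and st.second_layer]
    tree = cKDTree([d.centroid for d in donors]) if donors else None
    for st in state.stands.values():
        if not st.upper_layer:
            st.second_layer = []
            continue
        age = stand_age(st)
        if age < 60:
            st.second_layer = []
        elif age <= 90 and not st.second_layer and tree is not None:
            dist, idx = tree.query(st.centroid, distance_upper_bound=donor_radius)
            if dist <= donor_radius:
                st.second_layer = [
                    SpeciesComponent(c.species, c.share, c.age, c.stock)
                    for c in donors[idx].second_layer]
    return state
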