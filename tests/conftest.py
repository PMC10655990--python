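import hypothesis
import numpy as np
import pytest

from standsim import (
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

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("ci")


def make_stand(sid, *, area=10_000.0, centroid=(0.0, 0.0), neighbors=(),
               unit_id=0, zone=RestrictionZone.UNRESTRICTED,
               site=SiteType.MINERAL, productivity=1, species="pine",
               age=100.0, registered=True, hpi=False, second_layer=(),
               years_since_clearcut=None, stock=100.0,
               regeneration_mode=RegenerationMode.NATURAL, geometry=None):
    """One single-species test stand (default: mature pine, maturity age 90)."""
    return Stand(
        id=sid, area=area, centroid=centroid, neighbor_ids=set(neighbors),
        unit_id=unit_id, restriction_zone=zone, site_type=site,
        productivity_class=productivity,
        upper_layer=[SpeciesComponent(species, 1.0, age, stock)],
        second_layer=list(second_layer),
        regeneration_mode=regeneration_mode, registered=registered, hpi=hpi,
        years_since_clearcut=years_since_clearcut, geometry=geometry)


def make_state(stands, units=None, year=2022):
    """Landscape from a list of stands; one unit per distinct unit_id unless
    units are given explicitly."""
    stand_map = {s.id: s for s in stands}
    if units is None:
        grouping = {}
        for s in stands:
            grouping.setdefault(s.unit_id, []).append(s.id)
        units = [CadastralUnit(uid, OwnerType.PHYSICAL, Intensity.INT, sorted(ids))
                 for uid, ids in grouping.items()]
    return LandscapeState(year=year, stands=stand_map,
                          units={u.id: u for u in units})


@pytest.fixture
def worked_example():
    """The four-stand cadastral unit: one strictly protected stand (3 ha, 10 y
    past maturity), one class-A stand (3 ha, 30 y past), one immature and one
    mature unrestricted stand (2 ha each, -3 and +20 y past maturity).  All
    stands neighbor each other; the unit is intensively managed."""
    everyone = {1, 2, 3, 4}
    stands = [
        make_stand(1, area=30_000.0, zone=RestrictionZone.STRICT, age=100.0,
                   neighbors=everyone - {1}),
        make_stand(2, area=30_000.0, zone=RestrictionZone.CLASS_A, age=120.0,
                   neighbors=everyone - {2}),
        make_stand(3, area=20_000.0, age=87.0, neighbors=everyone - {3}),
        make_stand(4, area=20_000.0, age=110.0, neighbors=everyone - {4}),
    ]
    return make_state(stands)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
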