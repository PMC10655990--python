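# standsim

A stand-resolution forest landscape simulator of clear-cut forestry under
realistic ownership, protection and permitting rules, with landscape-ecology
output metrics and a synthetic landscape generator for desk-scale
experiments.

## The problem and who this is for

In even-aged (clear-cutting based) silvicultural systems, the forest
landscape of the next decades is largely determined by where and when
regeneration harvests happen.  Those decisions are made per *stand* (a
homogeneous forest unit) by the owner of a *cadastral unit* (an estate of
several contiguous stands), and they are constrained by law: a stand may only
be clear-cut above a minimum felling age (a matrix over species composition
and site productivity), and an **adjacency criterion** forbids a cut when the
candidate stand together with all connected recent clear-cuts would exceed a
management-type-specific total cutover area.  This package is for landscape
ecologists and forest-policy analysts who want to project stand-level
landscape futures under alternative socioeconomic scenarios — ownership
change, market pressure, land-reform completion, laxer governance — and read
off age structure, clear-cut patch patterns, edge proportions and old-forest
connectivity.

## The model

Each simulated year asks, for every stand, a double question: *does the
owner want to harvest it this year, and if so, is it allowed?*

**Willingness.**  Every stand has a yearly base cutting probability set by
its unit's management intensity (intensive `CUTPROB = 0.385`, non-intensive
`0.055`) and restriction class (class A `0.2`, class B `0.1`, never above the
unit's unrestricted base; strictly protected stands `0`).  The base is
age-adjusted linearly,

```
p(stand) = 0  if below maturity,  else  min(1, base · (1 + y/20))
```

with `y` the years past the minimum felling age, so 20 years past maturity
doubles the base.  A private owner applies for a permit with probability
equal to the mean of `p` over the stands with `p > 0` (one Bernoulli draw per
unit per year; success means applying for *all* eligible stands).  State
forest is harvested greedily by largest 1-km clusters of stands at least
10 years past maturity (20 years near settlements) until a yearly quota is
met.

**Allowance.**  Permits are processed sequentially within a year in the
order alvar → riparian → limited → bog → general management, largest stand
first within a unit, because each executed cut changes what its neighbors
may do.  General/bog cuts are limited to a 7/5 ha connected cutover cluster
(single stands larger than the limit are exempt), alvar/riparian cuts to
2 ha with larger stands cut in two steps, and limited-management stands only
require no neighbor cut in the last 5 years.

**Outputs.**  Age-class compositions by zone/ownership/management, patch
size distributions for early-successional (<20 y) and old (≥80, ≥100 y)
forest, 30-m edge proportions, and the incidence-function (Hanski)
connectivity `Σ exp(−a·d)·S^b` (a = b = 0.5, d in km edge-to-edge between
circular patch approximations, S in m²), aggregated as an area-weighted mean
on a 10×10 km grid.

## Worked example

The arithmetic of one willingness decision, for an intensively managed
four-stand estate (strictly protected 3 ha; class A 3 ha, 30 y past
maturity; unrestricted 2 ha below maturity; unrestricted 2 ha, 20 y past):

```python
>>> from standsim import age_adjusted_probability, application_probability
>>> age_adjusted_probability(0.385, 20)     # mature unrestricted stand
0.77
>>> application_probability([0.0, 0.3, 0.0, 0.77])
0.535
```

The owner applies for a permit this year with probability 0.535; if the
draw succeeds, both eligible stands (5 ha in total) are applied for, which
stays below the 7 ha general-management cutover limit.

A desk-scale scenario run from the shell:

```
standsim generate --out land --n-stands 2000 --seed 1
standsim simulate --landscape land --scenario REAL --years 29 --seeds 1..5 --out run
standsim report --run-dir run
```

`run/summary.csv` then holds per-year across-seed medians/min/max of the
age-class shares and cut areas; e.g. `share_old80_median` is the area share
of ≥80-year forest each year.

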