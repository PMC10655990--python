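# Methods

## Model overview

`standsim` is an annually iterated, stochastic, stand-resolution simulator of
clear-cut forestry.  The state consists of stands (area, planar centroid,
immutable adjacency, protection zone, site type, productivity class, layered
species composition with ages and stocks) grouped into cadastral units
(owner type, management intensity).  One iteration runs: scenario drivers →
willingness draws → sequential private permitting → state-forest harvest →
aging and second-layer transfer.  All lengths are meters, areas m², ages
integer years.

Assumptions inherited from the modeled system: management is entirely
clear-cut based; the stand map and its adjacency are stable through time
(two-step splits are the one exception, and children inherit the parent's
neighbors plus each other); protection zoning does not change; mortality and
species-level growth dynamics are out of scope (hooks exist as stock
bookkeeping, defaults are zero change).

## Management types and permitting

A stand's management type follows a strict priority order over protection
zone and site type: strict → no management; alvar site → alvar; restriction
class A/B → limited; waterbody restriction → riparian; bog site → bog; else
general.  Cutover-area limits: alvar/riparian 20,000 m², bog 50,000 m²,
general 70,000 m² (scaled ×1.2 in the GOV scenario).  The cutover cluster of
a candidate is found by flood fill over stands younger than 6 years
(neighbors' neighbors included); a stand counts as a clear-cut while younger
than 6 years.  Single stands larger than the bog/general limit are exempt,
but only when no young stand is attached to them.  Limited management checks
only that no neighbor was cut in the previous 5 years (`years_since_clearcut
< 5`).  Over-limit alvar/riparian stands split into two children — the first
child `min(limit, area/2)`, cut immediately if its own cluster passes; the
residual is automatically blocked while the first child is younger than 6.

Within a year, private cuts run in the sequence alvar, riparian, limited,
bog, general; units are visited in a freshly shuffled random order each year
(the source is silent on this order; shuffling avoids systematic spatial
bias while staying reproducible), and stands within a unit and type go
largest first, ties broken by id.

## Willingness

Base probabilities (REAL parameterization): intensive 0.385, non-intensive
0.055 (linearly ramped to 0.13 by 2050 in REAL), state 1, private class A
0.2 and class B 0.1 both capped at the unit's unrestricted base, state class
A/B 0.05.  The age adjustment is linear with a 20-year doubling horizon,
capped at 1, and zero below maturity.  The unit application probability is
the equal-weight mean over stands with non-zero adjusted probability (zero
entries get zero weight); on success the owner applies for all eligible
stands.  A published example adjusts a class-A base of 0.2 to 0.3 at 30
years past maturity, which is inconsistent with the doubling rule (0.5);
the doubling rule is the default and
`HarvestParams.restricted_doubling_horizon` (e.g. 60) reproduces the
example's slower class-A adjustment when wanted.

State harvest is quota-driven (120,000,000 m²/yr by default): repeatedly
score every eligible state stand (willing, registered, ≥10 years past
maturity, or ≥20 for stands within 1,000 m of a settlement) by the summed
area of eligible stands within a 1,000-m centroid radius, harvest the
top-scoring cluster through the same per-stand permit rules, and stop at the
quota (overshoot bounded by one stand) or when nothing remains.  Willingness
probabilities below 1 for unrestricted state stands are not modeled (every
shipped scenario uses 1).

## Maturity

The minimum felling age is a configurable (species × productivity class)
table; the shipped default (pine 90/100/110, spruce 80/90/100, birch
60/70/80 by descending productivity) is synthetic and clearly non-normative
— the statutory matrix can be supplied as CSV.  Mixed stands use the
stock-share-weighted mean of the per-species entries; the statutory mixing
rule for mixed compositions is not public, so this weighting is a documented
package choice.

## Succession

Ages advance by one year per iteration.  Where a second layer exists, 1 % of
each second-layer component's stock moves into the overstory yearly (the
second layer is retained undepleted); overstory shares renormalize by stock.
At initialization: stands under 60 years lose any recorded second layer,
stands over 90 without one never produce one, and 60–90-year stands without
one copy the second layer of the nearest >90-year donor within 1 km, if any.
After a clear-cut all ages reset to 0, the second layer is removed, and with
probability 0.05 the regeneration mode flips (planted ↔ natural), taking the
composition of the stand's stored similar stand of the target mode.

## Scenarios

Presets: DEFa/DEFb (no ownership change; intensive/non-intensive bases
0.35/0.05 in the *a* variants, 0.385/0.055 in *b*), MODa/MODb (plus 2.8 %/yr
conversion of eligible non-intensive units — those with at least one mature
stand — to intensive, count rounded half-even), GOV (DEFb with limits ×1.2),
REAL (MODb plus the 0.055→0.13 market ramp).  The *b* starting condition
adds simulated extra clear-cuts before year 1 (below).  Land-reform
completion registers an equal number of unregistered stands per year so that
all are harvestable by 2050.  Intensity priors: P(INT | juridical) = 0.95,
P(INT | physical) = 0.35, drawn per replicate.  Converted units use the
intensive probability from the next willingness draw onward.

## Registry update

Clear-cut detection works on per-stand canopy-height percentile summaries:
a stand is flagged when the median height is less than half of both the 90th
percentile and the expected stand height, or when the relative spread
(p90 − p50)/p90 exceeds a configurable unevenness threshold (default 0.7 —
the operational rule's details are not public, so the threshold is a package
choice and excluded from calibration checks).  Expected heights come from a
synthetic, monotone, saturating Chapman–Richards table (asymptote by species
and productivity, rate 0.03/yr, shape 1.3) — a documented stand-in for the
registry-specific height model.

The time decay of the detection rate (additional clear-cut rates 8.4 % for
2021 scans, 7.6 % for 2020, 6.8 % for 2019) is extrapolated linearly: stands
scanned in older years carry the full rate gap to the newest scan year, and
a partial-year term `slope × partial_year_fraction` (default 0.5, mid-year
scans) covers cuts after the newest scans.  The implied count per scan-year
region is drawn from mature, registered, non-strict stands, which are set to
age 0 before year 1.  When no scan-year map is given, west-to-east thirds of
the landscape stand in for the scan regions.

Composition imputation copies the overstory of a seeded-random pick among
the five nearest same-site-type donors, and draws the regeneration mode 0.2
planted / 0.8 natural.

## Synthetic landscapes

The generator emulates the modeled Estonian structure at configurable scale:
a perturbed rectangular tessellation (exact tiling; mean stand area
11,500 m²), contiguous BFS-grown cadastral units (mean 4 stands), zoning and
site types as BFS-grown blobs hitting 12.9 % strict / 12.3 % restricted
(waterbody share 5.1 points, the rest split 50/50 into classes A and B —
the A/B proportions are unstated in the source, so an even split is used),
2.0 % alvar and 13.6 % bog sites, 10 % spatially clustered unregistered
stands, 50 % state-owned units with the private rest split roughly 2:1
physical:juridical, gamma-distributed stand ages (shape 2.2, scale 25 —
mean ≈ 55 y), a three-species pool, stocks from a crude 4 m³/ha/yr yield
proxy, and settlement points at 0.1/km² defining the 1,000-m
heightened-public-interest buffer.  Everything is drawn from a single seeded
generator; equal seeds give bit-identical landscapes.

What it does *not* emulate: realistic geography, soils, species
autocorrelation beyond blob clustering, realistic estate size distributions,
or a country-scale quota-to-area ratio (the default state quota exceeds a
desk-scale landscape, so eligible state stands are harvested as soon as they
qualify).  Passing tests therefore demonstrate rule correctness, internal
consistency and calibration arithmetic — not predictive skill on real
registry data.

Canopy summaries are constructed to be separable: uncut stands get a median
clipped to ≥75 % of expected height and a narrow spread; secretly cut stands
get a near-ground median under a high 90th percentile.  Detector
recall/precision results on these fixtures are construction checks, not
remote-sensing validation.

## Numerical choices

- Counts from fractional expectations (ownership conversion) round
  half-even; the land-reform schedule uses a cumulative rounded target so
  registration finishes exactly on time.
- Quota stopping: stop once cumulative cut area ≥ quota.
- Cluster scoring ties break toward the smallest stand id; "largest first"
  ties break by id.
- The grid connectivity aggregate is the area-weighted **mean** per cell
  (weights = patch area inside the cell, circular footprints); a weighted
  **sum** variant is exposed as an option since the two appear
  interchangeably in the literature this follows.
- Edge areas use exact polygon buffering (erosion of rectangles is exact);
  landscapes without geometry raise `GeometryUnavailable`.
- Degenerate inputs: empty overstories read as age 0 for cluster traversal
  but are ineligible for willingness; zero-height canopy summaries are valid
  and never flagged.

## Problem sizes used in the shipped checks

Desk-scale suites run 2,000-stand landscapes over 29 years (50 replicates
for the adjacency/protection invariants) and a 10,000-stand landscape over
10 replicates for the variance report; the first-passage calibration uses
100,000 independent Monte-Carlo stand trajectories against the closed-form
product.  These sizes were chosen as the smallest at which blob-level zoning
fractions, multi-stand units and cluster permitting are all exercised
meaningfully.

## Known limitations

- Whole-stand harvesting only ("maximum possible extent" never means a
  partial cut outside the alvar/riparian two-step rule).
- The state cluster radius is measured centroid-to-centroid; the source
  does not state the reference point.
- Adjacency limits bind state cuts too — conservative and uniform, though
  the source is silent on whether state permitting differs.
- No timber volume/revenue accounting, salvage logging, disturbance or
  climate modules; no diameter-based felling allowance.
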