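# Methods

This note documents the models and procedures implemented in
`climwindows`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data generator does and does not
emulate.

## Delta-method downscaling

A delta method bias-corrects a simulated field at time *t* by applying
the ratio (multiplicative; precipitation) or difference (additive;
temperature) between a reference simulation and a reference target.
Two steps are chained:

1. **Dynamic delta** (coarse → ~1° grid). The reference snapshot time
   t̂ is the one, among the available high-resolution snapshot times,
   whose global CO₂ is closest to CO₂(t); ties break toward the more
   recent time. This relaxes the classical method's stationarity
   assumption: the fine-scale correction pattern varies with the global
   climatic state instead of being fixed at the present day.
2. **Classical delta** (~1° → ~0.5° hexagonal analysis grid), always
   referenced against present-day simulated and observed climatology.
   Both the coarse model at *t* = 0 and the observations enter here, so
   a model constant in time returns the observations exactly.

**Multiplicative guard.** The ratio corrections are undefined where the
reference precipitation vanishes (hyperarid cells). Denominators are
floored at 0.1 mm y⁻¹ and correction ratios capped at 100; both
constants live in `climwindows.downscale` and bound noise amplification
without affecting cells with ordinary rainfall. Multiplicative outputs
are clipped at 0.

**Interpolation (⊞).** The regridding contract is what matters:
continuously differentiable, exact on constant and (bi)linear fields,
and no overshoot beyond the local data range. We use a tensor-product
PCHIP (shape-preserving cubic Hermite) interpolant, which satisfies all
three by construction; axes with fewer than four nodes fall back to
(bi)linear. Targets outside the source hull raise — such nodes must be
filled explicitly (below), never extrapolated silently.

**Land masks and infilling.** Land at time *t* is the strict inequality
E(x) > s(t) (a node exactly at sea level is sea). Masks nest: lower sea
level exposes a superset of the land at higher sea level. Nodes below
present sea level but exposed at time *t* have no delta-method value and
receive the inverse-distance-weighted (power 2, k = 4 nearest donors,
great-circle distances) value of present-day land donors. The power and
k are conventional IDW defaults and are configurable; results at
coastal fringes are insensitive to k for smooth fields.

All great-circle distances in the package use the haversine formula on
a sphere of radius 6371.0088 km.

## Decadal variability

Millennial climatologies are 30-year normals. Annual series (exactly
1000 years per millennium, not stitched across millennia because
successive millennia were simulated in parallel and their endpoints
need not coincide) yield per-decade scalers:

ε⁽ᵈ⁾ = mean(decade d) / mean(30-year window of decades d−1, d, d+1),

with the difference of the same means for temperature. The ratio/
difference is taken between *means*, not raw 10- and 30-year sums, so a
constant series yields ε = 1 (δ = 0) and applying scalers to a normal
preserves its scale. Edge decades (d = 1, d = 100) clamp the window to
the years available inside the millennium (years 1–20 and 981–1000
respectively) — the simplest convention that avoids cross-millennium
stitching. A 30-year window mean below the 0.1 mm y⁻¹ floor raises
rather than producing unstable scalers. The scaler millennium for an
analysis time outside the annual-series coverage is chosen by the same
CO₂ matching as the dynamic delta reference.

Because windows overlap and truncate, the mean of the 100 decadal
fields is not exactly the normal; on smooth synthetic series it stays
well within 15 % (asserted in the tests), and sub-decadal variability
(interannual, seasonal, storms) is deliberately not modelled.

**Köppen aridity.** A = P / (T + 33) with P in mm y⁻¹ and T in °C;
lower is more arid. The index is undefined at T ≤ −33 °C, which raises;
it is homogeneous of degree one in precipitation.

## Corridor connectivity and critical tolerance

The analysis grid is a quasi-uniform hexagonal node set over
[15°E, 70°E] × [5°N, 43°N] with ~55 km spacing. Construction uses
latitude rows √3/2 spacings apart with cos(lat)-scaled in-row steps and
half-step offsets on alternate rows; only the spacing and hexagonal
topology matter for the analysis, and the median neighbour distance is
within 10 % of the target. Two nodes are adjacent iff their
great-circle distance is at most the grid's maximum internode spacing
(1.25 × target — above the neighbour shell at ~1.0–1.09 spacings, below
the second shell at √3 spacings).

For tolerance *p*, the suitable set is land nodes with field value ≥ p
(inclusive), minus route barriers, plus two kinds of zones that ignore
both sea level and climate: the strait exemption (nodes within 40 km of
the Bab al-Mandab centre, southern route only — the strait is assumed
crossable) and the Nile delta (assumed crossable at all times on every
route). Defaults, all configurable because only their intent is
prescribed by the underlying analysis: strait centre (43.4°E, 12.6°N),
delta polygon 30.5–32.5°E × 29.5–31.6°N, Sinai barrier band
32.8–36°E × 28.5–33°N (removed in the southern analysis to block the
northern passage), and the strait exemption disc removed in the
northern analysis to block the southern passage.

An exit is feasible at *p* when the start node (nearest node to 32.6°E,
10.2°N) connects through chains of adjacent suitable nodes to any node
with λ > 65°E or φ > 37°N. The critical tolerance is bisected: starting
from [0, 1000] mm y⁻¹ ([0, 4.0] for aridity), ten halvings give a final
bracket of width 1000/2¹⁰ ≈ 0.98 mm y⁻¹ whose midpoint is reported. If
no path exists even at the lower bound the result carries a NaN
"blocked" sentinel instead of running a meaningless bisection.

The quantity the bisection approximates is exactly the **maximin
(widest-path) bottleneck**: the maximum over start→exit paths of the
minimum node value on the path. `bottleneck_oracle` computes it exactly
by activating nodes in decreasing value order and merging components
with union-find; connectivity at *p* holds iff p ≤ bottleneck, so the
bisection midpoint is always within half the final bracket of the
oracle. Exempt/always-suitable nodes participate with effective value
+∞ (a connection carried entirely by them means a path exists at any
tolerance). Window-of-opportunity tables report, per millennium and
tolerance, the percentage of the 100 decades with a connected path;
they are non-increasing in the tolerance by construction.

## Strait crossing width

Cells of the bathymetry raster strictly above sea level form
8-connected land masses (diagonal contact does not split a mass — the
convention that avoids spurious splits at raster scale). The crossing
width is the minimax-path value between the Africa and Arabia masses
(identified by configurable seed coordinates, defaults near Djibouti
and the Yemen coast) on the complete graph of pairwise minimum
great-circle distances between boundary cells; it is computed by
admitting edges in increasing weight until the two masses connect.
Distances are between cell centres, so every reported width carries an
uncertainty of about one cell size; tests use that tolerance. Widths
are monotone non-increasing as sea level falls, zero once a land bridge
forms, and never increased by adding an island.

## Tolerance thresholds

The threshold statistic is the minimum of the chosen variable over
populations not flagged as freshwater-adjacent — the level below which
no population is recorded. Flagging is an input, not a geospatial
inference, because the excluded populations are identified by prior
knowledge. A percentile parameter (default 0 = minimum) exists as a
robustness knob only. The estimator is invariant to adding records
above the threshold and to adding flagged records anywhere. The
reference values on the real ethnographic data (~90 mm y⁻¹, ~1.7
aridity) are external-data checks; the synthetic population generator
plants exactly these floors by default, with three flagged
freshwater-adjacent populations placed below the floor.

## The synthetic world

`make_world(config, seed)` generates every pipeline input
deterministically from the seed. Climate fields are sums of seeded
band-limited cosine modes (smooth, so interpolation tests are
meaningful); precipitation is clipped at 0. The stylised geography
contains an African and an Arabian land mass separated by a "Red Sea"
strip that ends at a Sinai land bridge in the north and narrows to a
~50 km strait in the south, a Mediterranean, and an Indian Ocean, so
both dispersal routes and their isolation mechanisms are exercised.

Defaults (the study conditions of the desk-scale analysis): 10
millennia of analysis times at 1k-year steps; 9 fine snapshots; 1000
annual fields per millennium; a CO₂ curve oscillating over ~180–280
ppm; a sea-level curve with s(0) = 0 falling to −120 m at the oldest
time; hexagonal spacing 55 km over the full analysis window (~8 900
nodes); planted corridor bottlenecks drawn uniformly from
40–300 mm y⁻¹ over a barrier value of 10 mm y⁻¹; strait bathymetry at
0.01° with a piecewise-linear V cross-section giving a 4 km channel at
the −120 m lowstand and 20 km at present sea level (saddle −130 m) —
the printed widths of the real strait across its sea-level range; a
52-population table with floors 90 mm y⁻¹ / 1.7 and three flagged
populations. Along each planted corridor exactly one node equals the
bottleneck and all off-path nodes are clipped to the barrier, so the
route's maximin value is known exactly; nodes shared by both corridors
take the larger assignment so neither route's bottleneck is disturbed.

What the generator does **not** emulate: real HadCM3 spatial
statistics, actual palaeoclimate magnitudes or teleconnections,
realistic coastline geometry, monthly/seasonal climate, or isostasy.
Passing tests therefore demonstrate the correctness of the *algorithms*
(identities, planted-truth recovery, monotonicity, equivalences), not
the realism of any palaeoclimate reconstruction; headline statements
about the real out-of-Africa record require the real input datasets.

## Numerical conventions and problem sizes

Times are integer ka before present; decade indices run 1–100.
Longitudes are accepted in [−180, 360) and normalised to [0, 360).
Bisection uses exactly 10 iterations; reported critical tolerances are
final-bracket midpoints. The acceptance script runs the
bisection-vs-oracle comparison on 50 seeded random worlds of ~1 200
nodes (a ~40 × 30 window) with 100 decadal fields each — sizes chosen
so the whole script completes in a couple of minutes on one CPU while
still sweeping thousands of independent connectivity problems — and
every other quantity on the full default world.

## Known limitations

- The greedy waypoint walk that builds planted corridors assumes the
  default window and spacing; bespoke grids should supply their own
  node chains to `plant_corridor`.
- The bisection presumes connectivity at the lower bound; fully blocked
  configurations return the sentinel rather than a value.
- IDW infilling extends coastal patterns seaward; it cannot invent
  offshore climate structure.
- The reference time for the second (classical) delta step is the
  present day in both the multiplicative and additive branches; the
  dynamic step alone carries the time-varying reference.
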