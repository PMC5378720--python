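# Methods

This note records the statistical definitions, modelling choices and
numerical conventions behind `retmosaic`, and what the synthetic benchmarks
do and do not establish about real tissue.

## Mosaic statistics

**Nearest-neighbour distances.** Computed with a k-d tree (`k=2` query); an
O(n²) all-pairs computation serves as the oracle in tests. Distances are
reported for every cell. An optional *border buffer* excludes cells closer
than a margin to the window boundary from the summary statistics only (their
distances are still computed against all cells). `border_buffer=True` uses
one CSR mean spacing, `1/(2√ρ)` — the same length scale the dispersion index
normalises by. The buffer is **off by default**: published mosaic analyses of
this kind are typically uncorrected, and at whole-retina n the edge bias is
small. The buffer matters for the CSR anchor checks: in a finite window the
uncorrected NNRI of a random pattern is biased (≈1.89 at n = 2000 in a unit
square, versus the analytic 1.9131), and buffering one mean spacing removes
essentially all of it.

**Voronoi domains.** The tessellation comes from GEOS
(`shapely.voronoi_polygons`), each cell's polygon clipped to the analysis
window; clipped areas tile the window to machine precision (asserted at
1e-6 relative in tests, observed exact). Domains touching the boundary are
flagged. They are *included* in VDRI by default — whether published VDRI
values excluded boundary domains is generally unstated, so the choice is
exposed (`exclude_boundary=True`) and logged rather than hidden. A
quasi-Monte-Carlo nearest-site integration (Sobol, 2²⁰–2²¹ points) is the
independent oracle: plain Monte Carlo at 10⁶ points has ≈0.7% per-cell
standard error, too coarse for the 0.5% oracle tolerance, while scrambled
Sobol reaches ≈0.1%.

**Regularity and dispersion indices.** RI = mean/SD with the sample SD
(n−1 denominator) everywhere, the convention of the retinal-mosaic
literature. DI = observed mean NND divided by the Clark–Evans CSR
expectation `1/(2√ρ)` with ρ the full-window density n/|W|. Closed-form
anchors used in tests: CSR NNRI = √(π/(4−π)) ≈ 1.9131 (mean and variance of
the CSR nearest-neighbour distribution), CSR DI = 1, hexagonal-lattice
DI = 2√(2/√3) ≈ 2.1491.

**Gaussian histogram fits.** Freedman–Diaconis binning by default
(configurable; the choice is not standardised in the literature),
least-squares fit of `a·exp(−(x−µ)²/2σ²)` to bin counts at bin centres,
initialised from the sample mean/SD/peak count, σ bounded positive. R² is
computed on the binned counts. Degenerate histograms (zero variance, <3
occupied bins) and non-convergence return the raw histogram with a
`failed` flag instead of raising.

**Random-pattern null.** The null is the *density-matched* uniform pattern:
exactly the observed n placed uniformly in the same window. The phrase "same
density and SD" sometimes attached to such nulls is redundant for a
homogeneous random pattern — its NND SD is a function of density alone — so
only the density-matched null is modelled. Envelopes are the central 95%
quantiles over `n_reps` (default 99) replicates; the observed statistic is
also located as a percentile of the null sample.

## Morphometry

All metrics use the planar (x, y) projection, matching camera-lucida
digitisation; axon nodes are excluded throughout.

- **Soma size**: equivalent diameter `2√(A/π)` of the measured cross-section.
- **Dendritic field**: area of the convex hull of all dendrite nodes,
  reported in mm² (coordinates are µm). Fewer than three non-collinear
  dendrite nodes is a degenerate field, flagged rather than fatal in batch
  runs.
- **Branch points**: dendritic nodes with ≥2 dendritic children. A
  trifurcation is one branch point. The soma is never a branch point;
  counting the soma once when ≥2 primaries leave it is available as
  `include_primary_origins=True` because tracing softwares differ on this
  convention. For strictly bifurcating trees, tips − branch points = number
  of primary dendrites.
- **Sholl profile**: circles at radii step, 2·step, … about the soma
  centroid (default step 10 µm, configurable and logged — the convention is
  rarely printed). A crossing is a *transversal* circle–segment
  intersection: the count per edge equals the number of sign changes of
  (distance to soma − r) along the edge, so an edge that dips inside a
  circle and exits again counts twice, and tangencies — including an
  endpoint lying exactly on a circle — count zero. This definition agrees
  exactly with a dense arc-sampling oracle, which endpoint-only conventions
  do not.
- **Sholl area**: trapezoidal area under the profile divided by the step.
  The units are summed crossings per circle (a constant profile of c
  crossings over k radii gives c·(k−1)), which reproduces the magnitudes
  conventionally reported as "arbitrary units" at 10 µm steps. The value
  scales as 1/step by construction; the step-stable quantity is
  sholl_area·step, and Sholl areas should only be compared at a common step.

## Synthetic data

The generator's role is to emulate the study conditions of a human mRGC
aging dataset closely enough that every pipeline stage is exercised with
known ground truth.

**Mosaics.** Three models: homogeneous random (optionally conditioned on
exact n, which is how nulls are matched to an observed mosaic); *soft dmin* —
sequential placement where each candidate draws its own exclusion radius
from Normal(dmin_mean, dmin_sd) truncated at zero and is rejected if any
accepted cell is closer, the classic minimal-distance model of retinal
mosaic simulation, which produces the graded NNRI range (~1.2–2.2 and
beyond) seen across mRGC subtypes; and a jittered hexagonal lattice. The
dmin model refuses specifications beyond 55% of the hexagonal packing bound
and otherwise aborts with the achieved count after a candidate budget of
1000·n (configurable), so infeasible requests fail fast and loudly.

**Trees.** Strictly bifurcating: growth starts from `n_primary` unbranched
primaries (evenly spaced directions with jitter) and repeatedly bifurcates a
uniformly chosen tip until the branch-point target is met exactly, making
tips = primaries + branch points an identity. Segment lengths are truncated
normal; daughter directions deviate ±~26° from the parent, so edges grow
radially outward. After growth the arbor is scaled so its convex-hull area
equals π·field_radius², i.e. `field_radius` is the *equivalent field
radius*; subtype presets invert the published mean dendritic areas through
this definition. Preset per-cell variation: branch targets Poisson around
the subtype mean, field areas normal with 8% CV, soma diameters normal with
5% CV. Primary counts per subtype (M1: 3, M1d: 3, M2: 4, M3: 4) come from
the published tips-minus-branch-points differences. Dendritic strata are
assigned per primary subtree from the subtype's S1 fraction (M1/M1d fully
outer, M2 fully inner, M3 split) and encoded as two fixed z planes (S1 at
30 µm, S5 at 5 µm) in SWC output.

**Aging scenarios.** Cross-sectional: 24 donors aged 10–81 by default, six
per age range, each contributing one mosaic per subtype over a 1 cm² window
and five traced cells per subtype — the sampling depth typical of
post-mortem human studies. Age effects are piecewise-linear multipliers:
density steps down 44% at age 70 (the reported post-70 loss; the smaller,
non-significant mid-life tendency is deliberately not injected, so the
default scenario carries exactly one density effect), and morphology
(field area and branch count; tips and Sholl area follow mechanically)
declines from age 50 to a 40% total deficit by 80 — the onset is as
reported, the magnitude a realistic choice since published figures give
bar heights, not parameters. M1d and M3 mosaics use the dmin model
(exclusion 0.2 of the mean spacing), M1 and M2 are random, mirroring the
reported regular-vs-random dichotomy. Randomness derives per-donor,
per-subtype, per-cell substreams from one root seed by counter
(`SeedSequence`), so adding a donor never perturbs the others.

**What the synthetic benchmarks do not show.** The generator is spatially
homogeneous (no foveal density gradient), its trees are planar with one node
per segment (no tortuosity, no dendritic beads), observation noise on
coordinates is absent, and subtype mosaics are independent. Passing tests
therefore establish the correctness of the *measurements and inference*, not
that real retinas satisfy the generator's assumptions.

## Group statistics

Age bins are half-open — [0,30), [30,50), [50,70), [70,∞) — resolving the
overlap of conventionally printed ranges at 30/50/70 by sending boundary
ages upward. Composition percentages are shares of summed density; reported
integers use half-up rounding, and unrounded values (which sum to exactly
100) are always retained. The two-way ANOVA is an OLS fixed-effects model
`value ~ subtype * age_group` with Type-II sums of squares by default
(robust to mild imbalance; Type-I sequential is available — published
studies rarely state which was used). Empty design cells raise an error
naming the cells; the interaction term requires replicate observations.
Post-hoc comparisons are Tukey–Kramer on the factor level means using the
model residual MSE and the studentized-range distribution; the compact
letter display is built from maximal cliques of the non-significance graph,
guaranteeing two levels share a letter iff their adjusted p ≥ α (0.05 by
default, configurable). The Grubbs screen is the two-sided single-outlier
test with the t-based critical value; it flags at most one observation per
invocation, and iterated re-application is an explicit caller choice.

## Problem sizes in the test suite

The suite's simulation scales were chosen to make every stochastic check
statistically decisive at desk scale: CSR anchors use 100 replicates of
n = 2000 (Monte-Carlo SE of the mean NNRI ≈ 0.003 against a ±0.03 band);
oracle-equivalence checks run 20 seeded instances per primitive; aging
recovery and type-I control each use 20 replicate 24-donor studies; null
envelopes use 99 replicates. The whole suite runs in well under a minute on
one CPU.

## Known limitations

- No Ripley's K / pair-correlation statistics, and no inhomogeneous nulls:
  regularity here is strictly NND/Voronoi-based, as in the study design this
  package supports.
- Coordinates are planar mm (flattened whole mounts); no spherical-eye
  correction.
- Stratification depth within the IPL is categorical (S1/S5), not a measured
  continuous depth.
- `decline_summary` is generic over the metric supplied; whether a published
  "percent lower" figure refers to densities or whole-retina counts is the
  caller's interpretation.
- The Gaussian histogram fit is a least-squares description of a binned
  sample, not a distributional claim; CSR NND distributions are mildly
  skewed and still fit with R² ≈ 0.94 at n = 2000.
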