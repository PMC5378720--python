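# retmosaic

Spatial mosaic regularity and neurite morphometry for melanopsin ganglion
cell (mRGC/ipRGC) aging studies.

Melanopsin-expressing retinal ganglion cells drive circadian photoentrainment
and the pupillary light reflex. In whole-mount human retinas they occur in
four morphological subtypes (M1, displaced M1, M2, M3) at very low densities
(~0.5–2 cells/mm²), arranged in mosaics of varying regularity, and their
density and dendritic complexity decline in old age. `retmosaic` implements
the quantitative desk side of such a study for anyone working from digitized
camera-lucida tracings: cell-coordinate tables and SWC arbors in, regularity
statistics, morphometry and age-group comparisons out — plus a synthetic-data
generator with known ground truth so the whole pipeline is testable without
tissue.

## What it computes

**Mosaic statistics** (`retmosaic.mosaic`). For a labelled point pattern
inside a polygonal window *W*:

- nearest-neighbour distances `NND_i = min_{j≠i} ‖x_i − x_j‖`;
- Voronoi domain areas (clipped to *W*; the clipped areas tile *W* exactly);
- regularity indices `NNRI = mean(NND)/SD(NND)` and `VDRI = mean(VDA)/SD(VDA)`
  (sample SD, *n*−1). A homogeneous random (CSR) pattern has
  `NNRI = √(π/(4−π)) ≈ 1.91`; regular mosaics exceed it;
- the dispersion index `DI = mean(NND) / (1/(2√ρ))`, the Clark–Evans ratio,
  with `ρ = n/|W|`; 1 for random patterns, >1 for regular ones;
- Gaussian least-squares fits to the NND/VDA histograms (R² on binned counts);
- Monte-Carlo comparison against density-matched random patterns (exact same
  *n* in the same window), with null mean, SD, central-95% envelope and the
  observed statistic's percentile.

**Morphometry** (`retmosaic.morphometry`). Per traced cell: soma equivalent
diameter `d = 2√(A/π)`, convex-hull dendritic-field area, branch-point and
terminal-tip counts, and Sholl profiles (transversal crossings of concentric
circles around the soma) with the Sholl area (area under the profile per
step). All metrics work on the planar projection and exclude axon nodes.

**Group analysis** (`retmosaic.groups`). Subtype composition percentages,
donor age-range binning (<30, 30–50, 50–70, >70 years), fixed-effects two-way
ANOVA (subtype × age group, with interaction), Tukey HSD pairs with a compact
letter display, Grubbs single-outlier screening and percent-decline
summaries.

**Synthetic data** (`retmosaic.synthetic`). Homogeneous random, soft-dmin
(per-cell exclusion radius) and jittered-lattice mosaics; strictly
bifurcating dendritic trees with exact branch counts and preset parameters
per mRGC subtype; and full 24-donor cross-sectional aging datasets with
injected density/morphology decline curves and retained ground truth.

## Worked example

Simulate a regular M1d-like mosaic at its typical density and test it
against the density-matched random null:

```python
import numpy as np
from retmosaic import RegionPolygon, MosaicSpec, generate_dmin_mosaic, mosaic_stats

region = RegionPolygon.rectangle(10, 10)        # 1 cm^2 analysis window (mm)
spacing = 1 / np.sqrt(2.05)                     # mean spacing at 2.05 cells/mm^2
spec = MosaicSpec(region=region, density=2.05, model="dmin",
                  dmin_mean=0.4 * spacing, dmin_sd=0.08 * spacing, seed=1)
mosaic = generate_dmin_mosaic(spec, subtype="M1d")
stats = mosaic_stats(mosaic, null_reps=99, seed=2)

print(f"n = {stats.n} cells, density = {stats.density:.2f} cells/mm^2")
print(f"mean NND = {stats.nnd.mean:.3f} mm, SD = {stats.nnd.sd:.3f} mm")
print(f"NNRI = {stats.nnri:.2f}   VDRI = {stats.vdri:.2f}   DI = {stats.di:.2f}")
null = stats.null
print(f"random-null NNRI = {null.null_mean['nnri']:.2f} "
      f"(95% envelope [{null.null_lo95['nnri']:.2f}, {null.null_hi95['nnri']:.2f}])")
```

which prints:

```
n = 205 cells, density = 2.05 cells/mm^2
mean NND = 0.446 mm, SD = 0.123 mm
NNRI = 3.63   VDRI = 2.33   DI = 1.28
random-null NNRI = 1.86 (95% envelope [1.66, 2.18])
```

Read: the exclusion-built mosaic is far more regular than chance — its NNRI
of 3.63 lies well above the 95% envelope of density-matched random patterns,
whose own NNRI sits near the theoretical 1.91 (here 1.86 at this modest
*n* without edge correction). The DI of 1.28 says neighbours sit 28% farther
apart than the Clark–Evans expectation for a random pattern of this density.

## Command line

```bash
retmosaic simulate mosaic --density 2.05 --model dmin --out-dir out/sim --seed 1
retmosaic mosaic-stats --cells out/sim/cells.csv --region out/sim/region.csv \
    --null-reps 99 --seed 2 --out-dir out/stats
retmosaic simulate tree --subtype M1d --n-trees 5 --out-dir out/trees
retmosaic morpho --swc-dir out/trees --out out/morpho.csv
retmosaic pipeline --out-dir out/study --seed 0     # full aging study, defaults
```

Every run writes a `provenance.json` (config echo, seed, library versions,
timestamp); identical config + seed reproduce statistic tables byte for byte.

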