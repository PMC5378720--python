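"""Published anchor values for human melanopsin-expressing retinal ganglion cells.

These constants summarise the morphometric and mosaic-regularity literature on
human mRGC subtypes (M1, displaced M1, M2, M3).  They serve two purposes:

* defaults for the synthetic-data generator presets, so simulated mosaics and
  dendritic trees land on realistic magnitudes, and
* independent anchors for tests (e.g. the Clark–Evans regularity index of a
  complete-spatial-randomness pattern).

Units are stated per constant.  Soma sizes are equivalent diameters (diameter
of the circle with the same area as the traced soma cross-section).
"""

from __future__ import annotations

import math

SUBTYPES: tuple[str, ...] = ("M1", "M1d", "M2", "M3")
LAYERS: tuple[str, ...] = ("GCL", "INL")
STRATA: tuple[str, ...] = ("S1", "S5")

#: Soma layer per subtype: displaced M1 cells sit in the inner nuclear layer.
SOMA_LAYER: dict[str, str] = {"M1": "GCL", "M1d": "INL", "M2": "GCL", "M3": "GCL"}

#: Fraction of the dendritic arbor stratifying in the outer IPL stratum S1
#: (remainder in S5).  M1/M1d are outer-monostratified, M2 inner, M3 bistratified.
STRATUM_MIX: dict[str, float] = {"M1": 1.0, "M1d": 1.0, "M2": 0.0, "M3": 0.5}

# --- mosaic regularity anchors -------------------------------------------------

#: Regularity index (mean/SD of nearest-neighbour distance) of a homogeneous
#: random pattern, as conventionally cited in the retinal-mosaic literature.
CSR_NNRI_LITERATURE = 1.91

#: The same quantity in closed form: for complete spatial randomness the NND is
#: Rayleigh-like with mean 1/(2*sqrt(rho)) and variance (4-pi)/(4*pi*rho), so
#: RI = sqrt(pi / (4 - pi)).
CSR_NNRI_ANALYTIC = math.sqrt(math.pi / (4.0 - math.pi))

#: Dispersion index (observed mean NND over the Clark–Evans CSR expectation)
#: of a random pattern.
CSR_DI = 1.0

# --- densities and counts (superior-nasal sampling region, adult human) --------

#: Mean density per subtype, cells/mm^2.
MEAN_DENSITY_MM2: dict[str, float] = {"M1": 0.51, "M1d": 2.05, "M2": 0.65, "M3": 0.97}

#: Cell counts per subtype over one entire flat-mounted retina.
WHOLE_RETINA_COUNTS: dict[str, int] = {"M1": 988, "M1d": 1874, "M2": 802, "M3": 1036}
WHOLE_RETINA_TOTAL = 4700
WHOLE_RETINA_MEAN_DENSITY_MM2 = 4.77

#: Whole-retina mosaic statistics, all subtypes pooled.
WHOLE_RETINA_NNRI = 2.03
WHOLE_RETINA_VDRI = 1.24
WHOLE_RETINA_DI = 1.68

#: Per-subtype whole-retina regularity and dispersion indices.
SUBTYPE_NNRI: dict[str, float] = {"M1": 1.49, "M1d": 2.01, "M2": 1.58, "M3": 1.93}
SUBTYPE_DI: dict[str, float] = {"M1": 1.22, "M1d": 1.70, "M2": 1.28, "M3": 1.59}

# --- per-cell morphometry (means over 40-45 traced cells per subtype) ----------

SOMA_DIAMETER_UM: dict[str, float] = {"M1": 19.99, "M1d": 19.92, "M2": 20.82, "M3": 20.22}
DENDRITIC_AREA_MM2: dict[str, float] = {"M1": 0.47, "M1d": 0.54, "M2": 0.43, "M3": 0.44}
BRANCH_POINTS: dict[str, float] = {"M1": 18.43, "M1d": 21.57, "M2": 17.24, "M3": 14.58}
TERMINAL_TIPS: dict[str, float] = {"M1": 21.44, "M1d": 24.75, "M2": 21.59, "M3": 18.28}
SHOLL_AREA: dict[str, float] = {"M1": 180.7, "M1d": 211.1, "M2": 179.0, "M3": 146.7}

#: Primary dendrites per subtype, derived from the tips = primaries + branch
#: points identity of strictly bifurcating trees applied to the printed means.
N_PRIMARY: dict[str, int] = {"M1": 3, "M1d": 3, "M2": 4, "M3": 4}

# --- aging ---------------------------------------------------------------------

#: Fractional drop in mRGC density after age 70 relative to young retinas.
DENSITY_DROP_AFTER_70 = 0.44
DENSITY_DECLINE_ONSET_AGE = 70.0
#: Dendritic atrophy (area, branch points, tips, Sholl area) begins around 50.
MORPHO_DECLINE_ONSET_AGE = 50.0
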