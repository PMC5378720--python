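"""Synthetic mosaics, dendritic trees and multi-donor aging datasets.

Every pipeline stage in this package is exercised on data from this module:
point patterns with known regularity (homogeneous random, soft-dmin exclusion,
jittered lattice), strictly bifurcating dendritic trees with exact branch
counts, and full cross-sectional aging studies with injected density and
morphology decline curves whose ground truth is retained for recovery tests.

Randomness: every generator takes one seed; the aging-study generator derives
independent per-donor / per-subtype / per-cell substreams from its root seed
by counter (``numpy.random.SeedSequence``), so adding a donor never perturbs
the data of the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from .errors import InvalidSpecError, SimulationFailureError
from .morphometry import S1_Z_UM, S5_Z_UM, NeuriteTree, morphometry_batch
from .mosaic import CellMosaic, nearest_neighbor_distances, regularity_index, voronoi_domain_areas
from .reference import (
    BRANCH_POINTS,
    DENDRITIC_AREA_MM2,
    DENSITY_DROP_AFTER_70,
    MEAN_DENSITY_MM2,
    N_PRIMARY,
    SOMA_DIAMETER_UM,
    SOMA_LAYER,
    STRATUM_MIX,
    SUBTYPES,
)
from .region import RegionPolygon, sample_uniform_in_region

__all__ = [
    "MosaicSpec",
    "TreeSpec",
    "DeclineCurve",
    "AgingScenario",
    "AgingDataset",
    "DEFAULT_DONOR_AGES",
    "generate_poisson_mosaic",
    "generate_dmin_mosaic",
    "generate_jittered_lattice_mosaic",
    "generate_mosaic",
    "generate_tree",
    "tree_spec_for_subtype",
    "generate_aging_dataset",
]

MOSAIC_MODELS = ("poisson", "dmin", "jittered_lattice")


def _child_seed(root: int, *key: int) -> int:
    """A deterministic 31-bit substream seed derived by counter."""
    state = np.random.SeedSequence((int(root),) + tuple(int(k) for k in key)).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# mosaic generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MosaicSpec:
    """Specification of one simulated mosaic.

    density is in cells/mm²; ``exact_n`` fixes the count at round(density*area)
    instead of drawing it Poisson, which is how density-matched null patterns
    are conditioned.  For the soft-exclusion model, each placed cell draws its
    own exclusion radius from Normal(dmin_mean, dmin_sd) truncated at zero.
    """

    region: RegionPolygon
    density: float
    model: str = "poisson"
    dmin_mean: float = 0.0
    dmin_sd: float = 0.0
    jitter_sd: float | None = None
    exact_n: bool = False
    rejection_budget_factor: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.density < 0 or not np.isfinite(self.density):
            raise InvalidSpecError("density must be non-negative and finite")
        if self.model not in MOSAIC_MODELS:
            raise InvalidSpecError(f"unknown mosaic model {self.model!r}; choose from {MOSAIC_MODELS}")
        if self.dmin_mean < 0 or self.dmin_sd < 0:
            raise InvalidSpecError("dmin_mean and dmin_sd must be non-negative")
        if self.rejection_budget_factor < 1:
            raise InvalidSpecError("rejection_budget_factor must be >= 1")
        if self.model == "dmin" and self.dmin_mean > 0:
            # packing feasibility: hexagonal-lattice bound on centres >= dmin apart,
            # kept well below the random-sequential-adsorption jamming limit
            n_target = self.density * self.region.area
            n_max = 2.0 * self.region.area / (math.sqrt(3.0) * self.dmin_mean**2)
            if n_target > 0.55 * n_max:
                raise InvalidSpecError(
                    f"dmin packing infeasible: target n={n_target:.0f} exceeds "
                    f"55% of the hexagonal bound {n_max:.0f} for dmin_mean={self.dmin_mean}"
                )

    def target_n(self, rng: np.random.Generator) -> int:
        lam = self.density * self.region.area
        return int(round(lam)) if self.exact_n else int(rng.poisson(lam))


def _as_mosaic(points, spec, subtype, donor_id, donor_age) -> CellMosaic:
    n = len(points)
    st = layer = None
    if subtype is not None:
        if subtype not in SUBTYPES:
            raise InvalidSpecError(f"unknown subtype {subtype!r}")
        st = np.full(n, subtype, dtype=object)
        layer = np.full(n, SOMA_LAYER[subtype], dtype=object)
    return CellMosaic(points, spec.region, subtype=st, layer=layer,
                      donor_id=donor_id, donor_age=donor_age)


def generate_poisson_mosaic(spec: MosaicSpec, subtype=None, donor_id=None, donor_age=None) -> CellMosaic:
    """A homogeneous random (CSR) mosaic — the density-matched null model."""
    if spec.model != "poisson":
        raise InvalidSpecError(f"spec.model is {spec.model!r}, expected 'poisson'")
    rng = np.random.default_rng(spec.seed)
    n = spec.target_n(rng)
    points = sample_uniform_in_region(spec.region, n, rng)
    return _as_mosaic(points, spec, subtype, donor_id, donor_age)


def generate_dmin_mosaic(spec: MosaicSpec, subtype=None, donor_id=None, donor_age=None) -> CellMosaic:
    """A soft-exclusion ("dmin") mosaic: sequential placement with per-point
    exclusion radii drawn Normal(dmin_mean, dmin_sd) truncated at zero.

    Gives the graded regularity of real retinal mosaics; degenerates to CSR
    when dmin_mean = dmin_sd = 0.  Placement stops at the target count or
    raises :class:`SimulationFailureError` (naming the achieved count) once a
    rejection budget of 1000*n candidates is exhausted.
    """
    if spec.model != "dmin":
        raise InvalidSpecError(f"spec.model is {spec.model!r}, expected 'dmin'")
    rng = np.random.default_rng(spec.seed)
    n = spec.target_n(rng)
    if n == 0:
        return _as_mosaic(np.empty((0, 2)), spec, subtype, donor_id, donor_age)
    x0, y0, x1, y1 = spec.region.bounds
    accepted = np.empty((n, 2))
    k = 0
    budget = spec.rejection_budget_factor * n
    attempts = 0
    while k < n:
        if attempts >= budget:
            raise SimulationFailureError(
                f"dmin placement exhausted {budget} candidates; achieved n={k} of {n}",
                achieved_n=k,
            )
        attempts += 1
        cand = rng.random(2) * (x1 - x0, y1 - y0) + (x0, y0)
        if not spec.region.contains_points(cand[None, :])[0]:
            continue
        r_excl = max(0.0, rng.normal(spec.dmin_mean, spec.dmin_sd))
        if k:
            d2 = ((accepted[:k] - cand) ** 2).sum(axis=1)
            if (d2 <= r_excl**2).any():
                continue
        accepted[k] = cand
        k += 1
    return _as_mosaic(accepted, spec, subtype, donor_id, donor_age)


def generate_jittered_lattice_mosaic(spec: MosaicSpec, subtype=None, donor_id=None, donor_age=None) -> CellMosaic:
    """A hexagonal lattice at the requested density with Gaussian jitter.

    Jitter SD defaults to 15% of the lattice spacing; points jittered outside
    the region are dropped, so the achieved density fluctuates slightly.
    """
    if spec.model != "jittered_lattice":
        raise InvalidSpecError(f"spec.model is {spec.model!r}, expected 'jittered_lattice'")
    rng = np.random.default_rng(spec.seed)
    if spec.density == 0:
        return _as_mosaic(np.empty((0, 2)), spec, subtype, donor_id, donor_age)
    s = math.sqrt(2.0 / (math.sqrt(3.0) * spec.density))
    x0, y0, x1, y1 = spec.region.bounds
    rows = np.arange(y0 - s, y1 + s, s * math.sqrt(3.0) / 2.0)
    pts = []
    for j, y in enumerate(rows):
        xs = np.arange(x0 - s, x1 + s, s) + (0.5 * s if j % 2 else 0.0)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    pts = np.vstack(pts)
    pts = pts + rng.normal(0.0, spec.jitter_sd if spec.jitter_sd is not None else 0.15 * s,
                           size=pts.shape)
    pts = pts[spec.region.contains_points(pts)]
    return _as_mosaic(pts, spec, subtype, donor_id, donor_age)


_GENERATORS = {
    "poisson": generate_poisson_mosaic,
    "dmin": generate_dmin_mosaic,
    "jittered_lattice": generate_jittered_lattice_mosaic,
}


def generate_mosaic(spec: MosaicSpec, **kwargs) -> CellMosaic:
    """Dispatch on ``spec.model``."""
    return _GENERATORS[spec.model](spec, **kwargs)


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeSpec:
    """Specification of one simulated dendritic tree.

    The tree is strictly bifurcating: growth starts from ``n_primary``
    unbranched primary dendrites and bifurcates a uniformly chosen tip until
    exactly ``target_branch_points`` branch points exist, so terminal tips
    always equal n_primary + target_branch_points.  ``field_radius`` (µm) is
    the equivalent radius of the dendritic field: after growth the arbor is
    scaled so its convex-hull area equals pi*field_radius².  ``stratum_mix``
    is the fraction of primary subtrees stratifying in S1 (the rest in S5).
    """

    n_primary: int = 3
    target_branch_points: int = 20
    segment_length_mean: float = 60.0
    segment_length_sd: float = 15.0
    field_radius: float = 400.0
    stratum_mix: float = 1.0
    soma_area: float = 314.16
    seed: int = 0

    def __post_init__(self):
        if self.n_primary < 1:
            raise InvalidSpecError("n_primary must be >= 1")
        if self.target_branch_points < 0:
            raise InvalidSpecError("target_branch_points must be >= 0")
        if not (0.0 <= self.stratum_mix <= 1.0):
            raise InvalidSpecError("stratum_mix must be in [0, 1]")
        if self.field_radius <= 0:
            raise InvalidSpecError("field_radius must be positive")
        if self.segment_length_mean <= 0 or self.segment_length_sd < 0:
            raise InvalidSpecError("segment lengths must be positive (sd non-negative)")
        if self.soma_area <= 0:
            raise InvalidSpecError("soma_area must be positive")


def generate_tree(spec: TreeSpec, cell_id=None, subtype=None, donor_id=None, age_years=None) -> NeuriteTree:
    """Grow one strictly bifurcating dendritic tree from a soma at the origin."""
    rng = np.random.default_rng(spec.seed)
    seg = lambda: max(rng.normal(spec.segment_length_mean, spec.segment_length_sd),
                      0.1 * spec.segment_length_mean)

    # node store; index 0 is the soma
    parent = [-1]
    theta = [0.0]
    pos = [np.zeros(2)]
    depth = [0]
    strat = [None]

    n_s1 = int(round(spec.stratum_mix * spec.n_primary))
    tips: list[int] = []
    base = rng.uniform(0.0, 2.0 * math.pi)
    for k in range(spec.n_primary):
        ang = base + 2.0 * math.pi * k / spec.n_primary + rng.uniform(-0.25, 0.25)
        parent.append(0)
        theta.append(ang)
        length = seg()
        pos.append(pos[0] + length * np.array([math.cos(ang), math.sin(ang)]))
        depth.append(1)
        strat.append("S1" if k < n_s1 else "S5")
        tips.append(len(parent) - 1)

    for _ in range(spec.target_branch_points):
        t = tips.pop(int(rng.integers(len(tips))))
        turn = abs(rng.normal(0.45, 0.12))
        for sign in (+1.0, -1.0):
            ang = theta[t] + sign * turn + rng.normal(0.0, 0.05)
            parent.append(t)
            theta.append(ang)
            length = seg()
            pos.append(pos[t] + length * np.array([math.cos(ang), math.sin(ang)]))
            depth.append(depth[t] + 1)
            strat.append(strat[t])
            tips.append(len(parent) - 1)

    pos = np.asarray(pos)
    # scale the arbor so the convex-hull area matches pi*field_radius^2
    dend = pos[1:]
    if len(dend) >= 3:
        from scipy.spatial import ConvexHull

        spread = dend - dend.mean(axis=0)
        if np.linalg.matrix_rank(spread, tol=1e-9) == 2:
            hull_area = ConvexHull(dend).volume
            if hull_area > 0:
                pos = pos * math.sqrt(math.pi * spec.field_radius**2 / hull_area)

    n = len(parent)
    z = np.zeros(n)
    for k in range(1, n):
        z[k] = S1_Z_UM if strat[k] == "S1" else S5_Z_UM
    radius = np.empty(n)
    radius[0] = math.sqrt(spec.soma_area / math.pi)
    for k in range(1, n):
        radius[k] = max(1.0 * 0.85 ** (depth[k] - 1), 0.3)
    compartment = np.array(["soma"] + ["dendrite"] * (n - 1), dtype=object)
    ids = np.arange(1, n + 1)
    parents = np.array([-1] + [int(p) + 1 for p in parent[1:]])
    return NeuriteTree(
        ids=ids, parents=parents, xyz=np.column_stack([pos, z]), radius=radius,
        compartment=compartment, stratum=np.array(strat, dtype=object),
        soma_area=spec.soma_area, cell_id=cell_id, subtype=subtype,
        donor_id=donor_id, age_years=age_years,
    )


def tree_spec_for_subtype(
    subtype: str,
    seed: int,
    area_multiplier: float = 1.0,
    branch_multiplier: float = 1.0,
) -> TreeSpec:
    """A randomised per-cell tree specification from the subtype presets.

    Branch-point targets are drawn Poisson around the subtype mean, the
    dendritic-field area Normal with 8% coefficient of variation, and the soma
    diameter Normal with 5% CV, so populations of preset trees reproduce the
    subtype means with realistic cell-to-cell spread.  The multipliers rescale
    the field-area and branch-count means (used by the aging scenario).
    """
    if subtype not in SUBTYPES:
        raise InvalidSpecError(f"unknown subtype {subtype!r}")
    rng = np.random.default_rng(seed)
    target = int(rng.poisson(max(BRANCH_POINTS[subtype] * branch_multiplier, 0.0)))
    area_mean = DENDRITIC_AREA_MM2[subtype] * 1e6 * area_multiplier  # µm²
    area = max(rng.normal(area_mean, 0.08 * area_mean), 0.2 * area_mean)
    diam = max(rng.normal(SOMA_DIAMETER_UM[subtype], 0.05 * SOMA_DIAMETER_UM[subtype]), 5.0)
    return TreeSpec(
        n_primary=N_PRIMARY[subtype],
        target_branch_points=target,
        segment_length_mean=60.0,
        segment_length_sd=15.0,
        field_radius=math.sqrt(area / math.pi),
        stratum_mix=STRATUM_MIX[subtype],
        soma_area=math.pi * (diam / 2.0) ** 2,
        seed=_child_seed(seed, 1),
    )


# ---------------------------------------------------------------------------
# aging scenario
# ---------------------------------------------------------------------------

#: 24 donors, six per age range, spanning ages 10-81.
DEFAULT_DONOR_AGES: tuple[float, ...] = (
    10, 14, 18, 22, 26, 29,
    32, 36, 40, 43, 46, 49,
    52, 56, 60, 63, 66, 69,
    71, 73, 75, 77, 79, 81,
)


@dataclass(frozen=True)
class DeclineCurve:
    """A piecewise-linear age-decline multiplier.

    The multiplier is 1 up to ``onset_age``; with ``end_age`` set it falls
    linearly to ``1 - fraction`` at end_age and stays there (a progressive
    decline); without, it steps down at the onset.
    """

    onset_age: float
    fraction: float
    end_age: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0):
            raise InvalidSpecError("decline fraction must be in [0, 1]")
        if self.end_age is not None and self.end_age <= self.onset_age:
            raise InvalidSpecError("end_age must exceed onset_age")

    def multiplier(self, age: float) -> float:
        if age <= self.onset_age:
            return 1.0
        if self.end_age is None or age >= self.end_age:
            return 1.0 - self.fraction
        t = (age - self.onset_age) / (self.end_age - self.onset_age)
        return 1.0 - t * self.fraction


def _default_region() -> RegionPolygon:
    return RegionPolygon.rectangle(10.0, 10.0)  # 1 cm² sampling window


def _default_morpho_decline() -> dict:
    curve = DeclineCurve(onset_age=50.0, fraction=0.40, end_age=80.0)
    return {"dendritic_area": curve, "branch_points": curve}


@dataclass(frozen=True)
class AgingScenario:
    """A cross-sectional aging study design with known ground truth.

    Defaults emulate the human mRGC aging literature: 24 donors aged 10-81
    (six per age range), subtype baseline densities over a 1 cm²
    superior-nasal window, a 44% density drop after age 70, and progressive
    dendritic atrophy from age 50.  M1d and M3 mosaics are regular
    (soft-dmin); M1 and M2 are random, matching their reported arrangement.
    """

    ages: tuple[float, ...] = DEFAULT_DONOR_AGES
    region: RegionPolygon = dataclass_field(default_factory=_default_region)
    baseline_density: dict = dataclass_field(default_factory=lambda: dict(MEAN_DENSITY_MM2))
    density_decline: DeclineCurve = DeclineCurve(onset_age=70.0, fraction=DENSITY_DROP_AFTER_70)
    morpho_decline: dict = dataclass_field(default_factory=_default_morpho_decline)
    mosaic_model: dict = dataclass_field(
        default_factory=lambda: {"M1": "poisson", "M1d": "dmin", "M2": "poisson", "M3": "dmin"}
    )
    dmin_fraction: float = 0.2
    dmin_sd_fraction: float = 0.04
    cells_per_subtype: int = 5
    seed: int = 0

    def __post_init__(self):
        for a in self.ages:
            if not (0.0 <= a <= 120.0):
                raise InvalidSpecError(f"donor age {a} outside [0, 120]")
        for st in self.baseline_density:
            if st not in SUBTYPES:
                raise InvalidSpecError(f"unknown subtype {st!r} in baseline_density")
            if self.baseline_density[st] < 0:
                raise InvalidSpecError("baseline densities must be non-negative")


@dataclass
class AgingDataset:
    """Output bundle of :func:`generate_aging_dataset`."""

    scenario: AgingScenario
    study_table: pd.DataFrame
    mosaics: dict
    trees: dict
    ground_truth: pd.DataFrame


def generate_aging_dataset(
    scenario: AgingScenario,
    include_trees: bool = True,
    include_spatial: bool = False,
) -> AgingDataset:
    """Simulate one full aging study.

    Produces, per donor and subtype, a mosaic at the scenario's age-dependent
    density and (optionally) ``cells_per_subtype`` traced trees at the
    age-dependent morphology, then assembles the long-format study table of
    per-donor per-subtype metrics.  ``include_spatial`` adds NNRI/VDRI/DI rows
    for mosaics with at least 10 cells.
    """
    from .groups import assign_age_group  # local import to avoid a cycle

    rows = []
    truth_rows = []
    mosaics: dict[str, CellMosaic] = {}
    trees: dict[tuple[str, str], list[NeuriteTree]] = {}
    area = scenario.region.area
    for i, age in enumerate(scenario.ages):
        donor_id = f"donor{i:02d}"
        group = assign_age_group(age)
        pts, sts, lays = [], [], []
        for j, st in enumerate(SUBTYPES):
            base = scenario.baseline_density.get(st, 0.0)
            dens_curve = scenario.density_decline
            density = base * dens_curve.multiplier(age)
            model = scenario.mosaic_model.get(st, "poisson")
            spacing = 1.0 / math.sqrt(density) if density > 0 else 0.0
            spec = MosaicSpec(
                region=scenario.region, density=density, model=model,
                dmin_mean=scenario.dmin_fraction * spacing,
                dmin_sd=scenario.dmin_sd_fraction * spacing,
                seed=_child_seed(scenario.seed, i, j, 0),
            )
            sub = generate_mosaic(spec, subtype=st, donor_id=donor_id, donor_age=age)
            pts.append(sub.points)
            sts.append(sub.subtype)
            lays.append(sub.layer)

            def add(metric, value, n_cells):
                rows.append(dict(donor_id=donor_id, age_years=age, age_group=group,
                                 subtype=st, metric=metric, value=value, n_cells=n_cells))

            add("density_cells_per_mm2", sub.n / area, sub.n)
            if include_spatial and sub.n >= 10:
                nnd = nearest_neighbor_distances(sub)
                d = nnd.distances
                add("nnri", float(d.mean() / d.std(ddof=1)), sub.n)
                add("di", float(d.mean() * 2.0 * math.sqrt(sub.density)), sub.n)
                vda = voronoi_domain_areas(sub)
                add("vdri", regularity_index(vda.areas), sub.n)

            area_mult = scenario.morpho_decline["dendritic_area"].multiplier(age)
            branch_mult = scenario.morpho_decline["branch_points"].multiplier(age)
            truth_rows.append(dict(donor_id=donor_id, age_years=age, age_group=group,
                                   subtype=st, expected_density=density,
                                   area_multiplier=area_mult, branch_multiplier=branch_mult))
            if include_trees:
                cell_trees = [
                    generate_tree(
                        tree_spec_for_subtype(
                            st, seed=_child_seed(scenario.seed, i, j, 1, k),
                            area_multiplier=area_mult, branch_multiplier=branch_mult,
                        ),
                        cell_id=f"{donor_id}_{st}_{k}", subtype=st,
                        donor_id=donor_id, age_years=age,
                    )
                    for k in range(scenario.cells_per_subtype)
                ]
                trees[(donor_id, st)] = cell_trees
                morpho = morphometry_batch(cell_trees)
                n_cells = len(morpho)
                add("soma_equiv_diameter", float(morpho["soma_equiv_diameter_um"].mean()), n_cells)
                add("dendritic_area", float(morpho["dendritic_area_mm2"].mean()), n_cells)
                add("branch_points", float(morpho["branch_points"].mean()), n_cells)
                add("terminal_tips", float(morpho["terminal_tips"].mean()), n_cells)
                add("sholl_area", float(morpho["sholl_area"].mean()), n_cells)
        mosaics[donor_id] = CellMosaic(
            np.vstack(pts), scenario.region,
            subtype=np.concatenate(sts), layer=np.concatenate(lays),
            donor_id=donor_id, donor_age=age,
        )
    return AgingDataset(
        scenario=scenario,
        study_table=pd.DataFrame(rows),
        mosaics=mosaics,
        trees=trees,
        ground_truth=pd.DataFrame(truth_rows),
    )
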