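"""Two-dimensional mosaic statistics: NND, Voronoi domains, regularity indices.

The workhorse quantities of retinal-mosaic analysis:

* **NND** — each cell's Euclidean distance to its nearest neighbour, obtained
  from the Delaunay/k-d structure of the point pattern.
* **VDA** — each cell's Voronoi domain area, i.e. the area of the retinal
  plane closer to that cell than to any other, clipped to the analysis region.
* **Regularity index** (NNRI / VDRI) — sample mean over sample SD (ddof=1) of
  NND or VDA.  A homogeneous random (CSR) pattern has NNRI
  sqrt(pi/(4-pi)) ~ 1.91; regular mosaics exceed it.
* **Dispersion index** (DI) — observed mean NND divided by the Clark–Evans
  CSR expectation 1/(2*sqrt(rho)); 1 for random, >1 for regular patterns.
* Gaussian histogram fits of the NND/VDA distributions, and a Monte-Carlo
  comparison against density-matched random patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import optimize
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from .errors import (
    DegenerateGeometryError,
    InsufficientPointsError,
    InvalidSpecError,
    UndefinedStatisticError,
)
from .reference import LAYERS, SUBTYPES
from .region import RegionPolygon, sample_uniform_in_region

__all__ = [
    "CellMosaic",
    "NNDSample",
    "VDASample",
    "GaussianFit",
    "NullComparison",
    "MosaicStatsResult",
    "nearest_neighbor_distances",
    "voronoi_domain_areas",
    "regularity_index",
    "dispersion_index",
    "fit_gaussian",
    "null_comparison",
    "mosaic_stats",
    "per_subtype_stats",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class CellMosaic:
    """A labelled 2-D point pattern inside a polygonal region.

    Parameters
    ----------
    points : (n, 2) array, mm
    region : RegionPolygon
    subtype, layer : optional per-cell label arrays (closed vocabularies
        M1/M1d/M2/M3 and GCL/INL).
    donor_age : optional donor age in years.
    """

    __slots__ = ("points", "region", "subtype", "layer", "donor_id", "donor_age", "cell_ids")

    def __init__(
        self,
        points,
        region: RegionPolygon,
        subtype=None,
        layer=None,
        donor_id: str | None = None,
        donor_age: float | None = None,
        cell_ids=None,
        validate: bool = True,
    ):
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        self.points = points
        self.region = region
        self.subtype = None if subtype is None else np.asarray(subtype, dtype=object)
        self.layer = None if layer is None else np.asarray(layer, dtype=object)
        self.donor_id = donor_id
        self.donor_age = donor_age
        self.cell_ids = (
            np.arange(len(points)) if cell_ids is None else np.asarray(cell_ids)
        )
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = len(self.points)
        if not np.isfinite(self.points).all():
            raise InvalidSpecError("mosaic coordinates must be finite")
        inside = self.region.contains_points(self.points)
        if not inside.all():
            bad = np.flatnonzero(~inside)[:10].tolist()
            raise InvalidSpecError(f"{(~inside).sum()} point(s) outside region, rows {bad}")
        if n >= 2:
            d, _ = cKDTree(self.points).query(self.points, k=2)
            if (d[:, 1] <= 0).any():
                bad = np.flatnonzero(d[:, 1] <= 0)[:10].tolist()
                raise InvalidSpecError(
                    f"duplicate coordinates (zero pairwise distance) at rows {bad}"
                )
        for name, arr, vocab in (("subtype", self.subtype, SUBTYPES), ("layer", self.layer, LAYERS)):
            if arr is not None:
                if len(arr) != n:
                    raise InvalidSpecError(f"{name} labels must match point count")
                unknown = set(arr) - set(vocab)
                if unknown:
                    raise InvalidSpecError(f"unknown {name} label(s): {sorted(unknown)}")
        if len(self.cell_ids) != n:
            raise InvalidSpecError("cell_ids must match point count")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def density(self) -> float:
        """Cells per mm^2 over the analysis region."""
        return self.n / self.region.area

    def subset(self, subtype: str) -> "CellMosaic":
        """The mosaic restricted to one subtype, same region."""
        if self.subtype is None:
            raise InvalidSpecError("mosaic carries no subtype labels")
        if subtype not in SUBTYPES:
            raise InvalidSpecError(f"unknown subtype {subtype!r}")
        m = self.subtype == subtype
        return CellMosaic(
            self.points[m],
            self.region,
            subtype=self.subtype[m],
            layer=None if self.layer is None else self.layer[m],
            donor_id=self.donor_id,
            donor_age=self.donor_age,
            cell_ids=self.cell_ids[m],
            validate=False,
        )

    def __repr__(self) -> str:
        return f"CellMosaic(n={self.n}, density={self.density:.3g}/mm^2)"


@dataclass(frozen=True)
class NNDSample:
    """Per-cell nearest-neighbour distances with an inclusion mask.

    ``included`` marks the cells entering the summary statistics; with a
    border buffer, cells closer than the buffer to the region boundary keep
    their distance but are excluded from mean/SD.
    """

    distances: np.ndarray
    included: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.distances[self.included].mean())

    @property
    def sd(self) -> float:
        return float(self.distances[self.included].std(ddof=1))

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


@dataclass(frozen=True)
class VDASample:
    """Per-cell Voronoi domain areas, clipped to the region.

    ``boundary`` flags domains touching the region boundary; ``included``
    marks those entering the summary (all by default).
    """

    areas: np.ndarray
    boundary: np.ndarray
    included: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.areas[self.included].mean())

    @property
    def sd(self) -> float:
        return float(self.areas[self.included].std(ddof=1))


@dataclass(frozen=True)
class GaussianFit:
    """Least-squares Gaussian fit to a binned histogram."""

    amplitude: float
    mu: float
    sigma: float
    r_squared: float | None
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    failed: bool = False

    def predict(self, x) -> np.ndarray:
        return self.amplitude * np.exp(-((np.asarray(x) - self.mu) ** 2) / (2 * self.sigma**2))


@dataclass(frozen=True)
class NullComparison:
    """Observed statistics against a Monte-Carlo density-matched random null."""

    statistics: tuple[str, ...]
    observed: dict
    null_mean: dict
    null_sd: dict
    null_lo95: dict
    null_hi95: dict
    percentile: dict
    n_reps: int

    def outside_envelope(self, stat: str) -> bool:
        return not (self.null_lo95[stat] <= self.observed[stat] <= self.null_hi95[stat])


@dataclass(frozen=True)
class MosaicStatsResult:
    """Full spatial-statistics bundle for one mosaic."""

    n: int
    density: float
    nnd: NNDSample
    vda: VDASample | None
    nnri: float
    vdri: float | None
    di: float
    fit_nnd: GaussianFit | None
    fit_vda: GaussianFit | None
    null: NullComparison | None = None
    subtype: str | None = field(default=None)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _resolve_buffer(mosaic: CellMosaic, border_buffer) -> float:
    """Border-buffer width in mm; True means one CSR mean spacing 1/(2*sqrt(rho))."""
    if border_buffer is True:
        return 1.0 / (2.0 * np.sqrt(mosaic.density))
    return float(border_buffer)


def nearest_neighbor_distances(mosaic: CellMosaic, border_buffer=None) -> NNDSample:
    """Distance from each cell to its closest other cell.

    Parameters
    ----------
    border_buffer : None, True, or float (mm)
        If set, cells nearer than the buffer to the region boundary are
        excluded from the summary statistics (their distances are still
        reported).  ``True`` uses one CSR mean spacing, 1/(2*sqrt(rho)).
    """
    if mosaic.n < 2:
        raise InsufficientPointsError("nearest-neighbour distances need at least 2 cells")
    d, _ = cKDTree(mosaic.points).query(mosaic.points, k=2)
    distances = d[:, 1]
    if border_buffer:
        margin = _resolve_buffer(mosaic, border_buffer)
        included = mosaic.region.distance_to_boundary(mosaic.points) > margin
        if included.sum() < 2:
            raise InsufficientPointsError("border buffer excluded all but <2 cells")
    else:
        included = np.ones(mosaic.n, dtype=bool)
    return NNDSample(distances=distances, included=included)


def voronoi_domain_areas(mosaic: CellMosaic, exclude_boundary: bool = False) -> VDASample:
    """Voronoi domain area of every cell, clipped to the analysis region.

    Boundary-touching domains are flagged; they are *included* in summaries by
    default, with ``exclude_boundary=True`` to drop them.  The clipped areas
    always tile the region exactly.
    """
    n = mosaic.n
    region_poly = mosaic.region.polygon
    if n == 1:
        areas = np.array([mosaic.region.area])
        boundary = np.array([True])
        return VDASample(areas, boundary, np.ones(1, bool) if not exclude_boundary else ~boundary)
    if n >= 3:
        spread = mosaic.points - mosaic.points.mean(axis=0)
        if np.linalg.matrix_rank(spread, tol=1e-12) < 2:
            raise DegenerateGeometryError("all cells are collinear; Voronoi domains are unbounded")
    envelope = region_poly.buffer(2.0 * max(region_poly.bounds[2] - region_poly.bounds[0],
                                            region_poly.bounds[3] - region_poly.bounds[1]))
    cells = shapely.voronoi_polygons(MultiPoint(mosaic.points), extend_to=envelope)
    cell_list = list(cells.geoms)
    tree = shapely.STRtree(cell_list)
    pt_idx, cell_idx = tree.query(shapely.points(mosaic.points), predicate="within")
    if len(pt_idx) != n:  # pragma: no cover - guards against degenerate tessellations
        raise DegenerateGeometryError("Voronoi tessellation did not assign a domain to every cell")
    areas = np.empty(n)
    boundary = np.zeros(n, dtype=bool)
    ring = region_poly.exterior
    for p_i, c_i in zip(pt_idx, cell_idx):
        clipped = shapely.intersection(cell_list[c_i], region_poly)
        areas[p_i] = clipped.area
        boundary[p_i] = shapely.intersects(clipped, ring)
    included = ~boundary if exclude_boundary else np.ones(n, dtype=bool)
    if exclude_boundary and included.sum() < 3:
        warnings.warn("boundary exclusion left <3 interior domains; including all", stacklevel=2)
        included = np.ones(n, dtype=bool)
    return VDASample(areas=areas, boundary=boundary, included=included)


def regularity_index(values) -> float:
    """Mean over sample SD (ddof=1) of NND or VDA values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InsufficientPointsError("regularity index needs at least 2 values")
    sd = values.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("regularity index undefined: zero standard deviation")
    return float(values.mean() / sd)


def dispersion_index(mosaic: CellMosaic, border_buffer=None) -> float:
    """Observed mean NND over the Clark–Evans CSR expectation 1/(2*sqrt(rho)).

    rho is the full mosaic density n/area; the buffer (if any) only restricts
    which cells contribute to the observed mean.
    """
    if mosaic.region.area <= 0:  # pragma: no cover - RegionPolygon forbids this
        raise InvalidSpecError("degenerate region")
    nnd = nearest_neighbor_distances(mosaic, border_buffer=border_buffer)
    expected = 1.0 / (2.0 * np.sqrt(mosaic.density))
    return nnd.mean / expected


def _gauss(x, amplitude, mu, sigma):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(values, bins="fd") -> GaussianFit:
    """Least-squares Gaussian fit to the histogram of ``values``.

    The histogram uses Freedman–Diaconis binning by default (``bins`` is
    passed to :func:`numpy.histogram_bin_edges`).  The fit is initialised from
    the sample mean/SD and peak count; R^2 is computed on the binned counts.
    On failure (degenerate histogram or non-convergence) the raw histogram is
    returned with ``failed=True`` and no R^2.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise InsufficientPointsError("Gaussian fit needs at least 10 values")
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        counts, edges = np.histogram(values, bins=1)
        return GaussianFit(np.nan, np.nan, np.nan, None, edges, counts, failed=True)
    edges = np.histogram_bin_edges(values, bins=bins)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 3:
        return GaussianFit(np.nan, np.nan, np.nan, None, edges, counts, failed=True)
    p0 = (counts.max(), values.mean(), sd)
    try:
        popt, _ = optimize.curve_fit(
            _gauss, centers, counts, p0=p0,
            bounds=([0.0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning, ValueError):
        return GaussianFit(np.nan, np.nan, np.nan, None, edges, counts, failed=True)
    resid = counts - _gauss(centers, *popt)
    ss_tot = ((counts - counts.mean()) ** 2).sum()
    r2 = float(1.0 - (resid**2).sum() / ss_tot) if ss_tot > 0 else None
    return GaussianFit(float(popt[0]), float(popt[1]), float(popt[2]), r2, edges, counts)


_NULL_STATS = ("nnri", "di", "mean_nnd", "vdri")


def null_comparison(
    mosaic: CellMosaic,
    n_reps: int = 99,
    seed: int | np.random.SeedSequence | None = None,
    statistics: tuple[str, ...] = ("nnri", "di", "mean_nnd"),
    border_buffer=None,
) -> NullComparison:
    """Compare a mosaic against density-matched random patterns.

    ``n_reps`` uniform patterns with exactly the observed n are generated in
    the same region; the requested statistics are summarised by their null
    mean, SD and central-95% envelope, and the observed value is located as a
    percentile of the null distribution.

    Note: Voronoi statistics ('vdri') are markedly slower than the NND-based
    ones; request them only when needed.
    """
    if mosaic.n < 10:
        raise InsufficientPointsError("null comparison needs at least 10 cells")
    unknown = set(statistics) - set(_NULL_STATS)
    if unknown:
        raise InvalidSpecError(f"unknown null statistics {sorted(unknown)}; choose from {_NULL_STATS}")
    rng = np.random.default_rng(seed)

    def compute(m: CellMosaic) -> dict:
        out = {}
        if {"nnri", "di", "mean_nnd"} & set(statistics):
            nnd = nearest_neighbor_distances(m, border_buffer=border_buffer)
            d = nnd.distances[nnd.included]
            if "nnri" in statistics:
                out["nnri"] = float(d.mean() / d.std(ddof=1))
            if "di" in statistics:
                out["di"] = float(d.mean() * 2.0 * np.sqrt(m.density))
            if "mean_nnd" in statistics:
                out["mean_nnd"] = float(d.mean())
        if "vdri" in statistics:
            vda = voronoi_domain_areas(m)
            out["vdri"] = regularity_index(vda.areas[vda.included])
        return out

    observed = compute(mosaic)
    null = {s: np.empty(n_reps) for s in statistics}
    for r in range(n_reps):
        pts = sample_uniform_in_region(mosaic.region, mosaic.n, rng)
        rep = CellMosaic(pts, mosaic.region, validate=False)
        vals = compute(rep)
        for s in statistics:
            null[s][r] = vals[s]
    return NullComparison(
        statistics=tuple(statistics),
        observed=observed,
        null_mean={s: float(null[s].mean()) for s in statistics},
        null_sd={s: float(null[s].std(ddof=1)) for s in statistics},
        null_lo95={s: float(np.quantile(null[s], 0.025)) for s in statistics},
        null_hi95={s: float(np.quantile(null[s], 0.975)) for s in statistics},
        percentile={s: float((null[s] <= observed[s]).mean()) for s in statistics},
        n_reps=n_reps,
    )


def mosaic_stats(
    mosaic: CellMosaic,
    bins="fd",
    null_reps: int = 0,
    seed: int | None = None,
    border_buffer=None,
    exclude_boundary_vda: bool = False,
    subtype: str | None = None,
) -> MosaicStatsResult:
    """All spatial statistics for one mosaic in a single call."""
    nnd = nearest_neighbor_distances(mosaic, border_buffer=border_buffer)
    d = nnd.distances[nnd.included]
    nnri = regularity_index(d)
    di = dispersion_index(mosaic, border_buffer=border_buffer)
    vda = vdri = None
    if mosaic.n >= 3:
        try:
            vda = voronoi_domain_areas(mosaic, exclude_boundary=exclude_boundary_vda)
            vdri = regularity_index(vda.areas[vda.included])
        except DegenerateGeometryError:
            vda = vdri = None
    fit_nnd = fit_gaussian(d, bins=bins) if d.size >= 10 else None
    fit_vda = (
        fit_gaussian(vda.areas[vda.included], bins=bins)
        if vda is not None and vda.included.sum() >= 10
        else None
    )
    null = (
        null_comparison(mosaic, n_reps=null_reps, seed=seed, border_buffer=border_buffer)
        if null_reps
        else None
    )
    return MosaicStatsResult(
        n=mosaic.n, density=mosaic.density, nnd=nnd, vda=vda, nnri=nnri,
        vdri=vdri, di=di, fit_nnd=fit_nnd, fit_vda=fit_vda, null=null, subtype=subtype,
    )


def per_subtype_stats(mosaic: CellMosaic, min_n: int = 10, **kwargs) -> dict[str, MosaicStatsResult]:
    """Analyse each subtype as an independent mosaic within the same region.

    Subtypes with fewer than ``min_n`` cells are skipped with a warning.
    Keyword arguments are forwarded to :func:`mosaic_stats`.
    """
    if mosaic.subtype is None:
        raise InvalidSpecError("mosaic carries no subtype labels")
    out: dict[str, MosaicStatsResult] = {}
    for st in SUBTYPES:
        sub = mosaic.subset(st)
        if sub.n == 0:
            continue
        if sub.n < min_n:
            warnings.warn(f"subtype {st}: only {sub.n} cells (<{min_n}), skipped", stacklevel=2)
            continue
        out[st] = mosaic_stats(sub, subtype=st, **kwargs)
    return out
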