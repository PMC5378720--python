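"""Per-cell neurite morphometry: soma size, field area, branching, Sholl.

All metrics are computed on the 2-D retinal-plane projection (x, y) of the
traced arbor, mirroring planar camera-lucida digitisations.  Axon nodes are
excluded from every dendritic metric.  Units: node coordinates in µm; the
dendritic field area is reported in mm².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .errors import DegenerateGeometryError, InvalidSpecError

__all__ = [
    "NeuriteTree",
    "ShollProfile",
    "MorphometryResult",
    "S1_Z_UM",
    "S5_Z_UM",
    "soma_equivalent_diameter",
    "dendritic_field_area",
    "count_branch_points",
    "count_terminal_tips",
    "sholl_profile",
    "sholl_area",
    "morphometry",
    "morphometry_batch",
]

#: Fixed z planes (µm above the soma plane) encoding dendritic stratum in SWC
#: files: S1 is the outer IPL stratum, S5 the inner one.
S1_Z_UM = 30.0
S5_Z_UM = 5.0

COMPARTMENTS = ("soma", "dendrite", "axon")


class NeuriteTree:
    """A rooted soma + neurite tree with per-node compartment and stratum.

    Parameters
    ----------
    ids, parents : int arrays; the root's parent is -1.
    xyz : (n, 3) float array, µm.
    radius : per-node radius, µm.
    compartment : per-node label in {soma, dendrite, axon}.
    stratum : per-node label in {S1, S5} for dendrites, None elsewhere.
    soma_area : measured soma cross-section, µm²; defaults to the disc area
        of the root soma node's radius.
    """

    __slots__ = (
        "ids", "parents", "xyz", "radius", "compartment", "stratum",
        "soma_area", "cell_id", "subtype", "donor_id", "age_years",
        "_index", "_children",
    )

    def __init__(
        self,
        ids,
        parents,
        xyz,
        radius,
        compartment,
        stratum=None,
        soma_area: float | None = None,
        cell_id: str | None = None,
        subtype: str | None = None,
        donor_id: str | None = None,
        age_years: float | None = None,
    ):
        self.ids = np.asarray(ids, dtype=int)
        self.parents = np.asarray(parents, dtype=int)
        self.xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        self.radius = np.asarray(radius, dtype=float)
        self.compartment = np.asarray(compartment, dtype=object)
        n = len(self.ids)
        if stratum is None:
            stratum = np.array([None] * n, dtype=object)
        self.stratum = np.asarray(stratum, dtype=object)
        self.cell_id = cell_id
        self.subtype = subtype
        self.donor_id = donor_id
        self.age_years = age_years
        self._validate()
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self._children = [[] for _ in range(n)]
        for k, p in enumerate(self.parents):
            if p != -1:
                self._children[self._index[int(p)]].append(k)
        if soma_area is None:
            soma_r = self.radius[self.compartment == "soma"]
            soma_area = float(math.pi * soma_r[0] ** 2) if soma_r.size else None
        if soma_area is not None and soma_area <= 0:
            raise InvalidSpecError("soma_area must be positive")
        self.soma_area = soma_area

    def _validate(self) -> None:
        n = len(self.ids)
        for name, arr in (("parents", self.parents), ("xyz", self.xyz),
                          ("radius", self.radius), ("compartment", self.compartment),
                          ("stratum", self.stratum)):
            if len(arr) != n:
                raise InvalidSpecError(f"{name} length must match node count")
        if len(np.unique(self.ids)) != n:
            dup = pd.Series(self.ids).value_counts()
            raise InvalidSpecError(f"duplicate node id(s): {dup[dup > 1].index.tolist()}")
        roots = np.flatnonzero(self.parents == -1)
        if len(roots) != 1:
            raise InvalidSpecError(f"tree must have exactly one root, found {len(roots)}")
        id_set = set(self.ids.tolist())
        index = {int(i): k for k, i in enumerate(self.ids)}
        for k, p in enumerate(self.parents):
            if p == -1:
                continue
            if int(p) == int(self.ids[k]):
                raise InvalidSpecError(f"node {self.ids[k]} is its own parent (cycle)")
            if int(p) not in id_set:
                raise InvalidSpecError(f"node {self.ids[k]} has missing parent {p}")
        # cycle check: walk to root from every node with a visited budget
        for k in range(n):
            seen = set()
            j = k
            while self.parents[j] != -1:
                if j in seen:
                    raise InvalidSpecError(f"cycle detected at node {self.ids[j]}")
                seen.add(j)
                j = index[int(self.parents[j])]
        unknown = set(self.compartment) - set(COMPARTMENTS)
        if unknown:
            raise InvalidSpecError(f"unknown compartment label(s): {sorted(unknown)}")

    # -- structure helpers -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parents == -1)[0])

    def children_of(self, index: int) -> list[int]:
        return self._children[index]

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    @property
    def dendrite_mask(self) -> np.ndarray:
        return self.compartment == "dendrite"

    @property
    def soma_centroid(self) -> np.ndarray:
        """2-D centroid of soma nodes (the Sholl centre)."""
        soma = self.xyz[self.compartment == "soma", :2]
        if len(soma) == 0:
            raise InvalidSpecError("tree has no soma node")
        return soma.mean(axis=0)

    def dendrite_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) xy coordinates of every dendritic edge.

        An edge belongs to the dendritic arbor when its child node is a
        dendrite; the parent may be the soma (primary-dendrite origin).
        """
        child = np.flatnonzero((self.parents != -1) & self.dendrite_mask)
        parent = np.array([self._index[int(p)] for p in self.parents[child]], dtype=int)
        return self.xyz[parent, :2], self.xyz[child, :2]

    def __repr__(self) -> str:
        return (
            f"NeuriteTree(n_nodes={self.n_nodes}, "
            f"dendrites={int(self.dendrite_mask.sum())}, subtype={self.subtype})"
        )


@dataclass(frozen=True)
class ShollProfile:
    """Crossing counts of concentric circles around the soma."""

    radii: np.ndarray
    crossings: np.ndarray
    step: float


@dataclass(frozen=True)
class MorphometryResult:
    soma_equiv_diameter_um: float | None
    dendritic_area_mm2: float | None
    branch_points: int
    terminal_tips: int
    sholl: ShollProfile
    sholl_area: float
    subtype: str | None = None
    cell_id: str | None = None
    degenerate_field: bool = field(default=False)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def soma_equivalent_diameter(soma_area: float) -> float:
    """Diameter of the circle with the same area: d = 2*sqrt(area/pi)."""
    if soma_area is None or soma_area <= 0:
        raise InvalidSpecError("soma area must be positive")
    return 2.0 * math.sqrt(soma_area / math.pi)


def dendritic_field_area(tree: NeuriteTree) -> float:
    """Area (mm²) of the minimal convex polygon enclosing the dendritic field.

    The hull is taken over the (x, y) positions of all dendrite nodes.
    """
    pts = tree.xyz[tree.dendrite_mask, :2]
    if len(pts) < 3:
        raise DegenerateGeometryError("dendritic field needs >=3 dendrite nodes")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
        raise DegenerateGeometryError("dendrite nodes are collinear")
    hull = ConvexHull(pts)
    return float(hull.volume) * 1e-6  # µm² -> mm²


def count_branch_points(tree: NeuriteTree, include_primary_origins: bool = False) -> int:
    """Dendritic nodes with >=2 dendritic children.

    The soma is never a branch point; a node with three dendritic children is
    a single branch point.  ``include_primary_origins=True`` additionally
    counts the soma once when >=2 primary dendrites leave it (an alternative
    reading of per-cell branch counts, off by default).
    """
    dm = tree.dendrite_mask
    count = 0
    for k in range(tree.n_nodes):
        if not dm[k]:
            continue
        if sum(1 for c in tree.children_of(k) if dm[c]) >= 2:
            count += 1
    if include_primary_origins:
        soma_nodes = np.flatnonzero(tree.compartment == "soma")
        primaries = sum(
            1 for s in soma_nodes for c in tree.children_of(int(s)) if dm[c]
        )
        if primaries >= 2:
            count += 1
    return count


def count_terminal_tips(tree: NeuriteTree) -> int:
    """Dendritic leaf nodes (no dendritic children)."""
    dm = tree.dendrite_mask
    return sum(
        1
        for k in range(tree.n_nodes)
        if dm[k] and not any(dm[c] for c in tree.children_of(k))
    )


def sholl_profile(tree: NeuriteTree, step: float = 10.0) -> ShollProfile:
    """Crossings of concentric circles (radius step, 2*step, ...) by the arbor.

    Circles are centred on the soma centroid; each dendritic edge is a
    straight segment and contributes one crossing per transversal intersection
    with a circle.  Tangency (including an endpoint exactly on the circle)
    counts zero, so the count equals the number of sign changes of
    (distance-to-centre - r) along the edge.
    """
    if step <= 0:
        raise InvalidSpecError("Sholl step must be positive")
    center = tree.soma_centroid
    dend = tree.xyz[tree.dendrite_mask, :2]
    if len(dend) == 0:
        return ShollProfile(radii=np.array([step]), crossings=np.array([0]), step=step)
    max_extent = float(np.sqrt(((dend - center) ** 2).sum(axis=1)).max())
    n_circles = max(int(math.ceil(max_extent / step)), 1)
    radii = step * np.arange(1, n_circles + 1)

    p, q = tree.dendrite_edges()
    if len(p) == 0:
        return ShollProfile(radii=radii, crossings=np.zeros(n_circles, dtype=int), step=step)
    p = p - center
    q = q - center
    d0 = np.sqrt((p**2).sum(axis=1))
    d1 = np.sqrt((q**2).sum(axis=1))
    seg = q - p
    seg_len2 = (seg**2).sum(axis=1)
    # closest approach of each segment to the centre, clamped to the segment
    with np.errstate(invalid="ignore", divide="ignore"):
        t_star = np.where(seg_len2 > 0, -(p * seg).sum(axis=1) / seg_len2, 0.0)
    interior = (t_star > 0) & (t_star < 1)
    d_min = np.minimum(d0, d1)
    closest = p + t_star[:, None] * seg
    d_closest = np.sqrt((closest**2).sum(axis=1))
    d_min = np.where(interior, np.minimum(d_min, d_closest), d_min)
    # a transversal crossing occurs on each monotone half of the edge where
    # the distance passes strictly through r
    r = radii[:, None]
    crossings = ((d0 > r) & (d_min < r)).sum(axis=1) + ((d1 > r) & (d_min < r)).sum(axis=1)
    return ShollProfile(radii=radii, crossings=crossings.astype(int), step=step)


def sholl_area(profile: ShollProfile) -> float:
    """Area under the Sholl profile divided by the step (arbitrary units).

    The units are summed crossings per circle: for a constant profile of c
    crossings over k radii the value is c*(k-1).  The quantity therefore
    depends on the chosen step (halving the step doubles it); the underlying
    profile integral, sholl_area*step, is step-stable.  Compare Sholl areas
    only across cells profiled at the same step.
    """
    if len(profile.radii) == 0:
        raise InvalidSpecError("empty Sholl profile")
    if len(profile.radii) == 1:
        return float(profile.crossings[0])
    return float(np.trapezoid(profile.crossings, profile.radii) / profile.step)


def morphometry(tree: NeuriteTree, sholl_step: float = 10.0) -> MorphometryResult:
    """All per-cell metrics for one tree."""
    try:
        area = dendritic_field_area(tree)
        degenerate = False
    except DegenerateGeometryError:
        area = None
        degenerate = True
    sholl = sholl_profile(tree, step=sholl_step)
    return MorphometryResult(
        soma_equiv_diameter_um=(
            soma_equivalent_diameter(tree.soma_area) if tree.soma_area else None
        ),
        dendritic_area_mm2=area,
        branch_points=count_branch_points(tree),
        terminal_tips=count_terminal_tips(tree),
        sholl=sholl,
        sholl_area=sholl_area(sholl),
        subtype=tree.subtype,
        cell_id=tree.cell_id,
        degenerate_field=degenerate,
    )


def morphometry_batch(trees, sholl_step: float = 10.0) -> pd.DataFrame:
    """One metric row per cell; per-cell failures are flagged, never dropped.

    Rows are ordered by cell id.  Duplicate cell ids raise.
    """
    trees = list(trees)
    if not trees:
        raise InvalidSpecError("morphometry_batch needs at least one tree")
    ids = [t.cell_id if t.cell_id is not None else f"cell{k}" for k, t in enumerate(trees)]
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids).value_counts()
        raise InvalidSpecError(f"duplicate cell id(s): {dup[dup > 1].index.tolist()}")
    rows = []
    for cid, t in zip(ids, trees):
        try:
            m = morphometry(t, sholl_step=sholl_step)
            rows.append(
                dict(
                    cell_id=cid, subtype=t.subtype, donor_id=t.donor_id,
                    age_years=t.age_years,
                    soma_equiv_diameter_um=m.soma_equiv_diameter_um,
                    dendritic_area_mm2=m.dendritic_area_mm2,
                    branch_points=m.branch_points, terminal_tips=m.terminal_tips,
                    sholl_area=m.sholl_area,
                    degenerate_field=m.degenerate_field, error="",
                )
            )
        except Exception as exc:  # noqa: BLE001 - batch must continue
            rows.append(
                dict(
                    cell_id=cid, subtype=t.subtype, donor_id=t.donor_id,
                    age_years=t.age_years,
                    soma_equiv_diameter_um=None, dendritic_area_mm2=None,
                    branch_points=None, terminal_tips=None, sholl_area=None,
                    degenerate_field=True, error=str(exc),
                )
            )
    return pd.DataFrame(rows).sort_values("cell_id", kind="stable").reset_index(drop=True)
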