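"""Polygonal analysis regions (sampling windows) on the flattened retina.

Coordinates are planar millimetres: mosaics come from flat-mounted retinas, so
no spherical correction is applied anywhere in the package.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import InvalidSpecError


class RegionPolygon:
    """A closed, simple polygon bounding the analysis window.

    Parameters
    ----------
    vertices : array-like of shape (k, 2)
        Ordered vertices in mm.  The polygon is closed implicitly (the last
        vertex connects back to the first); do not repeat the first vertex.
    """

    __slots__ = ("vertices", "_polygon")

    def __init__(self, vertices):
        vertices = np.asarray(vertices, dtype=float)
        if vertices.ndim != 2 or vertices.shape[1] != 2:
            raise InvalidSpecError("region vertices must be an (k, 2) array")
        # drop an explicitly repeated closing vertex
        if len(vertices) > 1 and np.array_equal(vertices[0], vertices[-1]):
            vertices = vertices[:-1]
        if len(vertices) < 3:
            raise InvalidSpecError("region polygon needs at least 3 vertices")
        if not np.isfinite(vertices).all():
            raise InvalidSpecError("region vertices must be finite")
        poly = Polygon(vertices)
        if not poly.is_valid or not poly.is_simple:
            raise InvalidSpecError("region polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise InvalidSpecError("region polygon must have positive area")
        self.vertices = vertices
        self._polygon = poly

    # -- constructors ----------------------------------------------------------

    @classmethod
    def unit_square(cls) -> "RegionPolygon":
        return cls.rectangle(1.0, 1.0)

    @classmethod
    def rectangle(cls, width: float, height: float, origin=(0.0, 0.0)) -> "RegionPolygon":
        x0, y0 = origin
        return cls([(x0, y0), (x0 + width, y0), (x0 + width, y0 + height), (x0, y0 + height)])

    @classmethod
    def from_polygon(cls, polygon: Polygon) -> "RegionPolygon":
        return cls(np.asarray(polygon.exterior.coords))

    # -- geometry --------------------------------------------------------------

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    @property
    def area(self) -> float:
        return self._polygon.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self._polygon.bounds

    def contains_points(self, points) -> np.ndarray:
        """Strict-interior membership test for an (n, 2) array of points."""
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        return shapely.contains_xy(self._polygon, points[:, 0], points[:, 1])

    def distance_to_boundary(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float).reshape(-1, 2)
        return shapely.distance(self._polygon.exterior, shapely.points(points))

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionPolygon) and np.array_equal(self.vertices, other.vertices)

    def __repr__(self) -> str:
        return f"RegionPolygon({len(self.vertices)} vertices, area={self.area:.4g} mm^2)"


def sample_uniform_in_region(region: RegionPolygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw exactly ``n`` i.i.d. uniform points strictly inside the region.

    Rejection sampling from the bounding box; efficient for any region whose
    area is a non-trivial fraction of its bounding box.
    """
    if n == 0:
        return np.empty((0, 2))
    x0, y0, x1, y1 = region.bounds
    frac = max(region.area / ((x1 - x0) * (y1 - y0)), 1e-3)
    out = np.empty((n, 2))
    k = 0
    while k < n:
        m = max(int((n - k) / frac * 1.2), 16)
        cand = rng.random((m, 2)) * (x1 - x0, y1 - y0) + (x0, y0)
        cand = cand[region.contains_points(cand)]
        take = min(len(cand), n - k)
        out[k : k + take] = cand[:take]
        k += take
    return out
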