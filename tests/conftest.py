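import numpy as np
import pytest

from retmosaic import CellMosaic, NeuriteTree, RegionPolygon


@pytest.fixture
def unit_region() -> RegionPolygon:
    return RegionPolygon.unit_square()


@pytest.fixture
def region_10mm() -> RegionPolygon:
    return RegionPolygon.rectangle(10.0, 10.0)


def make_mosaic(points, region=None, **kwargs) -> CellMosaic:
    points = np.asarray(points, dtype=float)
    if region is None:
        lo = points.min(axis=0) - 1.0
        hi = points.max(axis=0) + 1.0
        region = RegionPolygon(
            [(lo[0], lo[1]), (hi[0], lo[1]), (hi[0], hi[1]), (lo[0], hi[1])]
        )
    return CellMosaic(points, region, **kwargs)


def make_tree(edges, soma_xy=(0.0, 0.0), compartments=None, soma_area=100.0, **kwargs):
    """Build a NeuriteTree from (child_id, parent_id, x, y) tuples.

    Node id 1 is the soma at ``soma_xy``; all listed nodes default to
    dendrites (override per id via ``compartments``).
    """
    compartments = compartments or {}
    ids = [1]
    parents = [-1]
    xyz = [(soma_xy[0], soma_xy[1], 0.0)]
    comp = [compartments.get(1, "soma")]
    for child, parent, x, y in edges:
        ids.append(child)
        parents.append(parent)
        xyz.append((x, y, 5.0))
        comp.append(compartments.get(child, "dendrite"))
    n = len(ids)
    return NeuriteTree(
        ids=np.array(ids),
        parents=np.array(parents),
        xyz=np.array(xyz, dtype=float),
        radius=np.ones(n),
        compartment=np.array(comp, dtype=object),
        soma_area=soma_area,
        **kwargs,
    )
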