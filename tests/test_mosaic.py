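import math

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import qmc

from retmosaic import (
    CellMosaic,
    DegenerateGeometryError,
    InsufficientPointsError,
    InvalidSpecError,
    MosaicSpec,
    RegionPolygon,
    UndefinedStatisticError,
    dispersion_index,
    fit_gaussian,
    generate_dmin_mosaic,
    generate_poisson_mosaic,
    mosaic_stats,
    nearest_neighbor_distances,
    null_comparison,
    per_subtype_stats,
    regularity_index,
    voronoi_domain_areas,
)
from retmosaic.reference import CSR_NNRI_ANALYTIC

from conftest import make_mosaic


def csr_mosaic(n, seed, region=None, **kwargs):
    region = region or RegionPolygon.unit_square()
    spec = MosaicSpec(region=region, density=n / region.area, exact_n=True, seed=seed, **kwargs)
    return generate_poisson_mosaic(spec)


class TestCellMosaic:
    def test_rejects_duplicates_and_outside_points(self, unit_region):
        with pytest.raises(InvalidSpecError, match="duplicate"):
            CellMosaic([[0.5, 0.5], [0.5, 0.5], [0.2, 0.2]], unit_region)
        with pytest.raises(InvalidSpecError, match="outside"):
            CellMosaic([[0.5, 0.5], [1.5, 0.5]], unit_region)

    def test_rejects_unknown_labels(self, unit_region):
        with pytest.raises(InvalidSpecError, match="subtype"):
            CellMosaic([[0.5, 0.5], [0.2, 0.2]], unit_region, subtype=["M1", "M4"])
        with pytest.raises(InvalidSpecError, match="layer"):
            CellMosaic([[0.5, 0.5], [0.2, 0.2]], unit_region, layer=["GCL", "ONL"])

    def test_subset_partitions_points(self, unit_region):
        m = CellMosaic([[0.1, 0.1], [0.5, 0.5], [0.9, 0.9]], unit_region,
                       subtype=["M1", "M1d", "M1"])
        assert m.subset("M1").n == 2
        assert m.subset("M2").n == 0


class TestNearestNeighborDistances:
    def test_collinear_hand_example(self):
        m = make_mosaic([[0, 0], [1, 0], [3, 0]])
        nnd = nearest_neighbor_distances(m)
        np.testing.assert_allclose(sorted(nnd.distances), [1, 1, 2])

    def test_square_corners_symmetry(self):
        m = make_mosaic([[0, 0], [1, 0], [1, 1], [0, 1]])
        nnd = nearest_neighbor_distances(m)
        np.testing.assert_allclose(nnd.distances, 1.0)

    def test_matches_brute_force_all_pairs(self):
        m = csr_mosaic(200, seed=11)
        nnd = nearest_neighbor_distances(m)
        diff = m.points[:, None, :] - m.points[None, :, :]
        dmat = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dmat, np.inf)
        np.testing.assert_allclose(nnd.distances, dmat.min(axis=1), rtol=1e-12)

    def test_insufficient_points(self, unit_region):
        with pytest.raises(InsufficientPointsError):
            nearest_neighbor_distances(CellMosaic([[0.5, 0.5]], unit_region))

    def test_border_buffer_excludes_edge_cells(self):
        m = csr_mosaic(500, seed=2)
        nnd = nearest_neighbor_distances(m, border_buffer=0.1)
        edge_dist = m.region.distance_to_boundary(m.points)
        assert (edge_dist[nnd.included] > 0.1).all()
        assert nnd.included.sum() < m.n
        # distances themselves are unchanged
        np.testing.assert_array_equal(
            nnd.distances, nearest_neighbor_distances(m).distances
        )

    def test_rigid_motion_invariance_and_scaling(self):
        m = csr_mosaic(100, seed=5)
        base = nearest_neighbor_distances(m).distances
        c, s = math.cos(0.7), math.sin(0.7)
        rot = m.points @ np.array([[c, -s], [s, c]]).T + [3.0, -2.0]
        m_rot = make_mosaic(rot)
        np.testing.assert_allclose(
            np.sort(nearest_neighbor_distances(m_rot).distances), np.sort(base), rtol=1e-9
        )
        big_region = RegionPolygon.rectangle(2.5, 2.5)
        m_scaled = CellMosaic(m.points * 2.5, big_region)
        scaled = nearest_neighbor_distances(m_scaled).distances
        np.testing.assert_allclose(scaled, base * 2.5, rtol=1e-12)
        assert regularity_index(scaled) == pytest.approx(regularity_index(base))
        assert dispersion_index(m_scaled) == pytest.approx(dispersion_index(m))


class TestVoronoiDomainAreas:
    def test_two_symmetric_points_halve_the_square(self, unit_region):
        m = CellMosaic([[0.25, 0.5], [0.75, 0.5]], unit_region)
        vda = voronoi_domain_areas(m)
        np.testing.assert_allclose(vda.areas, [0.5, 0.5])

    def test_single_point_owns_whole_region(self, unit_region):
        m = CellMosaic([[0.3, 0.6]], unit_region)
        vda = voronoi_domain_areas(m)
        assert vda.areas[0] == pytest.approx(1.0)

    def test_collinear_points_rejected(self):
        m = make_mosaic([[0, 0], [1, 0], [2, 0], [3, 0]])
        with pytest.raises(DegenerateGeometryError):
            voronoi_domain_areas(m)

    def test_areas_tile_region_exactly(self):
        for seed, n in [(0, 10), (1, 50), (2, 300)]:
            m = csr_mosaic(n, seed=seed)
            vda = voronoi_domain_areas(m)
            assert vda.areas.sum() == pytest.approx(m.region.area, rel=1e-9)
            assert (vda.areas > 0).all()

    def test_matches_quasi_monte_carlo_integration(self, unit_region):
        """Each clipped area equals nearest-site QMC integration within 0.5%."""
        m = csr_mosaic(50, seed=1)
        vda = voronoi_domain_areas(m)
        samp = qmc.Sobol(d=2, scramble=True, seed=7).random(2**20)
        _, label = cKDTree(m.points).query(samp)
        mc = np.bincount(label, minlength=m.n) / len(samp) * m.region.area
        np.testing.assert_allclose(vda.areas, mc, rtol=5e-3)

    def test_boundary_flags_and_exclusion(self):
        m = csr_mosaic(100, seed=4)
        vda = voronoi_domain_areas(m)
        assert vda.boundary.any() and not vda.boundary.all()
        assert vda.included.all()  # included by default
        excl = voronoi_domain_areas(m, exclude_boundary=True)
        assert excl.included.sum() == (~excl.boundary).sum()


class TestRegularityIndex:
    def test_two_point_closed_form(self):
        # mean 3, sample SD sqrt(2)
        assert regularity_index([2.0, 4.0]) == pytest.approx(3.0 / math.sqrt(2.0))
        with pytest.raises(InsufficientPointsError):
            regularity_index([2.0])

    def test_mean_over_sample_sd(self):
        vals = [2.0, 4.0, 2.0, 4.0]
        # mean 3, sample SD sqrt(4/3)
        assert regularity_index(vals) == pytest.approx(3.0 / math.sqrt(4.0 / 3.0))

    def test_zero_sd_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            regularity_index([1.0, 1.0, 1.0])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(4.0, 1.0, 100)
        assert regularity_index(vals) == pytest.approx(regularity_index(vals[::-1]), rel=1e-12)


class TestCSRAnchors:
    """A homogeneous random pattern has NNRI sqrt(pi/(4-pi)) ~ 1.91 and DI 1."""

    def test_poisson_nnri_and_di_match_clark_evans(self):
        nnris, dis = [], []
        for seed in range(30):
            m = csr_mosaic(1000, seed=seed)
            nnd = nearest_neighbor_distances(m, border_buffer=True)
            d = nnd.distances[nnd.included]
            nnris.append(d.mean() / d.std(ddof=1))
            dis.append(dispersion_index(m, border_buffer=True))
        assert np.mean(nnris) == pytest.approx(CSR_NNRI_ANALYTIC, abs=0.03)
        assert np.mean(dis) == pytest.approx(1.0, abs=0.02)


class TestDispersionIndex:
    def test_hexagonal_lattice_closed_form(self):
        """DI of a hexagonal lattice is 2*sqrt(2/sqrt(3)) at any density."""
        s = 0.1
        nx, ny = 20, 20
        pts = []
        for j in range(ny):
            xs = (np.arange(nx) + 0.25 + 0.5 * (j % 2)) * s
            ys = np.full(nx, (j + 0.5) * s * math.sqrt(3) / 2)
            pts.append(np.column_stack([xs, ys]))
        region = RegionPolygon.rectangle(nx * s, ny * s * math.sqrt(3) / 2)
        m = CellMosaic(np.vstack(pts), region)
        assert dispersion_index(m) == pytest.approx(2.0 * math.sqrt(2.0 / math.sqrt(3.0)), rel=1e-9)

    def test_regular_mosaic_has_higher_di_than_random(self, region_10mm):
        di_dmin, di_pois = [], []
        for seed in range(20):
            spacing = 1.0 / math.sqrt(2.0)
            dm = generate_dmin_mosaic(
                MosaicSpec(region=region_10mm, density=2.0, model="dmin",
                           dmin_mean=0.4 * spacing, dmin_sd=0.08 * spacing, seed=seed)
            )
            po = generate_poisson_mosaic(
                MosaicSpec(region=region_10mm, density=2.0, seed=seed)
            )
            di_dmin.append(dispersion_index(dm))
            di_pois.append(dispersion_index(po))
        assert np.mean(di_dmin) > np.mean(di_pois)


class TestGaussianFit:
    def test_parameter_recovery_on_normal_draws(self):
        rng = np.random.default_rng(42)
        values = rng.normal(2.0, 0.5, 5000)
        fit = fit_gaussian(values)
        assert not fit.failed
        assert abs(fit.mu - 2.0) < 2.0 * 0.5 / math.sqrt(5000)
        assert fit.sigma == pytest.approx(0.5, rel=0.10)
        assert fit.r_squared >= 0.95

    def test_constant_values_fail_cleanly(self):
        fit = fit_gaussian(np.ones(50))
        assert fit.failed and fit.r_squared is None
        assert fit.bin_counts.sum() == 50

    def test_too_few_values(self):
        with pytest.raises(InsufficientPointsError):
            fit_gaussian(np.arange(5.0))

    def test_whole_mosaic_nnd_histogram_fits_well(self):
        m = csr_mosaic(2000, seed=9)
        fit = fit_gaussian(nearest_neighbor_distances(m).distances)
        assert fit.r_squared >= 0.9


class TestNullComparison:
    def test_null_mean_nnri_near_random_value(self):
        m = csr_mosaic(2000, seed=0)
        null = null_comparison(m, n_reps=30, seed=1, border_buffer=True)
        assert null.null_mean["nnri"] == pytest.approx(1.91, abs=0.03)
        assert null.null_mean["di"] == pytest.approx(1.0, abs=0.02)

    def test_regular_mosaic_lies_above_envelope(self, region_10mm):
        spacing = 1.0 / math.sqrt(2.0)
        m = generate_dmin_mosaic(
            MosaicSpec(region=region_10mm, density=2.0, model="dmin",
                       dmin_mean=0.5 * spacing, dmin_sd=0.05 * spacing, seed=3)
        )
        null = null_comparison(m, n_reps=99, seed=4)
        assert null.observed["nnri"] > null.null_hi95["nnri"]
        assert null.outside_envelope("nnri")

    def test_envelope_coverage_for_random_mosaics(self):
        """A random mosaic falls inside its own null 95% envelope ~95% of the time."""
        inside = 0
        trials = 100
        for t in range(trials):
            m = csr_mosaic(100, seed=1000 + t)
            null = null_comparison(m, n_reps=99, seed=t)
            inside += not null.outside_envelope("nnri")
        assert 0.87 <= inside / trials <= 1.0


class TestPerSubtypeStats:
    def test_single_subtype_equals_whole_mosaic(self, unit_region):
        m = csr_mosaic(100, seed=6)
        labelled = CellMosaic(m.points, m.region, subtype=np.full(m.n, "M2", dtype=object))
        per = per_subtype_stats(labelled)
        whole = mosaic_stats(labelled)
        assert list(per) == ["M2"]
        assert per["M2"].nnri == pytest.approx(whole.nnri)
        assert per["M2"].di == pytest.approx(whole.di)

    def test_superposition_of_poisson_is_poisson(self, unit_region):
        rng = np.random.default_rng(8)
        a = rng.random((800, 2)) * 0.998 + 0.001
        b = rng.random((800, 2)) * 0.998 + 0.001
        m = CellMosaic(np.vstack([a, b]), unit_region,
                       subtype=np.array(["M1"] * 800 + ["M2"] * 800, dtype=object))
        per = per_subtype_stats(m, border_buffer=True)
        whole = mosaic_stats(m, border_buffer=True)
        for r in (*per.values(), whole):
            assert r.nnri == pytest.approx(1.91, abs=0.12)

    def test_regular_subtype_beats_sparse_random_subtype(self, region_10mm):
        spacing = 1.0 / math.sqrt(2.05)
        m1d = generate_dmin_mosaic(
            MosaicSpec(region=region_10mm, density=2.05, model="dmin",
                       dmin_mean=0.4 * spacing, dmin_sd=0.08 * spacing, seed=0),
            subtype="M1d",
        )
        m1 = generate_poisson_mosaic(
            MosaicSpec(region=region_10mm, density=0.51, seed=1), subtype="M1"
        )
        combined = CellMosaic(
            np.vstack([m1d.points, m1.points]), region_10mm,
            subtype=np.concatenate([m1d.subtype, m1.subtype]),
        )
        per = per_subtype_stats(combined)
        assert per["M1d"].nnri > per["M1"].nnri

    def test_small_subtype_skipped_with_warning(self, unit_region):
        m = csr_mosaic(30, seed=2)
        labels = np.array(["M1"] * 25 + ["M3"] * 5, dtype=object)
        labelled = CellMosaic(m.points, m.region, subtype=labels)
        with pytest.warns(UserWarning, match="M3"):
            per = per_subtype_stats(labelled)
        assert "M3" not in per
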