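import numpy as np
import pytest

from conftest import random_cloud, random_rotation, uniform_ball
from memchiral.descriptors import (
    DegenerateGeometryError,
    PointCloud,
    PrincipalFrame,
    axial_chirality_index,
    chiral_moment,
    chiral_moment_vector,
    circular_asymmetry_index,
    compute_all,
    fractal_dimension,
    geometric_asymmetry_index,
    helical_chirality_index,
    morphometric_ellipticity,
    principal_frame,
    radial_distribution,
    radius_of_gyration,
    rdf_heterogeneity,
    spatial_orientation_chirality,
)
from memchiral.synthetic_structures import SyntheticSpec, from_coords, generate

IDENTITY_FRAME = PrincipalFrame(axes=np.eye(3), sds=np.array([3.0, 2.0, 1.0]))


def cloud(*pts):
    return PointCloud(np.array(pts, dtype=float))


class TestRadiusOfGyration:
    def test_single_point_is_zero(self):
        assert radius_of_gyration(cloud([5.0, -2.0, 7.0])) == 0.0

    def test_symmetric_pair(self):
        assert radius_of_gyration(cloud([0, 0, 0], [2, 0, 0])) == \
            pytest.approx(1.0)

    def test_cube_corners(self, cube_corners):
        assert radius_of_gyration(cube_corners) == pytest.approx(np.sqrt(3.0))


class TestGeometricAsymmetry:
    def test_equidistant_cloud_is_zero(self, cube_corners):
        assert geometric_asymmetry_index(cube_corners) == pytest.approx(0.0)

    def test_collinear_hand_value(self):
        # distances {3,1,1,3}: mu=2, population sigma=1 -> 0.5
        c = cloud([-3, 0, 0], [-1, 0, 0], [1, 0, 0], [3, 0, 0])
        assert geometric_asymmetry_index(c) == pytest.approx(0.5)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            geometric_asymmetry_index(cloud([1, 1, 1], [1, 1, 1]))


class TestChiralMoment:
    def test_collinear_is_zero(self):
        c = cloud([0, 0, 0], [1, 0, 0], [2, 0, 0], [5, 0, 0])
        assert chiral_moment(c) == pytest.approx(0.0)

    def test_antipodal_pair_is_zero(self):
        assert chiral_moment(cloud([1, 0, 0], [-1, 0, 0])) == \
            pytest.approx(0.0)

    def test_ordered_square_hand_value(self):
        # three consecutive cross products, each (0,0,1); mean norm = 1
        c = cloud([1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0])
        assert chiral_moment(c) == pytest.approx(1.0)

    def test_translation_invariant_vector_rotates(self):
        c = random_cloud(30, seed=1)
        v = chiral_moment_vector(c)
        shifted = PointCloud(c.coords + np.array([5.0, -3.0, 2.0]))
        np.testing.assert_allclose(chiral_moment_vector(shifted), v,
                                   atol=1e-12)
        rot = random_rotation(np.random.default_rng(2))
        rotated = PointCloud(c.coords @ rot.T)
        np.testing.assert_allclose(chiral_moment_vector(rotated), rot @ v,
                                   atol=1e-12)

    def test_mirror_negates_reflected_vector_norm_unchanged(self):
        # for reflection M: cross(Ma, Mb) = -M cross(a, b)
        c = random_cloud(25, seed=3)
        v = chiral_moment_vector(c)
        mirror = np.diag([1.0, 1.0, -1.0])
        mirrored = PointCloud(c.coords @ mirror)
        np.testing.assert_allclose(chiral_moment_vector(mirrored),
                                   -(mirror @ v), atol=1e-12)
        assert chiral_moment(mirrored) == pytest.approx(chiral_moment(c))

    def test_order_dependence_is_unique_to_cm(self):
        c = random_cloud(40, seed=4)
        perm = np.random.default_rng(5).permutation(40)
        shuffled = PointCloud(c.coords[perm])
        assert chiral_moment(shuffled) != pytest.approx(chiral_moment(c))
        assert radius_of_gyration(shuffled) == \
            pytest.approx(radius_of_gyration(c))
        assert geometric_asymmetry_index(shuffled) == \
            pytest.approx(geometric_asymmetry_index(c))
        f1, f2 = principal_frame(c), principal_frame(shuffled)
        assert helical_chirality_index(shuffled, f2) == \
            pytest.approx(helical_chirality_index(c, f1))
        assert axial_chirality_index(shuffled, f2) == \
            pytest.approx(axial_chirality_index(c, f1))


class TestPrincipalFrame:
    def test_one_dimensional_cloud(self):
        c = cloud([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])
        frame = principal_frame(c)
        np.testing.assert_allclose(np.abs(frame.e1), [1, 0, 0], atol=1e-12)
        assert frame.sds[1] == pytest.approx(0.0, abs=1e-12)
        assert frame.sds[2] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_cube_unit_sds(self, cube_corners):
        frame = principal_frame(cube_corners)
        np.testing.assert_allclose(frame.sds, [1.0, 1.0, 1.0], atol=1e-12)

    def test_two_points_define_axis(self):
        frame = principal_frame(cloud([0, 0, 0], [0, 3, 4]))
        np.testing.assert_allclose(np.abs(frame.e1), [0, 0.6, 0.8],
                                   atol=1e-12)

    def test_orthonormal_right_handed(self):
        frame = principal_frame(random_cloud(50, seed=6))
        np.testing.assert_allclose(frame.axes @ frame.axes.T, np.eye(3),
                                   atol=1e-12)
        np.testing.assert_allclose(np.cross(frame.e1, frame.e2), frame.e3,
                                   atol=1e-12)


class TestSpatialOrientationChirality:
    def test_centrosymmetric_cloud_is_zero(self):
        pts = np.random.default_rng(7).normal(size=(20, 3))
        c = PointCloud(np.vstack([pts, -pts]))
        assert spatial_orientation_chirality(c, principal_frame(c)) == 0.0

    def test_lopsided_cloud_hand_count(self):
        pts = [[-1.0, 0.1 * i, 0.0] for i in range(9)] + [[9.0, 0.4, 0.0]]
        c = PointCloud(np.array(pts))
        assert spatial_orientation_chirality(c, principal_frame(c)) == \
            pytest.approx(0.8)

    def test_all_on_perpendicular_plane_is_zero(self):
        c = cloud([0, 1, 0], [0, -1, 0], [0, 0, 2], [0, 0, -2])
        frame = PrincipalFrame(axes=np.eye(3), sds=np.array([1.0, 1, 1]))
        assert spatial_orientation_chirality(c, frame) == 0.0


class TestHelicalChirality:
    def test_on_axis_atoms_zero(self):
        c = cloud([0, 0, 0], [1, 0, 0], [2, 0, 0], [4, 0, 0])
        assert helical_chirality_index(c, principal_frame(c)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_constant_radius_helix_near_zero(self):
        # height 100 A >> radius 2 A, so the principal axis is the helix axis
        spec = SyntheticSpec(preset="helix", n_atoms=2000, helix_radius=2.0,
                             helix_pitch=0.5, turns=200.0)
        c = PointCloud(generate(spec).coords)
        hci = helical_chirality_index(c, principal_frame(c))
        assert hci < 1e-3

    def test_two_coaxial_rings_population_variance(self):
        theta = np.linspace(0, 2 * np.pi, 36, endpoint=False)
        ring = np.column_stack([np.cos(theta), np.sin(theta),
                                np.zeros_like(theta)])
        pts = np.vstack([1.0 * ring + [0, 0, -500.0],
                         3.0 * ring + [0, 0, 500.0]])
        c = PointCloud(pts)
        assert helical_chirality_index(c, principal_frame(c)) == \
            pytest.approx(1.0, abs=1e-6)


class TestAxialChirality:
    def test_azimuth_cluster_small_deviation(self):
        # azimuths {pi/4, -pi/4, pi}: circular mean 0, deviations
        # {pi/4, pi/4, pi} -> mean pi/2; hand-checkable zero-centroid cloud
        c = cloud([0, 1, 1], [5, 1, -1], [-5, -2, 0])
        assert axial_chirality_index(c, IDENTITY_FRAME) == \
            pytest.approx(np.pi / 2)

    def test_pm_quarter_pi_azimuth_deviation(self):
        # mean absolute circular deviation of azimuths +/- pi/4 about their
        # circular mean (0) is pi/4
        from memchiral.descriptors import _wrap_angle, circular_mean
        theta = np.array([np.pi / 4, -np.pi / 4])
        ref = circular_mean(theta)
        assert ref == pytest.approx(0.0, abs=1e-15)
        assert np.mean(np.abs(_wrap_angle(theta - ref))) == \
            pytest.approx(np.pi / 4)

    def test_uniform_four_point_set(self):
        c = cloud([0, 1, 0], [0, 0, 1], [0, -1, 0], [0, 0, -1])
        assert axial_chirality_index(c, IDENTITY_FRAME) == \
            pytest.approx(np.pi / 2)

    def test_all_on_axis_degenerate(self):
        c = cloud([1, 0, 0], [2, 0, 0], [-1, 0, 0])
        with pytest.raises(DegenerateGeometryError, match="azimuth"):
            axial_chirality_index(c, IDENTITY_FRAME)


class TestCircularAsymmetry:
    def test_mirror_symmetric_cancels(self):
        c = cloud([0, 1, 1], [0, 1, -1], [0, 2, 0.5], [0, 2, -0.5])
        assert circular_asymmetry_index(c, IDENTITY_FRAME) == 0.0

    def test_two_one_imbalance_hand_value(self):
        # centred e3-components {+1, +1, -2}: signs {+, +, -} -> |2-1|/3
        c = cloud([0, 1, 1], [0, -1, 1], [0, 0.5, -2])
        assert circular_asymmetry_index(c, IDENTITY_FRAME) == \
            pytest.approx(1.0 / 3.0)

    def test_seven_three_imbalance(self):
        pts = [[0, np.cos(t), 0.5] for t in range(7)]  # z>0 -> sign +
        pts += [[0, np.cos(t), -0.5] for t in range(3)]
        assert circular_asymmetry_index(PointCloud(np.array(pts)),
                                        IDENTITY_FRAME) == pytest.approx(0.4)


class TestMorphometricEllipticity:
    def test_isotropic_cube_is_one(self, cube_corners):
        frame = principal_frame(cube_corners)
        assert morphometric_ellipticity(cube_corners, frame) == \
            pytest.approx(1.0)

    def test_recovers_gaussian_axis_ratio(self):
        c = random_cloud(20000, seed=11, sds=(3.0, 1.0, 1.0))
        frame = principal_frame(c)
        assert morphometric_ellipticity(c, frame) == pytest.approx(3.0,
                                                                   abs=0.1)

    def test_planar_ring_degenerate(self):
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        ring = PointCloud(np.column_stack([np.cos(theta), np.sin(theta),
                                           np.zeros_like(theta)]))
        with pytest.raises(DegenerateGeometryError, match="minor axis"):
            morphometric_ellipticity(ring, principal_frame(ring))


class TestFractalDimension:
    def test_insufficient_scales_raises(self):
        c = PointCloud(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(DegenerateGeometryError, match="scale"):
            fractal_dimension(c, min_scales=30)

    def test_line_dimension(self):
        pts = np.column_stack([np.linspace(0, 100, 1024),
                               np.zeros(1024), np.zeros(1024)])
        fd, series = fractal_dimension(PointCloud(pts))
        assert fd == pytest.approx(1.0, abs=0.15)
        assert np.all(np.diff(series.scales) < 0)
        assert np.all(np.diff(series.counts) > 0)


class TestRadialDistribution:
    def test_counts_conserved(self):
        c = random_cloud(500, seed=13)
        prof = radial_distribution(c)
        assert prof.counts.sum() == c.n

    def test_thin_shell_concentrates_in_one_bin(self):
        rng = np.random.default_rng(14)
        z = rng.uniform(-1, 1, 100)
        phi = rng.uniform(0, 2 * np.pi, 100)
        r = np.sqrt(1 - z ** 2)
        half = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        # antipodal pairing pins the centroid exactly at the sphere centre
        shell = 7.0 * np.vstack([half, -half])
        prof = radial_distribution(PointCloud(shell), n_bins=10)
        assert prof.counts[-1] == 200
        assert prof.counts[:-1].sum() == 0

    def test_rdf_heterogeneity_hand_value(self):
        prof = radial_distribution(random_cloud(100, seed=15))
        # two occupied bins with g {1, 3}: population CV = 1/2
        prof.counts = np.array([5, 5] + [0] * (prof.n_bins - 2))
        prof.g = np.array([1.0, 3.0] + [0.0] * (prof.n_bins - 2))
        assert rdf_heterogeneity(prof) == pytest.approx(0.5)

    def test_single_occupied_bin_insufficient(self):
        prof = radial_distribution(random_cloud(100, seed=16))
        prof.counts = np.array([100] + [0] * (prof.n_bins - 1))
        with pytest.raises(DegenerateGeometryError, match="profile"):
            rdf_heterogeneity(prof)

    def test_uniform_ball_unit_density(self):
        pts = uniform_ball(100000, np.random.default_rng(0))
        prof = radial_distribution(PointCloud(pts), n_bins=20)
        rel = prof.bin_centers / prof.r_max
        interior = (rel >= 0.2) & (rel <= 0.8)
        assert np.all(np.abs(prof.g[interior] - 1.0) < 0.05)


class TestScalingLaws:
    @pytest.mark.parametrize("lam", [0.5, 2.0, 10.0])
    def test_length_and_area_scaling(self, lam):
        c = random_cloud(120, seed=17)
        scaled = PointCloud(c.coords * lam)
        f, fs = principal_frame(c), principal_frame(scaled)
        assert radius_of_gyration(scaled) == \
            pytest.approx(lam * radius_of_gyration(c))
        assert helical_chirality_index(scaled, fs) == \
            pytest.approx(lam ** 2 * helical_chirality_index(c, f))
        for fn in (geometric_asymmetry_index,):
            assert fn(scaled) == pytest.approx(fn(c))
        for fn in (spatial_orientation_chirality, axial_chirality_index,
                   circular_asymmetry_index, morphometric_ellipticity):
            assert fn(scaled, fs) == pytest.approx(fn(c, f))
        fd_ref, _ = fractal_dimension(c)
        fd_scaled, _ = fractal_dimension(scaled)
        assert fd_scaled == pytest.approx(fd_ref, abs=1e-9)


class TestComputeAll:
    def test_helix_yields_full_vector(self, helix_model):
        vec = compute_all(helix_model)
        assert vec.missing == {}
        for name, value in vec.values.items():
            assert value is not None and np.isfinite(value), name

    def test_collinear_structure_partial_vector(self):
        pts = np.column_stack([np.linspace(0, 50, 64),
                               np.zeros(64), np.zeros(64)])
        vec = compute_all(from_coords(pts, "line"))
        assert vec.values["cm"] == pytest.approx(0.0)
        assert vec.values["me"] is None
        assert "minor axis" in vec.missing["me"]
        assert vec.values["rg"] is not None

    def test_single_atom_structure(self):
        vec = compute_all(from_coords(np.array([[1.0, 2.0, 3.0]]), "pt"))
        assert vec.values["rg"] == 0.0
        for name in ("soc", "hci", "aci", "cai", "me"):
            assert vec.values[name] is None


class TestDescriptorExtractor:
    def test_transform_returns_fixed_columns(self, helix_model):
        from memchiral.descriptors import DESCRIPTOR_NAMES, DescriptorExtractor
        ex = DescriptorExtractor()
        df = ex.fit_transform([helix_model])
        assert list(df.columns) == list(DESCRIPTOR_NAMES)
        assert df.index.tolist() == [helix_model.id]

    def test_get_set_params_round_trip(self):
        from memchiral.descriptors import DescriptorExtractor
        ex = DescriptorExtractor()
        params = ex.get_params()
        ex.set_params(rdf_bins=33)
        assert ex.get_params()["rdf_bins"] == 33
        with pytest.raises(ValueError):
            ex.set_params(bogus=1)
        params.pop("rdf_bins")
        for key, value in params.items():
            assert ex.get_params()[key] == value
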