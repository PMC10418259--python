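"""Principal axes, vectors, projected angles, superposition, RMSF."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dynmech import geometry as g
from dynmech.structure import TrajectoryFrames
from dynmech.synthetic import (
    ToyComplexSpec,
    TrajectorySimParams,
    generate_toy_complex,
    generate_trajectory,
    toy_reference_geometry,
)


@pytest.fixture(scope="module")
def ref():
    return toy_reference_geometry()


class TestPrincipalAxes:
    def test_pa1_is_construction_long_axis(self, toy, ref):
        axes = g.principal_axes(toy)
        assert np.allclose(axes.pa1, ref["long_axis"], atol=1e-9)
        assert np.allclose(axes.pa2, ref["radial_axis"], atol=1e-9)

    def test_pa2_points_radially_toward_anchor(self, toy):
        axes = g.principal_axes(toy)
        anchor = toy.coords[[toy.label_index("A3295"), toy.label_index("W3395")]].mean(0)
        radial = anchor - axes.origin
        radial -= radial @ axes.pa1 * axes.pa1
        assert np.dot(axes.pa2, radial / np.linalg.norm(radial)) == pytest.approx(1.0)

    def test_right_handed_orthonormal(self, toy):
        axes = g.principal_axes(toy)
        m = np.vstack([axes.pa1, axes.pa2, axes.pa3])
        assert np.allclose(m @ m.T, np.eye(3), atol=1e-12)
        assert np.dot(np.cross(axes.pa1, axes.pa2), axes.pa3) == pytest.approx(1.0)

    def test_rotation_equivariance(self, toy):
        rot = Rotation.random(rng=np.random.default_rng(0))
        rotated = toy.with_coords(rot.apply(toy.coords))
        a0 = g.principal_axes(toy)
        a1 = g.principal_axes(rotated)
        for name in ("pa1", "pa2", "pa3"):
            assert np.allclose(
                getattr(a1, name), rot.apply(getattr(a0, name)), atol=1e-9
            )

    def test_degenerate_cross_section_rejected(self):
        spec = ToyComplexSpec(slab_half_xy=(10.0, 10.0 * np.sqrt(2.0 / 3.0)))
        with pytest.raises(g.DegenerateGeometryError):
            generate_toy_complex(spec)


class TestVectors:
    def test_mtbd_vector_matches_construction(self, toy, ref):
        assert np.allclose(g.mtbd_vector(toy), ref["mtbd_vector"], atol=1e-12)

    def test_translation_invariance(self, toy):
        shifted = toy.coords + np.array([5.0, -3.0, 11.0])
        assert np.allclose(g.mtbd_vector(toy, shifted), g.mtbd_vector(toy), atol=1e-12)

    def test_rotation_equivariance(self, toy):
        rot = Rotation.random(rng=np.random.default_rng(1))
        assert np.allclose(
            g.mtbd_vector(toy, rot.apply(toy.coords)),
            rot.apply(g.mtbd_vector(toy)),
            atol=1e-9,
        )

    def test_missing_label_named_in_error(self, toy):
        bare = toy.with_coords(toy.coords)
        bare.labels = {}
        with pytest.raises(g.MissingAtomError, match="A3295"):
            g.mtbd_vector(bare)

    def test_stalk_vector_identity_reference(self, toy, ref):
        assert np.allclose(g.stalk_vector(toy, None, toy), ref["stalk_vector"], atol=1e-9)

    def test_stalk_vector_rotation_equivariance(self, toy):
        rot = Rotation.random(rng=np.random.default_rng(2))
        rotated = rot.apply(toy.coords)
        v_ref = g.stalk_vector(toy, None, toy)
        v_rot = g.stalk_vector(toy, rotated, toy)
        assert np.allclose(v_rot, rot.apply(v_ref), atol=1e-8)


class TestProjectedAngle:
    def test_reference_axis_maps_to_zero(self, toy):
        axes = g.principal_axes(toy)
        assert g.projected_angle(axes.pa2, axes, "PA2-PA3", "PA2") == pytest.approx(0.0)

    def test_rigid_tilt_changes_angle_by_tilt(self, toy):
        axes = g.principal_axes(toy)
        for tilt in (-7.9, 11.5, 91.0):
            rot = Rotation.from_rotvec(np.deg2rad(tilt) * axes.pa1)
            v = rot.apply(g.mtbd_vector(toy))
            angle = g.projected_angle(v, axes, "PA2-PA3", "PA2")
            assert angle == pytest.approx(tilt, abs=1e-6)

    def test_normal_vector_rejected(self, toy):
        axes = g.principal_axes(toy)
        with pytest.raises(g.DegenerateGeometryError):
            g.projected_angle(axes.pa1, axes, "PA2-PA3", "PA2")

    def test_reference_must_lie_in_plane(self, toy):
        axes = g.principal_axes(toy)
        with pytest.raises(ValueError):
            g.projected_angle(axes.pa2, axes, "PA2-PA3", "PA1")


class TestSuperimpose:
    def test_identity(self, rng):
        coords = rng.normal(size=(30, 3))
        tr = g.superimpose(coords, coords)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-9)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_transform(self, rng):
        coords = rng.normal(size=(40, 3)) * 10
        rot = Rotation.random(rng=rng)
        moved = rot.apply(coords) + np.array([1.0, -2.0, 3.0])
        tr = g.superimpose(coords, moved)
        assert tr.rmsd < 1e-9
        assert np.allclose(tr.apply(coords), moved, atol=1e-8)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0)

    def test_rotation_always_proper(self, rng):
        for _ in range(20):
            a = rng.normal(size=(10, 3))
            b = rng.normal(size=(10, 3))
            assert np.linalg.det(g.superimpose(a, b).rotation) == pytest.approx(1.0)

    def test_collinear_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(g.DegenerateGeometryError):
            g.superimpose(line, line)

    def test_beats_random_rotations(self, rng):
        a = rng.normal(size=(25, 3)) * 5
        b = rng.normal(size=(25, 3)) * 5
        best = g.superimpose(a, b)
        ac = a - a.mean(0)
        bc = b - b.mean(0)
        n = a.shape[0]
        for _ in range(200):
            r = Rotation.random(rng=rng)
            rmsd = np.sqrt(np.sum((bc - r.apply(ac)) ** 2) / n)
            assert best.rmsd <= rmsd + 1e-12


class TestAngleSeries:
    def test_noise_free_tilt_recovered_exactly(self, toy):
        params = TrajectorySimParams(
            n_frames=5, tilt_means=(11.5,), tilt_sds=(0.0,), tilt_weights=(1.0,), seed=0
        )
        traj = generate_trajectory(toy, params)
        series = g.mtbd_angle_series(toy, traj)
        assert np.allclose(series.angles, 11.5, atol=1e-6)

    def test_literal_methods_plane_switch(self, toy):
        traj = generate_trajectory(toy, TrajectorySimParams(n_frames=2, seed=0))
        series = g.mtbd_angle_series(toy, traj, literal_methods=True)
        assert series.plane == "PA1-PA2"
        # unperturbed MTBD vector is along PA2, so the literal projection
        # also reads zero
        assert np.allclose(series.angles, 0.0, atol=1e-9)

    def test_single_peak_fit_near_zero(self, toy):
        params = TrajectorySimParams(
            n_frames=800, tilt_means=(0.0,), tilt_sds=(2.0,), tilt_weights=(1.0,), seed=1
        )
        series = g.mtbd_angle_series(toy, generate_trajectory(toy, params))
        fit = g.angle_histogram_fit(series, n_peaks=1)
        assert fit.means[0] == pytest.approx(0.0, abs=0.2)
        assert fit.weights.sum() == pytest.approx(1.0)

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError, match="100"):
            g.angle_histogram_fit(np.zeros(50), n_peaks=1)


class TestFluctuations:
    def test_identical_frames_zero_rmsf(self, toy):
        traj = TrajectoryFrames(coords=np.repeat(toy.coords[None], 4, axis=0))
        profile = g.fluctuation_profile(traj, toy)
        assert all(v == 0.0 for v in profile.per_residue_rmsf.values())

    def test_isotropic_noise_rmsf_sigma_sqrt3(self, toy):
        sigma = 0.5
        params = TrajectorySimParams(
            n_frames=3000,
            per_residue_noise_sd=sigma,
            noise_chains=("mtbd", "stalk"),
            seed=7,
        )
        traj = generate_trajectory(toy, params)
        profile = g.fluctuation_profile(traj, toy)
        mean = profile.mean_rmsf(("mtbd", "stalk"))
        assert mean == pytest.approx(sigma * np.sqrt(3.0), rel=0.02)
        # tubulin was noiseless, so its residues do not fluctuate
        assert profile.mean_rmsf(("alpha_tubulin",)) == pytest.approx(0.0, abs=1e-9)

    def test_fluctuation_increase_ratio(self, toy):
        base = TrajectorySimParams(
            n_frames=600, per_residue_noise_sd=0.5,
            noise_chains=("mtbd", "stalk"), seed=3,
        )
        more = TrajectorySimParams(
            n_frames=600, per_residue_noise_sd=0.5 * 1.169,
            noise_chains=("mtbd", "stalk"), seed=4,
        )
        p0 = g.fluctuation_profile(generate_trajectory(toy, base), toy)
        p1 = g.fluctuation_profile(generate_trajectory(toy, more), toy)
        increase = g.fluctuation_increase(p0, p1, ("mtbd", "stalk"))
        assert increase == pytest.approx(16.9, abs=2.0)

    def test_single_frame_rejected(self, toy):
        traj = TrajectoryFrames(coords=toy.coords[None])
        with pytest.raises(ValueError):
            g.fluctuation_profile(traj, toy)
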