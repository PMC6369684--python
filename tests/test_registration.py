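import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes

from gp_atlas import synthetic as syn
from gp_atlas.errors import RegistrationError
from gp_atlas.registration import (
    SimilarityTransform,
    SurfaceRegistration,
    compute_tre,
    fit_nonrigid,
    fit_similarity,
    select_fiducial_phases,
    transform_to_reference,
)
from gp_atlas.surface import PV_LABELS, find_junction_plane


def rotation(axis, angle):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


class TestFitSimilarity:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        sim = fit_similarity(pts, pts)
        assert np.allclose(sim.rotation, np.eye(3), atol=1e-12)
        assert sim.scale == pytest.approx(1.0)
        assert np.allclose(sim.translation, 0.0, atol=1e-12)

    def test_exact_recovery_of_similarity(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        rot = rotation([0, 0, 1], np.deg2rad(30))
        ref = 1.2 * pts @ rot.T + np.array([3.0, -1.0, 2.0])
        sim = fit_similarity(pts, ref)
        assert np.allclose(sim.rotation, rot, atol=1e-9)
        assert sim.scale == pytest.approx(1.2, abs=1e-9)
        assert np.allclose(sim.apply(pts), ref, atol=1e-9)

    def test_noisy_residual_matches_procrustes_oracle(self):
        rng = np.random.default_rng(2)
        src = rng.normal(size=(20, 3))
        rot = rotation([1, 2, 3], 0.8)
        ref = 0.9 * src @ rot.T + 5.0 + rng.normal(scale=0.05, size=(20, 3))

        sim = fit_similarity(src, ref)
        residual = np.sum((sim.apply(src) - ref) ** 2)

        # independent oracle: orthogonal Procrustes rotation on centered sets,
        # then the closed-form optimal scale/translation for that rotation
        sc, rc = src - src.mean(0), ref - ref.mean(0)
        r_opt, _ = orthogonal_procrustes(sc, rc)
        scale = np.trace(rc.T @ sc @ r_opt) / np.sum(sc**2)
        oracle = np.sum((scale * sc @ r_opt - rc) ** 2)
        assert residual == pytest.approx(oracle, rel=1e-9)

    def test_collinear_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(RegistrationError, match="collinear"):
            fit_similarity(line, line + 1.0)

    def test_too_few_points(self):
        with pytest.raises(RegistrationError, match="at least 3"):
            fit_similarity(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_random_similarity_recovery_sweep(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            src = rng.normal(scale=10, size=(8, 3))
            rot = rotation(rng.normal(size=3), rng.uniform(0, np.pi))
            s = rng.uniform(0.5, 2.0)
            t = rng.uniform(-20, 20, size=3)
            sim = fit_similarity(src, s * src @ rot.T + t)
            assert np.allclose(sim.rotation, rot, atol=1e-9)
            assert sim.scale == pytest.approx(s, abs=1e-9)
            assert np.allclose(sim.translation, t, atol=1e-8)


class TestThinPlateSpline:
    def test_zero_displacement_is_identity(self):
        rng = np.random.default_rng(4)
        ctrl = rng.normal(size=(15, 3))
        warp = fit_nonrigid(ctrl, ctrl)
        q = rng.normal(size=(40, 3))
        assert np.allclose(warp(q), q, atol=1e-9)

    def test_translation_reproduced_everywhere(self):
        rng = np.random.default_rng(5)
        ctrl = rng.normal(size=(10, 3))
        shift = np.array([2.0, -1.0, 0.5])
        warp = fit_nonrigid(ctrl, ctrl + shift)
        q = rng.normal(scale=5, size=(50, 3))
        assert np.allclose(warp(q), q + shift, atol=1e-8)

    def test_affine_reproduced_everywhere(self):
        rng = np.random.default_rng(6)
        ctrl = rng.normal(size=(12, 3))
        a = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        warp = fit_nonrigid(ctrl, ctrl @ a.T + b)
        q = rng.normal(scale=3, size=(50, 3))
        assert np.allclose(warp(q), q @ a.T + b, atol=1e-7)

    def test_interpolates_landmarks_exactly(self):
        rng = np.random.default_rng(7)
        ctrl = rng.normal(scale=10, size=(20, 3))
        target = ctrl + rng.normal(scale=2, size=(20, 3))
        warp = fit_nonrigid(ctrl, target)
        assert np.allclose(warp(ctrl), target, atol=1e-6)

    def test_coincident_landmarks_rejected(self):
        ctrl = np.zeros((4, 3))
        ctrl[1:] = np.eye(3)
        ctrl[3] = ctrl[0]
        with pytest.raises(RegistrationError, match="coincident"):
            fit_nonrigid(ctrl, ctrl + 1.0)

    def test_smooth_deformation_generalizes(self, reference_shell):
        # landmarks sampled from a known smooth deformation; unseen surface
        # points must map back within 1.5 mm median
        shell = syn.make_patient_shell(reference_shell, deformation_scale_mm=2.5, seed=9)
        rng = np.random.default_rng(10)
        idx = rng.choice(len(reference_shell.vertices), size=60, replace=False)
        ref_pts = reference_shell.vertices[idx]
        pat_pts = shell.forward(ref_pts)
        warp = fit_nonrigid(pat_pts, ref_pts)

        unseen = rng.choice(
            np.setdiff1d(np.arange(len(reference_shell.vertices)), idx), size=400
        )
        mapped = warp(shell.forward(reference_shell.vertices[unseen]))
        err = np.linalg.norm(mapped - reference_shell.vertices[unseen], axis=1)
        assert np.median(err) < 1.5


def toy_registration(held_src, held_ref):
    rng = np.random.default_rng(11)
    used_src = rng.normal(scale=10, size=(8, 3))
    return SurfaceRegistration(
        source_id="s",
        reference_id="r",
        similarity=SimilarityTransform.identity(),
        warp=fit_nonrigid(used_src, used_src),
        used_source=used_src,
        used_reference=used_src,
        held_out_source=np.atleast_2d(held_src),
        held_out_reference=np.atleast_2d(held_ref),
    )


class TestTRE:
    def test_identity_is_zero(self):
        pts = np.random.default_rng(12).normal(scale=8, size=(5, 3)) + 30
        reg = toy_registration(pts, pts)
        assert compute_tre(reg) == pytest.approx(0.0, abs=1e-9)

    def test_single_pair_displaced_3mm(self):
        p = np.array([40.0, 0.0, 0.0])
        reg = toy_registration(p, p + [0.0, 3.0, 0.0])
        assert compute_tre(reg) == pytest.approx(3.0, abs=1e-9)

    def test_matches_distance_sum_oracle(self):
        rng = np.random.default_rng(13)
        src = rng.normal(scale=10, size=(7, 3)) + 50
        ref = src + rng.normal(scale=2, size=(7, 3))
        reg = toy_registration(src, ref)
        oracle = sum(
            float(np.sqrt(np.sum((s - r) ** 2))) for s, r in zip(src, ref)
        ) / len(src)
        assert compute_tre(reg) == pytest.approx(oracle, rel=1e-12)

    def test_empty_held_out_rejected(self):
        reg = toy_registration(np.zeros((1, 3)), np.zeros((1, 3)))
        reg.held_out_source = np.zeros((0, 3))
        reg.held_out_reference = np.zeros((0, 3))
        with pytest.raises(RegistrationError, match="empty"):
            compute_tre(reg)

    def test_invariant_to_common_rigid_motion(self, reference_shell):
        shell = syn.make_patient_shell(reference_shell, deformation_scale_mm=2.0, seed=14)
        reg = _register_cached(shell.surface, reference_shell)
        tre0 = compute_tre(reg)

        rot = rotation([1, 1, 0], 0.5)
        shift = np.array([10.0, -5.0, 3.0])
        moved_src = shell.surface.transformed(rot, shift)
        moved_ref = reference_shell.transformed(rot, shift)
        src_rings = {pv: find_junction_plane(moved_src, pv) for pv in PV_LABELS}
        ref_rings = {pv: find_junction_plane(moved_ref, pv) for pv in PV_LABELS}
        sel = select_fiducial_phases(
            moved_src, moved_ref, grid_steps=8,
            source_rings=src_rings, reference_rings=ref_rings,
        )
        # same optimum up to discretization of rings under the motion
        assert sel.objective_tre_mm == pytest.approx(tre0, abs=0.25)


_REG_CACHE = {}


def _register_cached(source, reference):
    key = (source.surface_id, id(reference))
    if key not in _REG_CACHE:
        sel = select_fiducial_phases(source, reference, grid_steps=8)
        _REG_CACHE[key] = sel.registration
    return _REG_CACHE[key]


class TestTransformToReference:
    def test_used_landmark_maps_to_its_pair(self, reference_shell):
        shell = syn.make_patient_shell(reference_shell, deformation_scale_mm=2.0, seed=14)
        reg = _register_cached(shell.surface, reference_shell)
        mapped, dist = transform_to_reference(
            reg, reg.used_source, reference_shell
        )
        assert np.allclose(mapped, reg.used_reference, atol=0.2)
        assert np.all(dist < 0.2)

    def test_identity_leaves_points_in_place(self, reference_shell):
        pts = reference_shell.vertices[::200]
        reg = toy_registration(pts, pts)
        mapped, dist = transform_to_reference(reg, pts, reference_shell)
        assert np.allclose(mapped, pts, atol=1e-8)
        assert np.all(dist < 1e-8)

    def test_synthetic_truth_within_3mm(self, reference_shell):
        shell = syn.make_patient_shell(
            reference_shell, deformation_scale_mm=3.0, seed=15, patient_id="p15"
        )
        reg = _register_cached(shell.surface, reference_shell)
        sites_ref = syn.sample_sites(reference_shell, 60, seed=16)
        mapped, _ = transform_to_reference(reg, shell.forward(sites_ref), reference_shell)
        err = np.linalg.norm(mapped - sites_ref, axis=1)
        assert np.mean(err) < 3.0


class TestPhaseSelection:
    def test_self_registration_is_exact_at_zero_phase(self, reference_shell):
        rings = {pv: find_junction_plane(reference_shell, pv) for pv in PV_LABELS}
        sel = select_fiducial_phases(
            reference_shell, reference_shell, grid_steps=4,
            source_rings=rings, reference_rings=rings,
        )
        assert sel.objective_tre_mm == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sel.phases, 0.0)

    def test_recovers_constructed_ring_rotation(self, reference_shell):
        # rotate the reference landmark rings in-plane by a known offset;
        # the selected source phases must compensate within one grid step
        rings = {pv: find_junction_plane(reference_shell, pv) for pv in PV_LABELS}
        n, grid = 8, 8
        period = 2 * np.pi / n
        delta = np.array([0.11, 0.23, 0.05, 0.17])
        sel = select_fiducial_phases(
            reference_shell, reference_shell, n_per_ring=n, grid_steps=grid,
            reference_phases=delta, source_rings=rings, reference_rings=rings,
        )
        step = period / grid
        err = np.abs(np.angle(np.exp(1j * (sel.phases - delta) * n))) / n
        assert np.all(err <= step + 1e-9)

    def test_bad_grid_rejected(self, reference_shell):
        with pytest.raises(RegistrationError, match="grid_steps"):
            select_fiducial_phases(reference_shell, reference_shell, grid_steps=1)


def test_registration_json_round_trip(tmp_path, reference_shell):
    shell = syn.make_patient_shell(reference_shell, deformation_scale_mm=2.0, seed=14)
    reg = _register_cached(shell.surface, reference_shell)
    reg.save(tmp_path / "reg.json")
    back = SurfaceRegistration.load(tmp_path / "reg.json")
    pts = reference_shell.vertices[:25]
    assert np.allclose(back.map_points(pts), reg.map_points(pts), atol=1e-9)
    assert back.tre_mm == pytest.approx(reg.tre_mm, rel=1e-9)
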