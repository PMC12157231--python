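"""Geometry engine: Procrustes, landmark alignment, mirroring, fields."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palsy3d.capture import EXPRESSIONS, ExpressionCapture, reflect_lateralize
from palsy3d.mesh import (
    CorrespondenceError,
    DegenerateConfigurationError,
    RigidTransform,
    ScalarField,
    TriangleMesh,
    asymmetry_field,
    displacement_field,
    landmark_rigid_align,
    mirror,
    partial_procrustes,
)
from palsy3d.synthetic import synthesize_capture

from conftest import make_subject, random_rigid


def rmsd(a, b):
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# partial Procrustes
# ---------------------------------------------------------------------------

class TestPartialProcrustes:
    def test_self_alignment_is_identity(self, template):
        transform, aligned = partial_procrustes(template.mesh, template.mesh)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0, atol=1e-9)
        assert rmsd(aligned.vertices, template.mesh.vertices) < 1e-9

    def test_recovers_arbitrary_rigid_motion(self, template, rng):
        for _ in range(5):
            T = random_rigid(rng)
            moved = template.mesh.transformed(T)
            _, aligned = partial_procrustes(moved, template.mesh)
            assert rmsd(aligned.vertices, template.mesh.vertices) < 1e-6

    def test_matches_brute_force_grid_search(self):
        """Single-axis toy problem against a 0.1-degree exhaustive search."""
        rng = np.random.default_rng(3)
        pts = np.array([[10.0, 0, 0], [0, 8.0, 0], [-6.0, -4.0, 0], [2.0, 3.0, 0]])
        true_angle = np.deg2rad(23.7)
        c, s = np.cos(true_angle), np.sin(true_angle)
        Rz = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        moved = pts @ Rz.T + np.array([3.0, -2.0, 0.5]) + rng.normal(0, 0.05, pts.shape)

        # oracle: grid over the single rotation angle, optimal translation in
        # closed form (centroid match) for each candidate
        grid = np.deg2rad(np.arange(0.0, 360.0, 0.1))
        best_angle, best_cost = None, np.inf
        for a in grid:
            ca, sa = np.cos(a), np.sin(a)
            R = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
            rot = moved @ R.T
            resid = (pts - pts.mean(0)) - (rot - rot.mean(0))
            cost = np.sum(resid**2)
            if cost < best_cost:
                best_cost, best_angle = cost, a

        faces = np.array([[0, 1, 2], [1, 2, 3]])
        transform, _ = partial_procrustes(
            TriangleMesh(moved, faces), TriangleMesh(pts, faces)
        )
        solved_angle = np.arctan2(transform.rotation[1, 0], transform.rotation[0, 0]) % (
            2 * np.pi
        )
        assert abs(solved_angle - best_angle) <= np.deg2rad(0.1) + 1e-9

    def test_preserves_centroid_size(self, template, rng):
        T = random_rigid(rng)
        moved = template.mesh.transformed(T)
        _, aligned = partial_procrustes(moved, template.mesh)
        assert aligned.centroid_size == pytest.approx(moved.centroid_size, rel=1e-9)

    def test_invariant_to_rigid_pretransform(self, template, rng):
        target = template.mesh
        moving = TriangleMesh(
            target.vertices + rng.normal(0, 1.0, target.vertices.shape), target.faces
        )
        _, aligned1 = partial_procrustes(moving, target)
        _, aligned2 = partial_procrustes(moving.transformed(random_rigid(rng)), target)
        assert rmsd(aligned1.vertices, aligned2.vertices) < 1e-6

    def test_vertex_count_mismatch_raises(self, template):
        small = TriangleMesh(template.mesh.vertices[:10], np.array([[0, 1, 2]]))
        with pytest.raises(CorrespondenceError):
            partial_procrustes(small, template.mesh)

    def test_degenerate_configuration_raises(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        faces = np.array([[0, 1, 2]])
        with pytest.raises(DegenerateConfigurationError):
            partial_procrustes(TriangleMesh(line, faces), TriangleMesh(line + 1.0, faces))


# ---------------------------------------------------------------------------
# landmark alignment
# ---------------------------------------------------------------------------

class TestLandmarkAlign:
    def test_identity_for_identical_meshes(self, template):
        transform, _ = landmark_rigid_align(
            template.mesh, template.mesh, template.landmark_indices
        )
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0, atol=1e-9)

    def test_removes_pure_head_motion(self, template, rng):
        """Peak = rigidly moved rest -> alignment restores rest exactly."""
        rest = template.mesh
        peak = rest.transformed(random_rigid(rng))
        _, aligned = landmark_rigid_align(peak, rest, template.landmark_indices)
        assert np.abs(aligned.vertices - rest.vertices).max() < 1e-6

    def test_matches_three_point_kabsch_oracle(self, template, rng):
        """Expression + head motion: landmark residual equals the closed-form
        3-point orthogonal Procrustes residual computed independently."""
        from scipy.spatial.transform import Rotation

        rest = template.mesh
        idx = np.array(template.landmark_indices)
        deform = rng.normal(0, 0.5, rest.vertices.shape)
        peak = TriangleMesh(rest.vertices + deform, rest.faces).transformed(
            random_rigid(rng)
        )
        _, aligned = landmark_rigid_align(peak, rest, idx)
        residual = np.linalg.norm(aligned.vertices[idx] - rest.vertices[idx])

        # independent oracle: scipy's Kabsch (align_vectors) on the 3 pairs
        P, Q = peak.vertices[idx], rest.vertices[idx]
        rot, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        fit = (P - P.mean(0)) @ rot.as_matrix().T + Q.mean(0)
        oracle_residual = np.linalg.norm(fit - Q)
        assert residual == pytest.approx(oracle_residual, abs=1e-8)

    def test_reference_is_untouched(self, template, rng):
        rest = template.mesh.copy()
        before = rest.vertices.copy()
        peak = template.mesh.transformed(random_rigid(rng))
        landmark_rigid_align(peak, rest, template.landmark_indices)
        assert np.array_equal(rest.vertices, before)

    def test_collinear_landmarks_raise(self, template):
        verts = template.mesh.vertices.copy()
        i, j, k = template.landmark_indices
        verts[j] = verts[i] + 1.0
        verts[k] = verts[i] + 2.0
        bad = TriangleMesh(verts, template.mesh.faces)
        with pytest.raises(DegenerateConfigurationError):
            landmark_rigid_align(bad, bad, (i, j, k))


# ---------------------------------------------------------------------------
# mirroring and asymmetry
# ---------------------------------------------------------------------------

class TestMirror:
    def test_involution(self, template, rng):
        mesh = TriangleMesh(
            template.mesh.vertices + rng.normal(0, 2.0, (template.n_vertices, 3)),
            template.mesh.faces,
        )
        twice = mirror(mirror(mesh, template), template)
        assert np.array_equal(twice.vertices, mesh.vertices)

    def test_symmetric_template_is_fixed_point(self, template):
        mirrored = mirror(template.mesh, template)
        assert np.abs(mirrored.vertices - template.mesh.vertices).max() < 1e-9

    def test_single_vertex_bump_lands_on_pair(self, template):
        left = int(np.flatnonzero(template.mesh.vertices[:, 0] > 5)[0])
        pair = int(template.symmetry_pairs[left])
        verts = template.mesh.vertices.copy()
        verts[left, 0] += 2.0
        mirrored = mirror(TriangleMesh(verts, template.mesh.faces), template)
        delta = mirrored.vertices - template.mesh.vertices
        assert delta[pair, 0] == pytest.approx(-2.0)
        moved = np.flatnonzero(np.abs(delta).max(axis=1) > 1e-12)
        assert list(moved) == [pair]


class TestAsymmetryField:
    def test_zero_for_symmetric_mesh(self, template):
        field = asymmetry_field(template.mesh, template)
        assert field.values.max() < 1e-9

    def test_left_right_pairing_symmetry(self, template, rng):
        mesh = TriangleMesh(
            template.mesh.vertices + rng.normal(0, 1.5, (template.n_vertices, 3)),
            template.mesh.faces,
        )
        field = asymmetry_field(mesh, template)
        assert np.abs(field.values - field.values[template.symmetry_pairs]).max() < 1e-6

    def test_matches_brute_force_recomputation(self, template, rng):
        """Independent oracle: explicit reflection, explicit Kabsch via scipy,
        explicit per-vertex distance loop."""
        from scipy.spatial.transform import Rotation

        mesh = TriangleMesh(
            template.mesh.vertices + rng.normal(0, 1.0, (template.n_vertices, 3)),
            template.mesh.faces,
        )
        field = asymmetry_field(mesh, template)

        refl = mesh.vertices * np.array([-1.0, 1.0, 1.0])
        refl = refl[template.symmetry_pairs]
        rot, _ = Rotation.align_vectors(
            mesh.vertices - mesh.vertices.mean(0), refl - refl.mean(0)
        )
        aligned = (refl - refl.mean(0)) @ rot.as_matrix().T + mesh.vertices.mean(0)
        expected = np.array(
            [np.linalg.norm(mesh.vertices[i] - aligned[i]) for i in range(len(aligned))]
        )
        assert np.abs(field.values - expected).max() < 1e-8

    def test_invariant_under_rigid_motion(self, template, rng):
        mesh = TriangleMesh(
            template.mesh.vertices + rng.normal(0, 1.0, (template.n_vertices, 3)),
            template.mesh.faces,
        )
        f1 = asymmetry_field(mesh, template)
        f2 = asymmetry_field(mesh.transformed(random_rigid(rng)), template)
        assert np.abs(f1.values - f2.values).max() < 1e-6

    def test_single_bump_yields_equal_paired_values(self, template):
        left = int(np.flatnonzero(template.mesh.vertices[:, 0] > 10)[0])
        pair = int(template.symmetry_pairs[left])
        verts = template.mesh.vertices.copy()
        verts[left] += np.array([0.0, 0.0, 3.0])
        field = asymmetry_field(TriangleMesh(verts, template.mesh.faces), template)
        assert field.values[left] == pytest.approx(field.values[pair], rel=1e-9)
        assert field.values[left] > 0.5


class TestDisplacementField:
    def test_zero_when_peak_equals_rest(self, template):
        field = displacement_field(template.mesh, template.mesh)
        assert np.all(field.values == 0)

    def test_single_vertex_shift(self, template):
        verts = template.mesh.vertices.copy()
        verts[7] += np.array([0.0, 3.0, 0.0])
        field = displacement_field(template.mesh, TriangleMesh(verts, template.mesh.faces))
        assert field.values[7] == pytest.approx(3.0)
        assert np.sum(field.values > 0) == 1

    def test_matches_naive_loop_oracle(self, template, rng):
        peak = TriangleMesh(
            template.mesh.vertices + rng.normal(0, 1.0, (template.n_vertices, 3)),
            template.mesh.faces,
        )
        field = displacement_field(template.mesh, peak)
        for i in rng.choice(template.n_vertices, 25, replace=False):
            d = float(np.linalg.norm(peak.vertices[i] - template.mesh.vertices[i]))
            assert field.values[i] == pytest.approx(d, abs=1e-12)


# ---------------------------------------------------------------------------
# lateralization
# ---------------------------------------------------------------------------

class TestReflectLateralize:
    def _capture(self, template, laterality):
        subject = make_subject(2, laterality)
        return synthesize_capture(subject, EXPRESSIONS[2], template, seed=5)

    def test_right_sided_unchanged(self, template):
        cap = self._capture(template, "right")
        out = reflect_lateralize(cap, template)
        assert out is cap

    def test_left_sided_reflected_and_relabelled(self, template):
        cap = self._capture(template, "left")
        out = reflect_lateralize(cap, template)
        assert out.laterality == "right"
        expected = mirror(cap.rest, template)
        assert np.array_equal(out.rest.vertices, expected.vertices)

    def test_asymmetry_preserved_by_reflection(self, template):
        cap = self._capture(template, "left")
        out = reflect_lateralize(cap, template)
        before = asymmetry_field(cap.peak, template).values
        after = asymmetry_field(out.peak, template).values
        assert np.abs(np.sort(before) - np.sort(after)).max() < 1e-6

    def test_idempotent(self, template):
        cap = self._capture(template, "left")
        once = reflect_lateralize(cap, template)
        twice = reflect_lateralize(once, template)
        assert twice is once

    def test_unknown_laterality_rejected(self, template):
        cap = self._capture(template, "right")
        object.__setattr__(cap, "laterality", "none")  # patient w/o laterality
        with pytest.raises(ValueError):
            reflect_lateralize(cap, template)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

class TestTypes:
    def test_rigid_transform_rejects_reflection(self):
        R = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            RigidTransform(R, np.zeros(3))

    def test_rigid_transform_compose_inverse(self, rng):
        T = random_rigid(rng)
        pts = rng.normal(size=(10, 3))
        back = T.inverse().apply(T.apply(pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_scalar_field_kind_validation(self):
        with pytest.raises(ValueError):
            ScalarField(np.array([-1.0, 2.0]), kind="displacement")
        ScalarField(np.array([-1.0, 2.0]), kind="difference")  # signed ok

    def test_faces_index_validation(self):
        with pytest.raises(ValueError):
            TriangleMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_procrustes_recovery_property(self, seed):
        """Any proper rigid motion of any noisy face mesh is recovered."""
        rng = np.random.default_rng(seed)
        base = np.random.default_rng(0).normal(0, 10, (30, 3))
        faces = np.array([[0, 1, 2]])
        mesh = TriangleMesh(base, faces)
        moved = mesh.transformed(random_rigid(rng))
        _, aligned = partial_procrustes(moved, mesh)
        assert rmsd(aligned.vertices, mesh.vertices) < 1e-6
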