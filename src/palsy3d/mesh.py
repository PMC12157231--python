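"""Geometry engine for corresponded facial meshes.

All meshes of a cohort share one triangulation and one vertex ordering
(the "conformed mesh" convention): vertex ``i`` denotes the same anatomical
point on every mesh, which is what makes per-vertex displacement and
asymmetry fields meaningful.

Coordinate convention (template frame): x runs from the subject's right to
the subject's left, y from foot to head, z from the back of the head to the
front of the face.  Units are millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

AXIS_CONVENTION = "x: right-to-left, y: foot-to-head, z: back-to-front (mm)"

# degenerate iff the second-largest singular value of the centered
# cross-covariance vanishes (collinear or coincident points); planar
# configurations are rank 2 and still have a unique proper-rotation optimum
_DEGENERATE_RTOL = 1e-12


class CorrespondenceError(ValueError):
    """Meshes that are supposed to share a vertex ordering do not."""


class DegenerateConfigurationError(ValueError):
    """Point configuration does not determine a unique rigid alignment."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det -1 (reflection not allowed)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class TriangleMesh:
    """Triangle mesh with semantic vertex order (mm coordinates)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {self.faces.shape}")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("faces reference invalid vertex indices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def centroid_size(self) -> float:
        """Square root of the summed squared deviations from the centroid."""
        return float(np.linalg.norm(self.vertices - self.centroid))

    @property
    def rms_radius(self) -> float:
        """Root-mean-square distance of vertices from the centroid."""
        return self.centroid_size / np.sqrt(self.n_vertices)

    def transformed(self, transform: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(transform.apply(self.vertices), self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class ScalarField:
    """Per-vertex scalar map (mm). ``difference`` fields may be signed."""

    values: np.ndarray
    kind: str = "displacement"

    _KINDS = ("displacement", "asymmetry", "difference")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).reshape(-1)
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.kind != "difference" and self.values.size and self.values.min() < 0:
            raise ValueError(f"{self.kind} fields must be non-negative")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class GenericTemplate:
    """Bilaterally symmetric reference mesh with left-right vertex pairing.

    ``symmetry_pairs[i]`` is the vertex anatomically mirroring vertex ``i``;
    the map is an involution and midline vertices are self-paired.  The three
    landmarks are (inner eye corner left, inner eye corner right, nose tip).
    """

    mesh: TriangleMesh
    symmetry_pairs: np.ndarray
    landmark_indices: tuple[int, int, int]
    midline_vertices: frozenset[int] = field(default=None)  # type: ignore[assignment]
    axis_convention: str = AXIS_CONVENTION
    symmetry_tol: float = 1e-9

    def __post_init__(self) -> None:
        self.symmetry_pairs = np.asarray(self.symmetry_pairs, dtype=np.int64).reshape(-1)
        n = self.mesh.n_vertices
        if self.symmetry_pairs.size != n:
            raise ValueError("symmetry_pairs length must equal vertex count")
        p = self.symmetry_pairs
        if not np.array_equal(p[p], np.arange(n)):
            raise ValueError("symmetry_pairs is not an involution")
        if self.midline_vertices is None:
            self.midline_vertices = frozenset(np.flatnonzero(p == np.arange(n)).tolist())
        self.landmark_indices = tuple(int(i) for i in self.landmark_indices)
        if len(self.landmark_indices) != 3:
            raise ValueError("exactly three landmark indices required")
        if any(i < 0 or i >= n for i in self.landmark_indices):
            raise ValueError("landmark index out of range")
        v = self.mesh.vertices
        mirrored = v[p] * np.array([-1.0, 1.0, 1.0])
        err = np.abs(mirrored - v).max() if n else 0.0
        if err > self.symmetry_tol:
            raise ValueError(
                f"template is not mirror-symmetric: max deviation {err:.3g} mm"
            )

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices


def _check_correspondence(a: TriangleMesh, b: TriangleMesh) -> None:
    if a.n_vertices != b.n_vertices:
        raise CorrespondenceError(
            f"vertex counts differ: {a.n_vertices} vs {b.n_vertices}"
        )


def _kabsch(moving_pts: np.ndarray, target_pts: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid fit of ``moving_pts`` onto ``target_pts``.

    Closed form via SVD of the centered cross-covariance; reflections are
    excluded by flipping the sign of the smallest singular direction when
    needed, so the result always has det(R) = +1 and unit scale.
    """
    P = np.asarray(moving_pts, dtype=float)
    Q = np.asarray(target_pts, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if S[0] <= 0 or S[1] < _DEGENERATE_RTOL * S[0]:
        raise DegenerateConfigurationError(
            "point configuration is collinear or coincident; rotation undetermined"
        )
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


def partial_procrustes(
    moving: TriangleMesh, target: TriangleMesh
) -> tuple[RigidTransform, TriangleMesh]:
    """Partial Procrustes superimposition: rotation + translation, no scaling.

    Minimises the sum of squared distances between index-corresponded
    vertices over proper rigid motions.  Centroid size is preserved exactly
    (no scaling step), so millimetre-scale severity signal is untouched.
    """
    _check_correspondence(moving, target)
    transform = _kabsch(moving.vertices, target.vertices)
    return transform, moving.transformed(transform)


def landmark_rigid_align(
    moving: TriangleMesh,
    reference: TriangleMesh,
    landmarks: Sequence[int],
) -> tuple[RigidTransform, TriangleMesh]:
    """Rigidly align ``moving`` to ``reference`` using three landmark pairs.

    The fit is computed on the landmark triplets only (inner eye corners and
    nose tip in the default template) and then applied to the whole mesh.
    Aligning the peak-expression frame to the rest frame this way removes
    rigid head motion without letting the expression deformation itself pull
    the alignment, because the landmarks sit on regions that barely move.
    """
    _check_correspondence(moving, reference)
    idx = np.asarray(list(landmarks), dtype=np.int64)
    if idx.size != 3:
        raise ValueError("exactly three landmarks required")
    if idx.min() < 0 or idx.max() >= moving.n_vertices:
        raise ValueError("landmark index out of range")
    transform = _kabsch(moving.vertices[idx], reference.vertices[idx])
    return transform, moving.transformed(transform)


def mirror(mesh: TriangleMesh, template: GenericTemplate) -> TriangleMesh:
    """Reflect a mesh through the sagittal plane and re-index anatomically.

    The reflection is x -> -x in the template frame; vertices are then
    re-indexed through the template's symmetry pairing so that vertex ``i``
    of the mirror corresponds to the same anatomical location as vertex
    ``i`` of the input.  Applying ``mirror`` twice returns the input exactly.
    """
    if mesh.n_vertices != template.n_vertices:
        raise CorrespondenceError(
            f"mesh has {mesh.n_vertices} vertices, template {template.n_vertices}"
        )
    reflected = mesh.vertices * np.array([-1.0, 1.0, 1.0])
    return TriangleMesh(reflected[template.symmetry_pairs], mesh.faces)


def asymmetry_field(mesh: TriangleMesh, template: GenericTemplate) -> ScalarField:
    """Per-vertex distance between a mesh and its aligned mirror image.

    The mirror is superimposed onto the original with partial Procrustes and
    the Euclidean distance between corresponding vertices is reported.  A
    perfectly symmetric mesh yields an identically zero field, and the field
    always satisfies ``value(i) == value(pair(i))``: left and right carry the
    same absolute left-right discrepancy.
    """
    mirrored = mirror(mesh, template)
    _, aligned = partial_procrustes(mirrored, mesh)
    d = np.linalg.norm(mesh.vertices - aligned.vertices, axis=1)
    return ScalarField(d, kind="asymmetry")


def displacement_field(rest: TriangleMesh, peak_aligned: TriangleMesh) -> ScalarField:
    """Per-vertex movement magnitude from rest to an aligned peak frame."""
    _check_correspondence(rest, peak_aligned)
    d = np.linalg.norm(peak_aligned.vertices - rest.vertices, axis=1)
    return ScalarField(d, kind="displacement")
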