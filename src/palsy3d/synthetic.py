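"""Synthetic face template and graded unilateral-palsy cohorts.

Real dynamic-photogrammetry captures of paralysis patients are not publicly
available, so this module fabricates the whole study: a bilaterally
symmetric face-like template with dense vertex correspondence, smooth
expression displacement bases, and subjects whose voluntary movement is
attenuated on one side according to a 1-5 severity grade.

The face is a parametric half-ellipsoid with ridge/socket features rather
than an anatomical scan.  That is sufficient on purpose: the downstream
pipeline consumes only correspondence, bilateral symmetry and regional
displacement structure, none of which require realistic anatomy.

Severity model: voluntary movement on the affected side is scaled by the
attenuation law a(g) = (g - 1) / 4, so grade 5 (normal) moves fully and
grade 1 (no movement) barely moves; 10% of the suppressed movement is
redirected to the opposite side as a crude synkinesis/compensation term.
Resting tone droops on the affected side in proportion to (5 - g).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .capture import EXPRESSIONS, ExpressionCapture, ExpressionType
from .mesh import AXIS_CONVENTION, GenericTemplate, RigidTransform, TriangleMesh

# face envelope half-axes (mm): width, height, depth of the dome
_FACE_A, _FACE_B, _FACE_C = 65.0, 90.0, 55.0

#: approximate template-frame feature centres (x, y) in mm, x > 0 = subject left
FEATURES = {
    "brow": (20.0, 35.0),
    "eye": (18.0, 21.0),
    "inner_eye": (11.0, 20.0),
    "nose_tip": (0.0, -5.0),
    "cheek": (32.0, -12.0),
    "mouth_corner": (26.0, -38.0),
    "lips": (0.0, -40.0),
}


def _gauss(u: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((u - center) / sigma) ** 2)


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _apportion(weights: np.ndarray, total: int, minimum: int = 1) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` items, each row >= minimum."""
    n = weights.size
    total_free = total - minimum * n
    if total_free < 0:
        raise ValueError(f"cannot place {total} vertices on {n} rows")
    raw = weights / weights.sum() * total_free
    counts = np.floor(raw).astype(int)
    remainder = total_free - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)), kind="stable")
    counts[order[:remainder]] += 1
    return counts + minimum


def _row_xs(count: int, half_width: float) -> np.ndarray:
    """Symmetric x positions for one row; odd counts include x = 0."""
    if count == 1:
        return np.zeros(1)
    if count % 2:
        k = (count - 1) // 2
        right = np.arange(1, k + 1) * (half_width / k)
        return np.concatenate([-right[::-1], [0.0], right])
    k = count // 2
    right = (np.arange(k) + 0.5) * (half_width / k)
    return np.concatenate([-right[::-1], right])


def _face_height(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Template z profile: ellipsoid dome plus symmetric facial features."""
    dome = _FACE_C * np.sqrt(
        np.maximum(0.0, 1.0 - (x / (_FACE_A * 1.02)) ** 2 - (y / (_FACE_B * 1.02)) ** 2)
    )
    bx, by = FEATURES["brow"]
    ex, ey = FEATURES["eye"]
    nx, ny = FEATURES["nose_tip"]
    lx, ly = FEATURES["lips"]
    # even in x by explicit +/- pairing, so paired vertices get bitwise-equal z
    brow = 2.0 * (_gauss(x, bx, 12.0) + _gauss(x, -bx, 12.0)) * _gauss(y, by, 5.0)
    socket = -3.0 * (_gauss(x, ex, 8.0) + _gauss(x, -ex, 8.0)) * _gauss(y, ey, 6.0)
    nose = 10.0 * _gauss(x, nx, 7.0) * _gauss(y, ny, 14.0)
    lips = 2.0 * _gauss(x, lx, 14.0) * _gauss(y, ly, 6.0)
    return dome + brow + socket + nose + lips


def _triangulate_rows(row_index: list[np.ndarray], row_x: list[np.ndarray]) -> np.ndarray:
    """Stitch consecutive vertex rows into a triangle strip (merge walk)."""
    faces: list[tuple[int, int, int]] = []
    for a_idx, a_x, b_idx, b_x in zip(row_index, row_x, row_index[1:], row_x[1:]):
        i = j = 0
        while i < len(a_idx) - 1 or j < len(b_idx) - 1:
            advance_a = j == len(b_idx) - 1 or (
                i < len(a_idx) - 1 and a_x[i + 1] <= b_x[j + 1]
            )
            if advance_a:
                faces.append((a_idx[i], a_idx[i + 1], b_idx[j]))
                i += 1
            else:
                faces.append((a_idx[i], b_idx[j + 1], b_idx[j]))
                j += 1
    return np.asarray(faces, dtype=np.int64)


def make_template(n_vertices: int = 7859, seed: int = 0) -> GenericTemplate:
    """Build the symmetric face template with exactly ``n_vertices`` vertices.

    Vertices are laid out on horizontal rows spanning an ellipse, densities
    proportional to row width, with a small seeded surface jitter applied
    symmetrically (mirror pairs receive mirrored jitter) so the mesh is
    irregular but exactly bilaterally symmetric.  Landmarks are the vertices
    nearest the inner eye corners (a symmetric pair) and the nose tip (the
    highest-z midline vertex).
    """
    if n_vertices < 10:
        raise ValueError("need at least 10 vertices to triangulate a face")
    rng = np.random.default_rng(seed)

    n_rows = max(3, int(round(math.sqrt(n_vertices / 1.4))))
    ys = np.linspace(-0.96 * _FACE_B, 0.96 * _FACE_B, n_rows)
    widths = _FACE_A * np.sqrt(1.0 - (ys / _FACE_B) ** 2)
    counts = _apportion(widths, n_vertices)
    # the nose-tip landmark needs a midline vertex: keep >=1 odd row
    if not np.any(counts % 2):
        mid_row = len(counts) // 2
        donor = next(i for i in np.argsort(-counts) if i != mid_row)
        counts[mid_row] += 1
        counts[donor] -= 1

    xs_list, idx_list, pair_chunks = [], [], []
    start = 0
    for count, hw in zip(counts, widths):
        xs = _row_xs(int(count), hw)
        idx = np.arange(start, start + count)
        # row is sorted by x and symmetric, so the pair of local i is count-1-i
        pair_chunks.append(start + (count - 1) - np.arange(count))
        xs_list.append(xs)
        idx_list.append(idx)
        start += count

    x = np.concatenate(xs_list)
    y = np.concatenate([np.full(len(xs), yy) for xs, yy in zip(xs_list, ys)])
    z = _face_height(x, y)
    pairs = np.concatenate(pair_chunks)

    # symmetric jitter: draw for left+midline, mirror onto the right
    jitter = np.zeros((n_vertices, 3))
    left = np.flatnonzero(x > 0)
    mid = np.flatnonzero(pairs == np.arange(n_vertices))
    jitter[left] = rng.normal(0.0, 0.25, (left.size, 3))
    jitter[mid, 1:] = rng.normal(0.0, 0.25, (mid.size, 2))
    right = pairs[left]
    jitter[right] = jitter[left] * np.array([-1.0, 1.0, 1.0])

    vertices = np.column_stack([x, y, z]) + jitter
    faces = _triangulate_rows(idx_list, xs_list)
    mesh = TriangleMesh(vertices, faces)

    iex, iey = FEATURES["inner_eye"]
    d2 = (x - iex) ** 2 + (y - iey) ** 2
    d2[x <= 0] = np.inf
    lm_left = int(np.argmin(d2))
    lm_right = int(pairs[lm_left])
    nose = int(mid[np.argmax(z[mid] + jitter[mid, 2])])
    if nose in (lm_left, lm_right):
        raise ValueError("degenerate template: landmarks coincide")

    return GenericTemplate(
        mesh=mesh,
        symmetry_pairs=pairs,
        landmark_indices=(lm_left, lm_right, nose),
        axis_convention=AXIS_CONVENTION,
    )


# ---------------------------------------------------------------------------
# expression displacement bases
# ---------------------------------------------------------------------------

def _sym_blob(
    x: np.ndarray,
    y: np.ndarray,
    cx: float,
    cy: float,
    sx: float,
    sy: float,
    amp: tuple[float, float, float],
) -> np.ndarray:
    """Mirror-symmetric displacement blob at (+/-cx, cy).

    The x component is odd in x (outward/inward moves mirror), y and z are
    even, so the field respects the left-right pairing exactly.
    """
    gp = _gauss(x, cx, sx) * _gauss(y, cy, sy)
    gm = _gauss(x, -cx, sx) * _gauss(y, cy, sy)
    out = np.zeros((x.size, 3))
    out[:, 0] = amp[0] * (gp - gm)
    out[:, 1] = amp[1] * (gp + gm)
    out[:, 2] = amp[2] * (gp + gm)
    return out


def _landmark_stability_mask(template: GenericTemplate, sigma: float = 8.0) -> np.ndarray:
    """Damp displacement near the alignment landmarks.

    The inner eye corners and nose tip are usable as rigid-alignment anchors
    precisely because soft-tissue motion there is negligible; every basis is
    multiplied by this mask so the landmarks stay put during expressions.
    Built from mirrored landmark pairs, so it is exactly symmetric.
    """
    v = template.mesh.vertices
    x, y = v[:, 0], v[:, 1]
    mask = np.ones(len(v))
    for i in template.landmark_indices:
        lx, ly = v[i, 0], v[i, 1]
        r2 = (x - lx) ** 2 + (y - ly) ** 2
        mask *= 1.0 - np.exp(-0.5 * r2 / sigma**2)
    return mask


def expression_basis(
    template: GenericTemplate, expression: ExpressionType
) -> np.ndarray:
    """Per-vertex displacement vectors (mm) of a full-strength expression.

    Fields are smooth, bilaterally symmetric and localised to the relevant
    region, with peak magnitudes in the 5-10 mm range typical of voluntary
    expressions; the rest "expression" is the zero field.  All fields vanish
    at the three alignment landmarks (see :func:`_landmark_stability_mask`).
    """
    expression = ExpressionType(expression)
    v = template.mesh.vertices
    x, y = v[:, 0], v[:, 1]
    if expression is ExpressionType.REST:
        return np.zeros((template.n_vertices, 3))
    bx, by = FEATURES["brow"]
    ex, ey = FEATURES["eye"]
    cx, cy = FEATURES["cheek"]
    mx, my = FEATURES["mouth_corner"]
    lx, ly = FEATURES["lips"]
    if expression is ExpressionType.EYEBROW_RAISING:
        field = _sym_blob(x, y, bx, by, 11.0, 8.0, (0.0, 7.0, 2.0))
    elif expression is ExpressionType.EYE_CLOSURE:
        field = _sym_blob(x, y, ex + 4.0, ey + 5.0, 8.0, 5.0, (0.0, -8.0, -2.5))
    elif expression is ExpressionType.SMILING:
        field = _sym_blob(x, y, mx, my, 9.0, 8.0, (6.0, 5.0, 2.0))
    elif expression is ExpressionType.CHEEK_PUFFING:
        field = _sym_blob(x, y, cx, cy, 12.0, 14.0, (3.0, 0.0, 7.0))
    elif expression is ExpressionType.LIP_PUCKERING:
        field = _sym_blob(x, y, lx, ly, 12.0, 7.0, (0.0, 0.0, 5.0))
        # lips purse toward the midline: odd-in-x inward pull
        field[:, 0] -= 3.0 * (x / 12.0) * np.exp(-0.5 * (x / 12.0) ** 2) * _gauss(
            y, ly, 7.0
        )
    else:
        raise ValueError(f"unknown expression {expression!r}")
    return field * _landmark_stability_mask(template)[:, None]


#: region masks for sanity checks on basis localisation
def region_mask(template: GenericTemplate, region: str) -> np.ndarray:
    y = template.mesh.vertices[:, 1]
    if region == "lower_face":
        return y < -10.0
    if region == "upper_face":
        return y > 10.0
    if region == "mid_face":
        return (y >= -10.0) & (y <= 10.0)
    raise ValueError(f"unknown region {region!r}")


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

def attenuation(grade: float) -> float:
    """Movement fraction retained on the affected side: a(g) = (g - 1) / 4."""
    return (float(grade) - 1.0) / 4.0


@dataclass
class SyntheticSubject:
    """One synthetic participant: identity, laterality and per-expression severity."""

    subject_id: str
    cohort: str  # "patient" | "control"
    laterality: str  # "left" | "right" | "none"
    severities: dict[ExpressionType, float]
    shape_seed: int

    def __post_init__(self) -> None:
        if self.cohort == "control":
            if self.laterality != "none":
                raise ValueError("controls have no palsy laterality")
            bad = [g for g in self.severities.values() if g != 5]
            if bad:
                raise ValueError("controls are grade 5 (normal) on every expression")
        elif self.laterality not in ("left", "right"):
            raise ValueError("patients must have unilateral laterality")
        for g in self.severities.values():
            if not 1.0 <= float(g) <= 5.0:
                raise ValueError(f"severity {g} outside [1, 5]")


@dataclass
class CohortSpec:
    """Study-design knobs for a synthetic cohort.

    Defaults mirror the study conditions: 16 unilateral-palsy patients and
    16 healthy controls, five expressions each, integer severities, mild
    sensor noise (0.1 mm), head pose within 5 degrees / 10 mm, and low
    rater noise for the expert panels.
    """

    n_patients: int = 16
    n_controls: int = 16
    severity_choices: tuple[int, ...] = (1, 2, 3, 4, 5)
    rater_noise: float = 0.2
    sensor_noise_mm: float = 0.1
    head_pose: bool = True
    max_head_rotation_deg: float = 5.0
    max_head_translation_mm: float = 10.0
    shape_amp_mm: float = 1.5
    droop_mm_per_grade: float = 0.5
    compensation_fraction: float = 0.1
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("need at least one patient and one control")


def _shape_perturbation(
    template: GenericTemplate, shape_seed: int, amp: float
) -> np.ndarray:
    """Smooth symmetric per-subject shape offset built from mirrored blobs."""
    rng = np.random.default_rng(shape_seed)
    v = template.mesh.vertices
    x, y = v[:, 0], v[:, 1]
    out = np.zeros((len(v), 3))
    for _ in range(8):
        cx = rng.uniform(0.0, 0.8 * _FACE_A)
        cy = rng.uniform(-0.8 * _FACE_B, 0.8 * _FACE_B)
        sx = rng.uniform(10.0, 25.0)
        sy = rng.uniform(10.0, 25.0)
        a = rng.normal(0.0, amp / math.sqrt(8.0), 3)
        out += _sym_blob(x, y, cx, cy, sx, sy, (a[0], a[1], a[2]))
    return out


def _side_weight(x: np.ndarray, laterality: str, tau: float = 5.0) -> np.ndarray:
    """Smooth indicator of the affected side (x > 0 is the subject's left)."""
    if laterality == "left":
        return 1.0 / (1.0 + np.exp(-x / tau))
    if laterality == "right":
        return 1.0 / (1.0 + np.exp(x / tau))
    return np.zeros_like(x)


def _random_pose(rng: np.random.Generator, max_rot_deg: float, max_trans_mm: float) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-max_trans_mm, max_trans_mm, 3)
    return RigidTransform(R, t)


def synthesize_capture(
    subject: SyntheticSubject,
    expression: ExpressionType,
    template: GenericTemplate,
    seed: int,
    spec: CohortSpec | None = None,
) -> ExpressionCapture:
    """Generate one rest/peak capture for a subject and expression.

    rest  = template + symmetric subject shape + resting droop on the
            affected side scaled by (5 - g)
    peak  = rest + expression basis, attenuated to a(g) on the affected side
            with a small contralateral compensation term
    Both frames then receive an independent random head pose and isotropic
    sensor noise, exactly what the alignment chain must undo.
    """
    spec = spec or CohortSpec()
    expression = ExpressionType(expression)
    grade = float(subject.severities[expression])
    if not 1.0 <= grade <= 5.0:
        raise ValueError(f"severity {grade} outside [1, 5]")
    rng = np.random.default_rng(seed)
    v = template.mesh.vertices
    x, y = v[:, 0], v[:, 1]

    w_aff = _side_weight(x, subject.laterality)
    shape = _shape_perturbation(template, subject.shape_seed, spec.shape_amp_mm)

    droop = np.zeros_like(v)
    if subject.cohort == "patient":
        cxa, cya = FEATURES["cheek"]
        sag = _gauss(np.abs(x), cxa, 18.0) * _gauss(y, -25.0, 25.0)
        droop[:, 1] = -spec.droop_mm_per_grade * (5.0 - grade) * w_aff * sag

    rest_geom = v + shape + droop

    basis = expression_basis(template, expression)
    a = attenuation(grade)
    scale = 1.0 - (1.0 - a) * w_aff
    comp = spec.compensation_fraction * (1.0 - a) * (1.0 - w_aff) * (
        1.0 if subject.cohort == "patient" else 0.0
    )
    peak_geom = rest_geom + basis * (scale + comp)[:, None]

    def _observe(geom: np.ndarray) -> TriangleMesh:
        if spec.head_pose:
            pose = _random_pose(
                rng, spec.max_head_rotation_deg, spec.max_head_translation_mm
            )
            geom = pose.apply(geom)
        if spec.sensor_noise_mm > 0:
            geom = geom + rng.normal(0.0, spec.sensor_noise_mm, geom.shape)
        return TriangleMesh(geom, template.mesh.faces)

    return ExpressionCapture(
        subject_id=subject.subject_id,
        cohort=subject.cohort,
        expression=expression,
        laterality=subject.laterality,
        rest=_observe(rest_geom),
        peak=_observe(peak_geom),
    )


def make_subjects(spec: CohortSpec) -> list[SyntheticSubject]:
    """Draw the subject roster (identities, lateralities, true severities)."""
    rng = np.random.default_rng(spec.master_seed)
    subjects = []
    for i in range(spec.n_patients):
        base = int(rng.choice(spec.severity_choices))
        sev = {}
        for expr in EXPRESSIONS:
            jitter = int(rng.choice([-1, 0, 1], p=[0.2, 0.6, 0.2]))
            sev[expr] = int(np.clip(base + jitter, 1, 5))
        subjects.append(
            SyntheticSubject(
                subject_id=f"P{i:03d}",
                cohort="patient",
                laterality="left" if rng.random() < 0.5 else "right",
                severities=sev,
                shape_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    for i in range(spec.n_controls):
        subjects.append(
            SyntheticSubject(
                subject_id=f"C{i:03d}",
                cohort="control",
                laterality="none",
                severities={expr: 5 for expr in EXPRESSIONS},
                shape_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return subjects


def synthesize_cohort(
    spec: CohortSpec, template: GenericTemplate
) -> tuple[list[ExpressionCapture], dict[tuple[str, ExpressionType], float]]:
    """Generate the full cohort: one capture per subject per expression.

    Returns the captures plus the ground-truth severity of each
    (subject, expression) pair for parameter-recovery tests.  The default
    spec (16 patients + 16 controls x 5 expressions) yields 160 captures.
    """
    subjects = make_subjects(spec)
    rng = np.random.default_rng(spec.master_seed + 1)
    captures, truth = [], {}
    for subject in subjects:
        for expr in EXPRESSIONS:
            seed = int(rng.integers(0, 2**31 - 1))
            captures.append(
                synthesize_capture(subject, expr, template, seed=seed, spec=spec)
            )
            truth[(subject.subject_id, expr)] = subject.severities[expr]
    return captures, truth
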