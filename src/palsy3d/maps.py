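"""Cohort-level morphometric maps.

For each expression: the mean control movement field, the mean patient
movement field, their signed difference (patient − control; negative on the
affected right side means a movement deficit), and the mean patient
asymmetry field at peak expression.  Rendering uses the blue-to-red
convention with fixed scales of 0–10 mm for movement/asymmetry and
−5 to +5 mm for differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .capture import EXPRESSIONS, ExpressionCapture, ExpressionType, reflect_lateralize
from .mesh import (
    GenericTemplate,
    ScalarField,
    TriangleMesh,
    asymmetry_field,
    displacement_field,
    landmark_rigid_align,
    partial_procrustes,
)

MOVEMENT_RANGE = (0.0, 10.0)
DIFFERENCE_RANGE = (-5.0, 5.0)


def average_field(fields: list[ScalarField]) -> ScalarField:
    """Vertex-wise arithmetic mean of equally sized fields."""
    if not fields:
        raise ValueError("cannot average an empty list of fields")
    lengths = {len(f) for f in fields}
    if len(lengths) != 1:
        raise ValueError(f"fields have differing lengths: {sorted(lengths)}")
    values = np.mean([f.values for f in fields], axis=0)
    kind = fields[0].kind
    if kind != "difference" and values.min() < 0:
        kind = "difference"
    return ScalarField(values, kind=kind)


def difference_field(patients_mean: ScalarField, controls_mean: ScalarField) -> ScalarField:
    """Signed per-vertex difference: patient mean − control mean."""
    if len(patients_mean) != len(controls_mean):
        raise ValueError("field lengths differ")
    return ScalarField(patients_mean.values - controls_mean.values, kind="difference")


@dataclass
class CohortMapSet:
    """The four map rows for one expression."""

    expression: ExpressionType
    control_movement: ScalarField
    patient_movement: ScalarField
    movement_difference: ScalarField
    patient_asymmetry: ScalarField


def _aligned_pair(
    capture: ExpressionCapture, template: GenericTemplate
) -> tuple[TriangleMesh, TriangleMesh]:
    _, rest_aligned = partial_procrustes(capture.rest, template.mesh)
    _, peak_aligned = landmark_rigid_align(
        capture.peak, rest_aligned, template.landmark_indices
    )
    return rest_aligned, peak_aligned


def compute_cohort_maps(
    captures: list[ExpressionCapture], template: GenericTemplate
) -> dict[ExpressionType, CohortMapSet]:
    """Build all four map rows per expression from raw captures.

    Left-sided patients are mirrored first so deficits accumulate on the
    right; movement is measured after the standard alignment chain and
    asymmetry at the peak frame.  Means are taken over subjects.
    """
    per_expr: dict[ExpressionType, dict[str, list[ScalarField]]] = {
        e: {"control": [], "patient": [], "asym": []} for e in EXPRESSIONS
    }
    for capture in captures:
        capture = reflect_lateralize(capture, template)
        rest_aligned, peak_aligned = _aligned_pair(capture, template)
        movement = displacement_field(rest_aligned, peak_aligned)
        per_expr[capture.expression][capture.cohort].append(movement)
        if capture.cohort == "patient":
            per_expr[capture.expression]["asym"].append(
                asymmetry_field(peak_aligned, template)
            )

    out: dict[ExpressionType, CohortMapSet] = {}
    for expression, groups in per_expr.items():
        if not groups["control"] or not groups["patient"]:
            continue
        control_mean = average_field(groups["control"])
        patient_mean = average_field(groups["patient"])
        out[expression] = CohortMapSet(
            expression=expression,
            control_movement=control_mean,
            patient_movement=patient_mean,
            movement_difference=difference_field(patient_mean, control_mean),
            patient_asymmetry=average_field(groups["asym"]),
        )
    return out


def field_to_colors(
    field: ScalarField, vrange: tuple[float, float], palette: str = "jet"
) -> np.ndarray:
    """Map field values to RGBA uint8 through a matplotlib palette, clamped."""
    import matplotlib

    lo, hi = vrange
    if lo >= hi:
        raise ValueError(f"invalid range {vrange}: min must be < max")
    cmap = matplotlib.colormaps[palette]
    normed = np.clip((field.values - lo) / (hi - lo), 0.0, 1.0)
    return (cmap(normed) * 255).astype(np.uint8)


def render_map(
    field: ScalarField,
    mesh: TriangleMesh,
    vrange: tuple[float, float],
    palette: str = "jet",
    out_path: str | Path = "map.ply",
    png: bool = True,
) -> list[Path]:
    """Write a colour-mapped mesh (PLY with vertex colours) and a 2-D render.

    Values outside ``vrange`` are clamped to the palette endpoints.  The PNG
    is a frontal (x, y) projection coloured by the field.
    """
    import trimesh

    colors = field_to_colors(field, vrange, palette)
    out_path = Path(out_path)
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.faces, vertex_colors=colors, process=False
    )
    tm.export(out_path)
    written = [out_path]
    if png:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 5))
        sc = ax.scatter(
            mesh.vertices[:, 0],
            mesh.vertices[:, 1],
            c=np.clip(field.values, *vrange),
            cmap=palette,
            vmin=vrange[0],
            vmax=vrange[1],
            s=3,
        )
        ax.set_aspect("equal")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        fig.colorbar(sc, ax=ax, label=f"{field.kind} (mm)")
        png_path = out_path.with_suffix(".png")
        fig.savefig(png_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(png_path)
    return written
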