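"""Expression captures: one subject performing one expression (rest + peak)."""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .mesh import GenericTemplate, TriangleMesh, mirror


class ExpressionType(str, Enum):
    """The five graded voluntary expressions, plus the rest frame."""

    REST = "rest"
    EYEBROW_RAISING = "eyebrow_raising"
    EYE_CLOSURE = "eye_closure"
    SMILING = "smiling"
    CHEEK_PUFFING = "cheek_puffing"
    LIP_PUCKERING = "lip_puckering"


#: The non-rest expressions, in canonical (one-hot) order.
EXPRESSIONS: tuple[ExpressionType, ...] = (
    ExpressionType.EYEBROW_RAISING,
    ExpressionType.EYE_CLOSURE,
    ExpressionType.SMILING,
    ExpressionType.CHEEK_PUFFING,
    ExpressionType.LIP_PUCKERING,
)

LATERALITIES = ("left", "right", "none")


@dataclass
class ExpressionCapture:
    """Rest/peak mesh pair for one subject and one voluntary expression."""

    subject_id: str
    cohort: str  # "patient" | "control"
    expression: ExpressionType
    laterality: str  # "left" | "right" | "none"
    rest: TriangleMesh
    peak: TriangleMesh

    def __post_init__(self) -> None:
        self.expression = ExpressionType(self.expression)
        if self.expression is ExpressionType.REST:
            raise ValueError("a capture pairs rest with a non-rest expression")
        if self.cohort not in ("patient", "control"):
            raise ValueError(f"cohort must be patient|control, got {self.cohort!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")
        if self.rest.n_vertices != self.peak.n_vertices:
            raise ValueError("rest and peak meshes must share the vertex set")

    @property
    def expression_index(self) -> int:
        return EXPRESSIONS.index(self.expression)


def reflect_lateralize(
    capture: ExpressionCapture, template: GenericTemplate
) -> ExpressionCapture:
    """Put every palsy on the right side of the face.

    Left-sided captures are mirrored (rest and peak both) and relabelled as
    right-sided, so the network always sees the deficit on the same side;
    right-sided and control captures pass through unchanged.  Mirroring
    preserves all inter-vertex distances, so asymmetry fields are unaffected.
    Idempotent: applying twice equals applying once.
    """
    if capture.cohort == "patient" and capture.laterality not in ("left", "right"):
        raise ValueError(
            f"patient capture {capture.subject_id} has unknown laterality"
        )
    if capture.laterality != "left":
        return capture
    return replace(
        capture,
        laterality="right",
        rest=mirror(capture.rest, template),
        peak=mirror(capture.peak, template),
    )
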