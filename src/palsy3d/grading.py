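"""Modified Sunnybrook scale, expert-consensus mode and assessor accuracy.

Severity is graded on a modified Sunnybrook system: three resting-symmetry
parameters (eye 1-2, cheek 1-3, mouth 1-2) and five voluntary-movement
parameters, one per expression, each on a 1 (no movement) to 5 (normal)
scale.  A panel of 7 assessors grades every subject twice (sessions 45 days
apart in the original protocol), giving 14 observations per parameter.  The
consensus grade is the mode of the 14 observations, and the accuracy of a
parameter is the mode's occurrence count divided by 14, averaged over
subjects.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .capture import EXPRESSIONS, ExpressionType

N_ASSESSORS = 7
N_SESSIONS = 2


@dataclass(frozen=True)
class SunnybrookParameter:
    name: str
    category: str  # "resting" | "voluntary"
    grade_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.category not in ("resting", "voluntary"):
            raise ValueError("category must be resting|voluntary")
        lo, hi = self.grade_range
        if lo >= hi:
            raise ValueError("grade range must be non-trivial")

    def validate_grade(self, grade: int) -> None:
        lo, hi = self.grade_range
        if not (lo <= grade <= hi):
            raise ValueError(
                f"grade {grade} outside [{lo}, {hi}] for parameter {self.name!r}"
            )


RESTING_PARAMETERS: tuple[SunnybrookParameter, ...] = (
    SunnybrookParameter("resting_eye", "resting", (1, 2)),
    SunnybrookParameter("resting_cheek", "resting", (1, 3)),
    SunnybrookParameter("resting_mouth", "resting", (1, 2)),
)

VOLUNTARY_PARAMETERS: tuple[SunnybrookParameter, ...] = tuple(
    SunnybrookParameter(expr.value, "voluntary", (1, 5)) for expr in EXPRESSIONS
)

ALL_PARAMETERS = RESTING_PARAMETERS + VOLUNTARY_PARAMETERS
_BY_NAME = {p.name: p for p in ALL_PARAMETERS}


def parameter_for_expression(expression: ExpressionType) -> SunnybrookParameter:
    return _BY_NAME[ExpressionType(expression).value]


@dataclass(frozen=True)
class ConsensusGrade:
    """Panel mode with its occurrence count and accuracy fraction."""

    mode: int
    occurrences: int
    n_observations: int
    tie: bool = False

    @property
    def accuracy(self) -> float:
        return self.occurrences / self.n_observations


def consensus_mode(
    grades, parameter: SunnybrookParameter | None = None
) -> ConsensusGrade:
    """Mode of a panel cell; ties broken by the smaller grade.

    The tie-break toward the smaller (more severe) grade is a deliberate
    conservative choice and is flagged in the result so downstream reports
    can surface multimodal panels.
    """
    obs = np.asarray(list(grades))
    if obs.size == 0:
        raise ValueError("empty grade panel")
    if not np.issubdtype(obs.dtype, np.integer):
        if not np.all(obs == np.round(obs)):
            raise ValueError("grades must be integers")
        obs = obs.astype(int)
    if parameter is not None:
        for g in obs:
            parameter.validate_grade(int(g))
    counts = Counter(int(g) for g in obs)
    top = max(counts.values())
    modes = sorted(g for g, c in counts.items() if c == top)
    return ConsensusGrade(
        mode=modes[0], occurrences=top, n_observations=obs.size, tie=len(modes) > 1
    )


_PANEL_COLUMNS = ["subject_id", "parameter", "assessor", "session", "grade"]


@dataclass
class GradePanel:
    """Long-format grade table: one row per (subject, parameter, assessor, session)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PANEL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"panel table missing columns {missing}")
        self.table = self.table[_PANEL_COLUMNS].copy()
        for _, row in self.table.iterrows():
            param = _BY_NAME.get(row["parameter"])
            if param is not None:
                param.validate_grade(int(row["grade"]))

    @classmethod
    def from_cells(
        cls, cells: dict[tuple[str, str], np.ndarray]
    ) -> "GradePanel":
        """Build from {(subject, parameter): (n_assessors, n_sessions) array}."""
        rows = []
        for (subject, parameter), cell in cells.items():
            cell = np.asarray(cell)
            if cell.ndim != 2:
                raise ValueError("panel cell must be (assessors, sessions)")
            for a in range(cell.shape[0]):
                for s in range(cell.shape[1]):
                    rows.append((subject, parameter, a, s, int(cell[a, s])))
        return cls(pd.DataFrame(rows, columns=_PANEL_COLUMNS))

    def cell(self, subject_id: str, parameter: str) -> np.ndarray:
        sel = self.table[
            (self.table.subject_id == subject_id)
            & (self.table.parameter == parameter)
        ]
        return sel["grade"].to_numpy()

    def consensus(self) -> pd.DataFrame:
        """Per (subject, parameter) mode, occurrences and accuracy."""
        expected = N_ASSESSORS * N_SESSIONS
        out = []
        for (subject, parameter), group in self.table.groupby(
            ["subject_id", "parameter"], sort=True
        ):
            if len(group) != expected:
                raise ValueError(
                    f"panel cell ({subject}, {parameter}) has {len(group)} "
                    f"observations, expected {expected} (no imputation)"
                )
            c = consensus_mode(group["grade"].to_numpy(), _BY_NAME.get(parameter))
            out.append(
                (subject, parameter, c.mode, c.occurrences, c.accuracy, c.tie)
            )
        return pd.DataFrame(
            out,
            columns=["subject_id", "parameter", "mode", "occurrences", "accuracy", "tie"],
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "GradePanel":
        return cls(pd.read_csv(path))


def assessor_accuracy(panel: GradePanel) -> pd.Series:
    """Per-parameter mean of (mode occurrences / 14) across subjects.

    High values mean the expert panel was internally consistent for that
    parameter; 1.0 means unanimous agreement on every subject.
    """
    cons = panel.consensus()
    return cons.groupby("parameter")["accuracy"].mean()


def simulate_rater_panel(
    true_grade: int,
    parameter: SunnybrookParameter | None = None,
    n_assessors: int = N_ASSESSORS,
    n_sessions: int = N_SESSIONS,
    noise: float = 0.2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one panel cell: true grade + rounded Gaussian ordinal noise.

    Each of the ``n_assessors * n_sessions`` observations is the true grade
    plus N(0, noise^2), rounded to the nearest integer and clipped to the
    parameter's allowed range (1-5 for voluntary parameters by default).
    As noise -> 0 every observation equals the truth.
    """
    lo, hi = parameter.grade_range if parameter is not None else (1, 5)
    if not (lo <= true_grade <= hi):
        raise ValueError(f"true grade {true_grade} outside [{lo}, {hi}]")
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = np.round(true_grade + rng.normal(0.0, noise, (n_assessors, n_sessions)))
    return np.clip(obs, lo, hi).astype(int)
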