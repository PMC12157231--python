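"""Feature engineering: alignment chain, augmentation, leakage-safe splits.

A training sample is a pair of point clouds — the face at rest, Procrustes-
aligned to the template, and the face at peak expression, landmark-aligned
to the rest frame — plus a one-hot expression code and the expert-consensus
grade.  Augmentation rotates both clouds together about the vertical axis
(within ±15°) and jitters coordinates with Gaussian noise at 2% of the
cloud's size, multiplying 160 original captures into 960 samples.  Splitting
is done at the level of original captures (80/20, stratified by expression
and cohort) so augmented near-duplicates can never leak across partitions:
128 × 6 = 768 train, 32 × 6 = 192 test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .capture import EXPRESSIONS, ExpressionCapture, ExpressionType
from .mesh import GenericTemplate, landmark_rigid_align, partial_procrustes

N_EXPRESSIONS = len(EXPRESSIONS)


@dataclass
class Sample:
    """One network input: rest cloud, peak cloud, expression code, target grade."""

    rest_points: np.ndarray
    peak_points: np.ndarray
    expression: ExpressionType
    target_grade: float
    subject_id: str
    cohort: str = "patient"
    original_id: str = ""
    augmented: bool = False
    augmentation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rest_points = np.asarray(self.rest_points, dtype=np.float64)
        self.peak_points = np.asarray(self.peak_points, dtype=np.float64)
        if self.rest_points.shape != self.peak_points.shape:
            raise ValueError("rest and peak clouds must have identical shape")
        if self.rest_points.ndim != 2 or self.rest_points.shape[1] != 3:
            raise ValueError("point clouds must be (n, 3)")
        self.expression = ExpressionType(self.expression)
        if not 1.0 <= float(self.target_grade) <= 5.0:
            raise ValueError(f"target grade {self.target_grade} outside [1, 5]")
        if not self.original_id:
            self.original_id = f"{self.subject_id}:{self.expression.value}"

    @property
    def expression_index(self) -> int:
        return EXPRESSIONS.index(self.expression)

    @property
    def expression_onehot(self) -> np.ndarray:
        onehot = np.zeros(N_EXPRESSIONS)
        onehot[self.expression_index] = 1.0
        return onehot

    @property
    def n_points(self) -> int:
        return len(self.rest_points)


@dataclass
class AugmentationConfig:
    """Point-cloud augmentation: yaw within ±rotation_deg, jitter at
    noise_fraction × cloud size; each original yields ``variants`` samples
    (the unmodified original counted as one of them)."""

    rotation_deg: float = 15.0
    noise_fraction: float = 0.02
    variants: int = 6
    axis: str = "y"
    noise_reference: str = "rms_radius"  # or "bbox_diagonal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_deg < 0:
            raise ValueError("rotation limit must be >= 0")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise fraction must be in [0, 1)")
        if self.variants < 1:
            raise ValueError("variants must be >= 1")
        if self.axis not in ("x", "y", "z"):
            raise ValueError("axis must be x|y|z")
        if self.noise_reference not in ("rms_radius", "bbox_diagonal"):
            raise ValueError("noise_reference must be rms_radius|bbox_diagonal")


def build_sample(
    capture: ExpressionCapture,
    template: GenericTemplate,
    consensus_grade: float,
) -> Sample:
    """Alignment chain producing one original sample from a capture.

    The rest frame is superimposed onto the template with partial Procrustes
    (rotation + translation over all corresponded vertices); the peak frame
    is then rigidly aligned to the aligned rest frame using the three facial
    landmarks only, removing head motion while leaving the expression
    deformation intact.  The capture must already be lateralized (palsy on
    the right); apply :func:`palsy3d.capture.reflect_lateralize` first.
    """
    if capture.laterality == "left":
        raise ValueError(
            "capture is left-lateralized; apply reflect_lateralize before building"
        )
    _, rest_aligned = partial_procrustes(capture.rest, template.mesh)
    _, peak_aligned = landmark_rigid_align(
        capture.peak, rest_aligned, template.landmark_indices
    )
    return Sample(
        rest_points=rest_aligned.vertices,
        peak_points=peak_aligned.vertices,
        expression=capture.expression,
        target_grade=consensus_grade,
        subject_id=capture.subject_id,
        cohort=capture.cohort,
    )


def _yaw_matrix(angle_rad: float, axis: str) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _noise_scale(points: np.ndarray, reference: str) -> float:
    if reference == "bbox_diagonal":
        return float(np.linalg.norm(points.max(0) - points.min(0)))
    centered = points - points.mean(0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def augment(
    sample: Sample,
    config: AugmentationConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[Sample]:
    """Expand one original into ``config.variants`` samples.

    Variant 0 is the untouched original; each further variant rotates both
    clouds by one shared random angle about the vertical axis through the
    rest-cloud centroid, then adds independent per-coordinate Gaussian noise
    with σ = noise_fraction × RMS radius of the rest cloud.  The target grade
    is unchanged — augmentation perturbs pose and measurement, not severity.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    out = [replace(sample, augmented=False, augmentation={})]
    center = sample.rest_points.mean(axis=0)
    sigma = config.noise_fraction * _noise_scale(sample.rest_points, config.noise_reference)
    for k in range(1, config.variants):
        angle = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg))
        R = _yaw_matrix(angle, config.axis)
        rest = (sample.rest_points - center) @ R.T + center
        peak = (sample.peak_points - center) @ R.T + center
        if sigma > 0:
            rest = rest + rng.normal(0.0, sigma, rest.shape)
            peak = peak + rng.normal(0.0, sigma, peak.shape)
        out.append(
            replace(
                sample,
                rest_points=rest,
                peak_points=peak,
                augmented=True,
                augmentation={"variant": k, "angle_deg": float(np.rad2deg(angle)), "sigma_mm": sigma},
            )
        )
    return out


def augment_all(
    samples: list[Sample], config: AugmentationConfig
) -> list[Sample]:
    """Augment every original; |output| = |originals| × variants."""
    rng = np.random.default_rng(config.seed)
    out: list[Sample] = []
    for sample in samples:
        out.extend(augment(sample, config, rng=rng))
    return out


@dataclass
class DatasetSplit:
    """Disjoint train/test partitions with a per-sample manifest."""

    train: list[Sample]
    test: list[Sample]

    def __post_init__(self) -> None:
        train_ids = {s.original_id for s in self.train}
        test_ids = {s.original_id for s in self.test}
        if train_ids & test_ids:
            raise ValueError(
                f"leakage: originals in both partitions: {sorted(train_ids & test_ids)[:5]}"
            )

    @property
    def manifest(self) -> pd.DataFrame:
        rows = []
        for part, samples in (("train", self.train), ("test", self.test)):
            for i, s in enumerate(samples):
                rows.append(
                    {
                        "sample_id": f"{part}-{i:04d}",
                        "partition": part,
                        "subject_id": s.subject_id,
                        "cohort": s.cohort,
                        "expression": s.expression.value,
                        "original_id": s.original_id,
                        "grade": s.target_grade,
                        "augmented": s.augmented,
                        "angle_deg": s.augmentation.get("angle_deg", 0.0),
                        "sigma_mm": s.augmentation.get("sigma_mm", 0.0),
                    }
                )
        return pd.DataFrame(rows)


def split(
    samples: list[Sample],
    train_fraction: float = 0.8,
    seed: int = 0,
    mode: str = "grouped",
) -> DatasetSplit:
    """Partition samples into train/test at the original-capture level.

    ``grouped`` (default): unique originals are stratified by (expression,
    cohort) and split 80/20; every augmented variant follows its original,
    so near-duplicates never straddle the boundary.  With the default cohort
    (160 originals × 6 variants) this yields exactly 768 train / 192 test.
    ``naive``: a flat random split over individual samples, kept only for
    comparison — it leaks augmented copies across partitions.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if mode == "naive":
        order = rng.permutation(len(samples))
        n_train = int(round(train_fraction * len(samples)))
        train = [samples[i] for i in order[:n_train]]
        test = [samples[i] for i in order[n_train:]]
        # bypass the leakage guard deliberately
        ds = DatasetSplit.__new__(DatasetSplit)
        ds.train, ds.test = train, test
        return ds
    if mode != "grouped":
        raise ValueError("mode must be grouped|naive")

    by_original: dict[str, list[Sample]] = {}
    strata: dict[tuple[str, str], list[str]] = {}
    for s in samples:
        if s.original_id not in by_original:
            strata.setdefault((s.expression.value, s.cohort), []).append(s.original_id)
        by_original.setdefault(s.original_id, []).append(s)

    n_orig = len(by_original)
    n_train_target = int(round(train_fraction * n_orig))
    train_ids: set[str] = set()
    leftovers: list[tuple[float, float, str]] = []
    for key in sorted(strata):
        ids = strata[key]
        rng.shuffle(ids)
        quota = train_fraction * len(ids)
        base = int(np.floor(quota))
        train_ids.update(ids[:base])
        if base < len(ids):
            leftovers.append((quota - base, rng.random(), ids[base]))
    # top up largest fractional remainders until the global quota is met
    for _, _, candidate in sorted(leftovers, reverse=True):
        if len(train_ids) >= n_train_target:
            break
        train_ids.add(candidate)

    train = [s for oid in sorted(by_original) if oid in train_ids for s in by_original[oid]]
    test = [s for oid in sorted(by_original) if oid not in train_ids for s in by_original[oid]]
    return DatasetSplit(train=train, test=test)


# ---------------------------------------------------------------------------
# serialization: one array container per split + CSV manifest
# ---------------------------------------------------------------------------

def save_split(ds: DatasetSplit, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = ds.manifest
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    for part, samples in (("train", ds.train), ("test", ds.test)):
        if samples:
            np.savez_compressed(
                out_dir / f"{part}.npz",
                rest=np.stack([s.rest_points for s in samples]).astype(np.float32),
                peak=np.stack([s.peak_points for s in samples]).astype(np.float32),
                expression=np.array([s.expression_index for s in samples]),
                grade=np.array([s.target_grade for s in samples]),
            )
    return out_dir


def load_split(out_dir: str | Path) -> DatasetSplit:
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv")
    parts: dict[str, list[Sample]] = {"train": [], "test": []}
    for part in parts:
        npz_path = out_dir / f"{part}.npz"
        if not npz_path.exists():
            continue
        with np.load(npz_path) as data:
            arrays = {k: data[k] for k in ("rest", "peak", "expression", "grade")}
        meta = manifest[manifest.partition == part].reset_index(drop=True)
        for i in range(len(meta)):
            row = meta.iloc[i]
            parts[part].append(
                Sample(
                    rest_points=arrays["rest"][i],
                    peak_points=arrays["peak"][i],
                    expression=EXPRESSIONS[int(arrays["expression"][i])],
                    target_grade=float(arrays["grade"][i]),
                    subject_id=row["subject_id"],
                    cohort=row["cohort"],
                    original_id=row["original_id"],
                    augmented=bool(row["augmented"]),
                    augmentation={
                        "angle_deg": float(row["angle_deg"]),
                        "sigma_mm": float(row["sigma_mm"]),
                    },
                )
            )
    return DatasetSplit(train=parts["train"], test=parts["test"])
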