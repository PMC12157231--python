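"""End-to-end orchestration: synth → grade → build → augment → split →
train → evaluate → maps, with a single resolved config stamped per run."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import grading
from .capture import reflect_lateralize
from .dataset import AugmentationConfig, augment_all, build_sample, save_split, split
from .maps import DIFFERENCE_RANGE, MOVEMENT_RANGE, compute_cohort_maps, render_map
from .pointnet import NetworkConfig, PointNetGradeRegressor, evaluate
from .synthetic import CohortSpec, make_template, synthesize_cohort

log = logging.getLogger("palsy3d")


@dataclass
class PipelineConfig:
    """Everything one run needs, serializable to a single YAML file."""

    template_vertices: int = 7859
    template_seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig.desk)
    train_fraction: float = 0.8
    split_seed: int = 0
    split_mode: str = "grouped"
    render_maps: bool = True

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs:
            cohort = dict(kwargs["cohort"])
            if "severity_choices" in cohort:
                cohort["severity_choices"] = tuple(cohort["severity_choices"])
            kwargs["cohort"] = CohortSpec(**cohort)
        if "augmentation" in kwargs:
            kwargs["augmentation"] = AugmentationConfig(**kwargs["augmentation"])
        if "network" in kwargs:
            net = dict(kwargs["network"])
            for key in ("branch_widths", "head_widths", "betas", "lr_milestones"):
                if key in net and net[key] is not None:
                    net[key] = tuple(net[key])
            kwargs["network"] = NetworkConfig(**net)
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Derive a fully reseeded copy (all stage seeds driven by ``seed``)."""
        cfg = PipelineConfig.from_dict(asdict(self))
        cfg.cohort.master_seed = seed
        cfg.augmentation.seed = seed + 1
        cfg.split_seed = seed + 2
        cfg.network.seed = seed + 3
        return cfg


def run_pipeline(config: PipelineConfig, out_dir: str | Path, dry_run: bool = False) -> Path:
    """Execute the full pipeline into ``out_dir``; returns the run directory.

    Writes: resolved config, dataset split (arrays + manifest), consensus
    grades, model checkpoint, training curve, evaluation report and, when
    enabled, the per-expression cohort maps.  Stage wall times and seeds are
    logged and recorded in the run manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    if dry_run:
        (out_dir / "plan.json").write_text(
            json.dumps({"stages": _STAGES, "dry_run": True}, indent=2)
        )
        return out_dir

    manifest: dict = {"stages": {}, "artifacts": ["config.yaml"]}

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, *exc):
                dt = time.perf_counter() - self.t0
                manifest["stages"][name] = round(dt, 3)
                log.info("stage %s: %.2fs", name, dt)

        return _Timer()

    with stage("synth"):
        template = make_template(config.template_vertices, seed=config.template_seed)
        captures, truth = synthesize_cohort(config.cohort, template)

    with stage("grade"):
        rng = np.random.default_rng(config.cohort.master_seed + 7)
        cells = {}
        for (subject_id, expression), true_grade in truth.items():
            param = grading.parameter_for_expression(expression)
            cells[(subject_id, param.name)] = grading.simulate_rater_panel(
                int(round(true_grade)),
                parameter=param,
                noise=config.cohort.rater_noise,
                rng=rng,
            )
        panel = grading.GradePanel.from_cells(cells)
        consensus = panel.consensus()
        panel.to_csv(out_dir / "panel.csv")
        consensus.to_csv(out_dir / "consensus.csv", index=False)
        manifest["artifacts"] += ["panel.csv", "consensus.csv"]
        cons_lookup = {
            (row.subject_id, row.parameter): row.mode
            for row in consensus.itertuples()
        }

    with stage("build"):
        originals = []
        for capture in captures:
            capture = reflect_lateralize(capture, template)
            grade = cons_lookup[(capture.subject_id, capture.expression.value)]
            originals.append(build_sample(capture, template, float(grade)))

    with stage("augment"):
        samples = augment_all(originals, config.augmentation)

    with stage("split"):
        ds = split(
            samples,
            train_fraction=config.train_fraction,
            seed=config.split_seed,
            mode=config.split_mode,
        )
        save_split(ds, out_dir / "dataset")
        manifest["artifacts"] += [
            "dataset/manifest.csv",
            "dataset/train.npz",
            "dataset/test.npz",
        ]

    with stage("train"):
        model = PointNetGradeRegressor.from_config(config.network)
        model.fit(ds.train)
        model.save(out_dir / "model.npz")
        model.history_.to_csv(out_dir / "training_curve.csv", index=False)
        manifest["artifacts"] += ["model.npz", "training_curve.csv"]

    with stage("evaluate"):
        report = evaluate(model, ds.test)
        (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        manifest["artifacts"].append("report.json")

    if config.render_maps:
        with stage("maps"):
            map_dir = out_dir / "maps"
            map_dir.mkdir(exist_ok=True)
            rows = []
            for expression, maps in compute_cohort_maps(captures, template).items():
                for label, fld, rng_ in (
                    ("control_movement", maps.control_movement, MOVEMENT_RANGE),
                    ("patient_movement", maps.patient_movement, MOVEMENT_RANGE),
                    ("difference", maps.movement_difference, DIFFERENCE_RANGE),
                    ("patient_asymmetry", maps.patient_asymmetry, MOVEMENT_RANGE),
                ):
                    for p in render_map(
                        fld,
                        template.mesh,
                        rng_,
                        out_path=map_dir / f"{expression.value}_{label}.ply",
                    ):
                        manifest["artifacts"].append(str(p.relative_to(out_dir)))
                    rows.append(
                        pd.Series(fld.values, name=f"{expression.value}_{label}")
                    )
            pd.concat(rows, axis=1).to_csv(map_dir / "vertex_means.csv", index=False)
            manifest["artifacts"].append("maps/vertex_means.csv")

    manifest["seeds"] = {
        "template": config.template_seed,
        "cohort": config.cohort.master_seed,
        "augmentation": config.augmentation.seed,
        "split": config.split_seed,
        "network": config.network.seed,
    }
    manifest["min_accuracy"] = report.min_accuracy
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


_STAGES = ["synth", "grade", "build", "augment", "split", "train", "evaluate", "maps"]
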