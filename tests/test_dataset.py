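"""Alignment chain, augmentation arithmetic, and leakage-safe splitting."""

import numpy as np
import pytest

from palsy3d.capture import EXPRESSIONS, ExpressionType, reflect_lateralize
from palsy3d.dataset import (
    AugmentationConfig,
    DatasetSplit,
    Sample,
    augment,
    augment_all,
    build_sample,
    load_split,
    save_split,
    split,
)
from palsy3d.synthetic import CohortSpec, synthesize_capture, synthesize_cohort

from conftest import make_subject, random_rigid


def _cohort_samples(template, n_patients=2, n_controls=2, seed=0):
    spec = CohortSpec(n_patients=n_patients, n_controls=n_controls, master_seed=seed)
    captures, truth = synthesize_cohort(spec, template)
    out = []
    for cap in captures:
        cap = reflect_lateralize(cap, template)
        out.append(build_sample(cap, template, float(truth[(cap.subject_id, cap.expression)])))
    return out


class TestBuildSample:
    def test_pure_head_motion_leaves_peak_near_rest(self, template, rng):
        """Control capture where peak = rigidly moved rest: the landmark
        alignment must cancel the motion down to the sensor-noise floor."""
        subject = make_subject(5, "none")
        spec = CohortSpec(n_patients=1, n_controls=1, sensor_noise_mm=0.05)
        cap = synthesize_capture(subject, ExpressionType.REST
                                 if False else EXPRESSIONS[0], template, seed=2, spec=spec)
        # overwrite peak with a rigid motion of rest (no expression at all)
        moved = cap.rest.transformed(random_rigid(rng))
        cap.peak = moved
        sample = build_sample(cap, template, 5.0)
        gap = np.linalg.norm(sample.peak_points - sample.rest_points, axis=1)
        assert gap.max() < 1e-6

    def test_capture_in_template_frame_passes_through(self, template):
        subject = make_subject(4)
        clean = CohortSpec(n_patients=1, n_controls=1, sensor_noise_mm=0.0, head_pose=False)
        cap = synthesize_capture(subject, EXPRESSIONS[1], template, seed=3, spec=clean)
        cap = reflect_lateralize(cap, template)
        sample = build_sample(cap, template, 4.0)
        # rest is template + symmetric shape field: Procrustes should be ~identity
        assert np.abs(sample.rest_points - cap.rest.vertices).max() < 0.5

    def test_severe_patient_has_right_side_deficit(self, template, clean_spec):
        cap = synthesize_capture(make_subject(1), EXPRESSIONS[2], template, seed=4, spec=clean_spec)
        cap = reflect_lateralize(cap, template)
        sample = build_sample(cap, template, 1.0)
        d = np.linalg.norm(sample.peak_points - sample.rest_points, axis=1)
        x = template.mesh.vertices[:, 0]
        assert d[x < -5].mean() < 0.2 * d[x > 5].mean()

    def test_invariant_to_rigid_pretransform_of_capture(self, template, rng):
        subject = make_subject(3)
        clean = CohortSpec(n_patients=1, n_controls=1, sensor_noise_mm=0.0, head_pose=False)
        cap = synthesize_capture(subject, EXPRESSIONS[0], template, seed=5, spec=clean)
        cap = reflect_lateralize(cap, template)
        s1 = build_sample(cap, template, 3.0)
        T = random_rigid(rng)
        cap.rest = cap.rest.transformed(T)
        cap.peak = cap.peak.transformed(random_rigid(rng))
        s2 = build_sample(cap, template, 3.0)
        assert np.abs(s1.rest_points - s2.rest_points).max() < 1e-6
        assert np.abs(s1.peak_points - s2.peak_points).max() < 1e-6

    def test_left_lateralized_capture_rejected(self, template):
        cap = synthesize_capture(make_subject(2, "left"), EXPRESSIONS[0], template, seed=1)
        with pytest.raises(ValueError, match="reflect_lateralize"):
            build_sample(cap, template, 2.0)


class TestAugment:
    def _sample(self, template):
        return _cohort_samples(template, 1, 1, seed=1)[0]

    def test_default_config_multiplies_160_to_960(self, template):
        samples = [s for s in _cohort_samples(template, 2, 2, seed=0)]
        # 20 originals x 6 variants = 120; same arithmetic as 160 -> 960
        out = augment_all(samples, AugmentationConfig(seed=0))
        assert len(out) == len(samples) * 6

    def test_zero_noise_zero_rotation_reproduces_original(self, template):
        s = self._sample(template)
        config = AugmentationConfig(rotation_deg=0.0, noise_fraction=0.0, variants=3)
        out = augment(s, config)
        for variant in out:
            assert np.allclose(variant.rest_points, s.rest_points, atol=1e-9)
            assert np.allclose(variant.peak_points, s.peak_points, atol=1e-9)

    def test_rotation_only_preserves_inter_point_distances(self, template):
        s = self._sample(template)
        config = AugmentationConfig(noise_fraction=0.0, variants=2, seed=3)
        rotated = augment(s, config)[1]
        idx = np.arange(0, s.n_points, 37)
        for pts, rpts in ((s.rest_points, rotated.rest_points), (s.peak_points, rotated.peak_points)):
            d0 = np.linalg.norm(pts[idx][:, None] - pts[idx][None], axis=2)
            d1 = np.linalg.norm(rpts[idx][:, None] - rpts[idx][None], axis=2)
            assert np.abs(d0 - d1).max() < 1e-9

    def test_rotation_is_about_vertical_axis_within_limit(self, template):
        s = self._sample(template)
        config = AugmentationConfig(noise_fraction=0.0, variants=20, seed=4)
        for variant in augment(s, config)[1:]:
            angle = variant.augmentation["angle_deg"]
            assert -15.0 <= angle <= 15.0
            # y coordinates unchanged by a yaw rotation
            assert np.abs(variant.rest_points[:, 1] - s.rest_points[:, 1]).max() < 1e-9

    def test_noise_scale_follows_rms_radius(self, template):
        s = self._sample(template)
        config = AugmentationConfig(rotation_deg=0.0, variants=40, seed=5)
        centered = s.rest_points - s.rest_points.mean(0)
        expected_sigma = 0.02 * np.sqrt((centered**2).sum(1).mean())
        resid = np.concatenate(
            [(v.rest_points - s.rest_points).ravel() for v in augment(s, config)[1:]]
        )
        assert np.std(resid) == pytest.approx(expected_sigma, rel=0.05)

    def test_target_and_provenance_preserved(self, template):
        s = self._sample(template)
        for v in augment(s, AugmentationConfig(seed=1)):
            assert v.target_grade == s.target_grade
            assert v.original_id == s.original_id

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            AugmentationConfig(rotation_deg=-1)
        with pytest.raises(ValueError):
            AugmentationConfig(noise_fraction=1.5)
        with pytest.raises(ValueError):
            AugmentationConfig(variants=0)


class TestSplit:
    def _augmented(self, template):
        samples = _cohort_samples(template, 2, 2, seed=2)
        return augment_all(samples, AugmentationConfig(seed=2))

    def test_grouped_split_counts(self, template):
        out = self._augmented(template)  # 20 originals x 6 = 120
        ds = split(out, seed=0)
        assert len(ds.train) + len(ds.test) == 120
        assert len(ds.train) == 96 and len(ds.test) == 24

    def test_no_original_straddles_partitions(self, template):
        ds = split(self._augmented(template), seed=1)
        assert {s.original_id for s in ds.train}.isdisjoint(
            {s.original_id for s in ds.test}
        )

    def test_stratified_by_expression(self, template):
        ds = split(self._augmented(template), seed=3)
        test_orig = {(s.original_id, s.expression) for s in ds.test}
        per_expr = {}
        for _, expr in test_orig:
            per_expr[expr] = per_expr.get(expr, 0) + 1
        # 4 originals per expression, 20% -> 1 test original each (up to rounding)
        assert all(c in (0, 1, 2) for c in per_expr.values())
        assert sum(per_expr.values()) == 4

    def test_reproducible_given_seed(self, template):
        out = self._augmented(template)
        a = split(out, seed=9)
        b = split(out, seed=9)
        assert [s.original_id for s in a.test] == [s.original_id for s in b.test]

    def test_leakage_guard_raises(self, template):
        out = self._augmented(template)
        with pytest.raises(ValueError, match="leakage"):
            DatasetSplit(train=out[:12], test=out[:6])

    def test_bad_fraction_rejected(self, template):
        with pytest.raises(ValueError):
            split(self._augmented(template), train_fraction=1.5)

    def test_round_trip_serialization(self, template, tmp_path):
        ds = split(self._augmented(template), seed=4)
        save_split(ds, tmp_path)
        again = load_split(tmp_path)
        assert len(again.train) == len(ds.train)
        assert len(again.test) == len(ds.test)
        for a, b in zip(ds.test, again.test):
            assert np.allclose(a.rest_points, b.rest_points, atol=1e-6)
            assert a.target_grade == b.target_grade
            assert a.original_id == b.original_id
        manifest = ds.manifest
        assert set(manifest.partition.unique()) == {"train", "test"}


class TestSampleType:
    def test_onehot_and_validation(self, template):
        s = _cohort_samples(template, 1, 1, seed=0)[0]
        assert s.expression_onehot.sum() == 1.0
        assert s.expression_onehot[s.expression_index] == 1.0
        with pytest.raises(ValueError):
            Sample(
                rest_points=np.zeros((4, 3)),
                peak_points=np.zeros((4, 3)),
                expression=EXPRESSIONS[0],
                target_grade=7.0,
                subject_id="s",
            )
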