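import numpy as np
import pytest

from palsy3d.capture import EXPRESSIONS
from palsy3d.synthetic import CohortSpec, SyntheticSubject, make_template


@pytest.fixture(scope="session")
def template():
    """Small face template: fast but fully featured (landmarks, pairing)."""
    return make_template(500, seed=1)


@pytest.fixture(scope="session")
def big_template():
    """Full-resolution 7859-vertex template."""
    return make_template(7859, seed=0)


@pytest.fixture(scope="session")
def clean_spec():
    """Cohort spec with measurement effects switched off (pure deformation)."""
    return CohortSpec(n_patients=1, n_controls=1, sensor_noise_mm=0.0, head_pose=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_subject(grade: int, laterality: str = "right", shape_seed: int = 7):
    cohort = "control" if laterality == "none" else "patient"
    return SyntheticSubject(
        subject_id=f"S{grade}",
        cohort=cohort,
        laterality=laterality,
        severities={e: (5 if cohort == "control" else grade) for e in EXPRESSIONS},
        shape_seed=shape_seed,
    )


def random_rigid(rng: np.random.Generator):
    """Uniform-ish random proper rotation + translation for invariance tests."""
    from scipy.spatial.transform import Rotation

    from palsy3d.mesh import RigidTransform

    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return RigidTransform(R, t)
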