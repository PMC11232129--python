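import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from avcoupling.pipeline import PipelineConfig, run_subject
from avcoupling.synthetic import SubjectParams, generate_subject

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_params(**overrides) -> SubjectParams:
    base = dict(
        subject_id="T0",
        age=35.0,
        sex="M",
        height=178.0,
        weight=75.0,
        hr=70.0,
        n_frames=40,
        noise_sd=0.0,
        seed=7,
    )
    base.update(overrides)
    return SubjectParams(**base)


@pytest.fixture(scope="session")
def zero_noise_params() -> SubjectParams:
    return make_params()


@pytest.fixture(scope="session")
def zero_noise_subject(zero_noise_params):
    return generate_subject(zero_noise_params)


@pytest.fixture(scope="session")
def zero_noise_record(zero_noise_subject):
    return run_subject(zero_noise_subject, PipelineConfig())


def random_convex_polygon(rng: np.random.Generator, n_points: int = 12, scale: float = 30.0):
    """Convex polygon as the hull of random points (mm), CCW ordered."""
    from scipy.spatial import ConvexHull

    pts = rng.uniform(-scale, scale, size=(max(n_points, 6), 2))
    hull = ConvexHull(pts)
    return pts[hull.vertices]
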