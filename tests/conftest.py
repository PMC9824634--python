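import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msaccid.core import Microsaccade

settings.register_profile(
    "ci", derandomize=True, max_examples=50, database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_event(seed: int, n: int = 20, scale: float = 0.1) -> Microsaccade:
    """A random-walk microsaccade for property/oracle tests."""
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(0.0, scale, (n, 2)), axis=0)
    return Microsaccade(points=pts)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_feature_cohort():
    """Two persons x three segments of raw feature matrices, well separated."""
    rng = np.random.default_rng(42)

    class Rec:
        def __init__(self, pid, segs):
            self.person_id = pid
            self.segments = segs

    def person(center, n_segs=3, n_events=8):
        segs = []
        for _ in range(n_segs):
            segs.append(center + rng.normal(0.0, 0.05, (n_events, 13)))
        return segs

    c1 = rng.uniform(0.5, 1.5, 13)
    c2 = c1 + rng.uniform(1.0, 2.0, 13)
    return [Rec("A", person(c1)), Rec("B", person(c2))]


@pytest.fixture(scope="session")
def e2e_result():
    """The standard synthetic identification study, shared across tests.

    4 persons x 5 fixations of 15 s each, detection with the velocity
    detector, weight learning by 30-restart projected crawl descent on
    the d2 error ratio, identification with robust d3.
    """
    from msaccid.pipeline import end_to_end

    return end_to_end(
        n_persons=4, n_fixations=5, duration_s=15.0, seed=7,
        n_starts=30, max_iter=60,
    )
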