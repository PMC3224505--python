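import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pulsewave as pw

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return pw.default_time_grid()


@pytest.fixture()
def tiny_grid():
    """4-sample grid for hand-sized fixtures."""
    return pw.TimeGrid(
        times=np.array([-1.0, 60.0, 3600.0, 360000.0]),
        labels=("ss1", "60s", "1h", "ss2"),
        is_steady=np.array([True, False, False, True]),
        reference_index=0,
    )


def angle_profiles(angles_deg, n_points=8):
    """Centered profiles whose pairwise PCC equals cos(angle_i - angle_j).

    Built from two orthonormal centered basis vectors, so correlations can
    be engineered exactly for network fixtures.
    """
    rng = np.random.default_rng(12345)
    a = rng.normal(size=n_points)
    b = rng.normal(size=n_points)
    a -= a.mean()
    a /= np.linalg.norm(a)
    b -= b.mean()
    b -= a * (a @ b)
    b /= np.linalg.norm(b)
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return np.outer(np.cos(th), a) + np.outer(np.sin(th), b)


@pytest.fixture()
def angle_expr():
    """Expression series over an 8-point grid built from profile angles."""

    def build(names, angles_deg):
        profs = angle_profiles(angles_deg)
        g = pw.TimeGrid(
            times=np.array([-1.0, 10, 20, 40, 80, 160, 320, 640], dtype=float),
            labels=tuple(f"s{i}" for i in range(8)),
            is_steady=np.array([True] + [False] * 7),
            reference_index=0,
        )
        return pw.ExpressionSeries(tuple(names), profs + 8.0, g)

    return build
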