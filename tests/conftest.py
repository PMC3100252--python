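import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from selentropy import reference_fixtures, worked_examples

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def examples():
    """Hand-written example profiles keyed by name."""
    return worked_examples()


@pytest.fixture(scope="session")
def fixtures():
    """Example panel + expected values + the 38-compound benchmark vector."""
    return reference_fixtures()


@pytest.fixture()
def toy_csv(tmp_path):
    """A small Kd matrix (nM) with a censored and a missing cell."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "compound,KIN1,KIN2,KIN3\n"
        "cmp-a,1,1000,>10000\n"
        "cmp-b,5,,50\n"
    )
    return path


def lorenz_area_bruteforce(values):
    """Geometric oracle: integrate the piecewise-linear Lorenz curve on a fine grid."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    xs = np.concatenate([[0.0], np.arange(1, n + 1) / n])
    ys = np.concatenate([[0.0], np.cumsum(x) / x.sum()])
    grid = np.linspace(0.0, 1.0, 20000 * n + 1)  # multiple of n: nodes hit exactly
    return np.trapezoid(np.interp(grid, xs, ys), grid)
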