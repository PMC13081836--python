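import numpy as np
import pytest

from tractometry.streamlines import ResampledStreamline, Streamline


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_line(offset=0.0, n=20, length=10.0, axis=0, perp=1):
    """Straight resampled line along `axis`, translated by `offset` along `perp`."""
    pts = np.zeros((n, 3))
    pts[:, axis] = np.linspace(0.0, length, n)
    pts[:, perp] = offset
    return ResampledStreamline(points=pts, source_id=f"line_{offset}")


def quarter_circle(radius=10.0, n=100):
    theta = np.linspace(0.0, np.pi / 2, n)
    pts = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)]
    )
    return Streamline(points=pts, id="quarter")


def random_resampled(rng, n_points=12, scale=10.0, source_id=None):
    start = rng.normal(0, scale, 3)
    steps = rng.normal(0, 1.0, (n_points - 1, 3))
    pts = start + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return ResampledStreamline(points=pts, source_id=source_id)


@pytest.fixture
def mother_profile():
    """Bumpy profile with distinct features, identifiable under warping."""

    def mother(t):
        t = np.asarray(t, dtype=float)
        return (
            np.exp(-((t - 0.35) ** 2) / (2 * 0.05**2))
            + 0.8 * np.exp(-((t - 0.7) ** 2) / (2 * 0.04**2))
        )

    return mother
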