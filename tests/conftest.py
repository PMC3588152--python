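import numpy as np
import pytest
from hypothesis import settings

from commstab import CommunityMoments, sample_correlation, validate_moments

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_random_moments(rng: np.random.Generator, n: int) -> CommunityMoments:
    """A random valid community: lognormal means, lognormal sds, and a
    hyperspherically sampled correlation matrix (PSD by construction)."""
    m = np.exp(rng.normal(1.0, 1.0, size=n))
    sd = np.exp(rng.normal(0.0, 0.7, size=n))
    R = sample_correlation(n, rng) if n > 1 else np.ones((1, 1))
    V = R * np.outer(sd, sd)
    return validate_moments(CommunityMoments(m=m, V=V))


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def wide_csv(tmp_path):
    path = tmp_path / "wide.csv"
    path.write_text("time,alder,birch\n1,1,2\n2,2,2\n3,3,2\n")
    return path


@pytest.fixture
def long_csv(tmp_path):
    path = tmp_path / "long.csv"
    rows = ["time,species,abundance"]
    for t, (a, b) in enumerate([(1, 2), (2, 2), (3, 2)], start=1):
        rows.append(f"{t},alder,{a}")
        rows.append(f"{t},birch,{b}")
    path.write_text("\n".join(rows) + "\n")
    return path
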