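import pytest
from hypothesis import settings

from dcbmine import ProfileNetwork

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_net(genes, edges, profiles, condition_names=None):
    """Convenience builder: profiles as dict of lists, NaN for missing."""
    n_cond = len(next(iter(profiles.values())))
    if condition_names is None:
        condition_names = [f"c{i}" for i in range(n_cond)]
    return ProfileNetwork(genes, edges, profiles, condition_names)


@pytest.fixture
def triangle_net():
    """Triangle A-B-C with identical 3-condition profiles."""
    return make_net(
        ["A", "B", "C"],
        [("A", "B"), ("A", "C"), ("B", "C")],
        {"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0], "C": [1.0, 2.0, 3.0]},
    )


@pytest.fixture
def path_net():
    """Path A-B-C with identical profiles."""
    return make_net(
        ["A", "B", "C"],
        [("A", "B"), ("B", "C")],
        {"A": [0.0, 0.0], "B": [0.0, 0.0], "C": [0.0, 0.0]},
    )


@pytest.fixture
def pendant_triangle_net():
    """Triangle A,B,C plus pendant D on C, all profiles identical."""
    return make_net(
        ["A", "B", "C", "D"],
        [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D")],
        {g: [0.5, 0.5, 0.5] for g in "ABCD"},
    )
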