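import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import poms
from poms.simulate import _random_bifurcating_newick

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def four_tip_tree():
    return poms.read_tree("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def abc_tree():
    return poms.read_tree("((A:1,B:1):2,C:3);")


def balanced_newick(n):
    """Balanced tree over n=2^k tips T0..T{n-1}, all branch lengths 1."""
    nodes = [f"T{i}:1" for i in range(n)]
    while len(nodes) > 1:
        nodes = [f"({nodes[i]},{nodes[i+1]}):1" for i in range(0, len(nodes), 2)]
    return nodes[0][: nodes[0].rfind(":")] + ";"


@pytest.fixture
def balanced8():
    return poms.read_tree(balanced_newick(8))


@pytest.fixture
def balanced16():
    return poms.read_tree(balanced_newick(16))


def random_tree(n_tips, seed):
    rng = np.random.default_rng(seed)
    return poms.read_tree(_random_bifurcating_newick(n_tips, rng))


@pytest.fixture(scope="session")
def small_community():
    """A reduced synthetic community shared by read-only tests."""
    return poms.generate_community(
        n_taxa=80, n_samples_per_group=12, n_functions=40, seed=7
    )


@pytest.fixture(scope="session")
def demo():
    return poms.simulate.contrast_demo(seed=0, include_mixed=True)


def random_table(n_taxa, n_samples, seed, prefix="T"):
    rng = np.random.default_rng(seed)
    vals = np.where(rng.random((n_taxa, n_samples)) < 0.3, 0.0,
                    rng.lognormal(1.0, 1.0, (n_taxa, n_samples)))
    return pd.DataFrame(
        vals,
        index=[f"{prefix}{i}" for i in range(n_taxa)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
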