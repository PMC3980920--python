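import numpy as np
import pytest

from typicality import FeatureTable, SynthSpec, make_continuous, make_mixed


def table_from_array(x: np.ndarray) -> FeatureTable:
    """All-continuous FeatureTable from a float matrix."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, p = x.shape
    return FeatureTable(
        [f"u{i}" for i in range(n)],
        x.astype(object),
        ["continuous"] * p,
        np.zeros((n, p), dtype=bool),
        [f"x{j}" for j in range(p)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def separated_classes():
    """Well-separated two-class continuous benchmark (5 sd, n=100, p=5)."""
    return make_continuous(SynthSpec(n_target=100, n_nontarget=100, p=5,
                                     shift=5.0, seed=7))


@pytest.fixture
def mixed_table():
    """Mixed-type table with 20% MCAR missingness."""
    return make_mixed(SynthSpec(n_target=60, n_nontarget=40, p=4, n_ordinal=1,
                                n_binary=2, n_nominal=2, missing_rate=0.2,
                                nominal_levels=3, seed=5))
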