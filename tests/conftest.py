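import numpy as np
import pytest

import placperm as pp


@pytest.fixture(scope="session")
def default_synth():
    """Default study-conditions table (66 x 120) with ground truth, seed 7."""
    return pp.generate(pp.SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def narrow_synth():
    """Narrow table (66 x 40: 5 informative, 15 noise, 20 decoys) for forest-heavy tests."""
    return pp.generate(pp.SyntheticSpec(seed=3, n_noise=15))


@pytest.fixture(scope="session")
def normalized_narrow(narrow_synth):
    table, truth = narrow_synth
    filtered, _ = pp.remove_useless_features(table)
    params = pp.fit_normalizer(filtered)
    return pp.apply_normalizer(filtered, params), params, truth


def make_table(values, ci=None, ids=None, features=None, **kw):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return pp.DescriptorTable(
        chemical_ids=ids or [f"c{i}" for i in range(n)],
        feature_names=features or [f"f{j}" for j in range(p)],
        values=values,
        ci=ci,
        **kw,
    )


@pytest.fixture
def tiny_linear_table():
    """y exactly linear in the single feature x (y = 2x + 1)."""
    x = np.array([0.0, 1.0, 2.0, 3.0])
    return make_table(x[:, None], ci=2 * x + 1)
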