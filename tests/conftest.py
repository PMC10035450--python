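import numpy as np
import pandas as pd
import pytest

import gipipe


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-sample default-condition cohort shared by read-only tests."""
    cfg = gipipe.default_config(n_samples=400, seed=42)
    return cfg, gipipe.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)


@pytest.fixture()
def tiny_expr():
    """3 genes x 4 samples, hand-enumerable."""
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [0.5, 0.5, 0.5, 0.5]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return gipipe.ExpressionMatrix(df)
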