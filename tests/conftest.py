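import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from scipy.optimize import linear_sum_assignment

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


def label_agreement(truth, derived) -> float:
    """Fraction of cells agreeing after optimal one-to-one label matching."""
    cells = sorted(truth.labels)
    a = np.array([truth.labels[c] for c in cells])
    b = np.array([derived.labels[c] for c in cells])
    conf = pd.crosstab(a, b).to_numpy()
    r, c = linear_sum_assignment(-conf)
    return float(conf[r, c].sum() / len(cells))


@pytest.fixture
def agreement():
    return label_agreement


@pytest.fixture
def small_scenario():
    from phytoregions.synthetic import SyntheticScenario
    return SyntheticScenario(grid_rows=10, grid_cols=10, n_regions=4, seed=11)
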