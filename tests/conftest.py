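import numpy as np
import pandas as pd
import pytest

from tnbcstrat.classifier import classify_table
from tnbcstrat.concordance import crosstab
from tnbcstrat.synthetic import reference_cohort

# Published 5x4 cross-tabulation (molecular truth rows x classified columns)
# that the deterministic fixture must reproduce cell for cell.
REFERENCE_COUNTS = {
    "LAR": [34, 1, 4, 6],
    "IM": [10, 38, 7, 7],
    "BL1": [1, 17, 23, 21],
    "M": [13, 1, 10, 56],
    "UNC": [13, 16, 15, 24],
}
REFERENCE_COLUMN_TOTALS = {"LAR": 71, "LP": 73, "LI": 59, "LD": 114}


@pytest.fixture(scope="session")
def fixture_cohort():
    return reference_cohort()


@pytest.fixture(scope="session")
def fixture_classified(fixture_cohort):
    return classify_table(fixture_cohort)


@pytest.fixture(scope="session")
def fixture_crosstab(fixture_classified):
    return crosstab(
        fixture_classified["classified"], fixture_classified["molecular_truth"]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def rule_labeled_grid(n, seed):
    """Cases with labels generated by the shipped decision rule itself."""
    from tnbcstrat.classifier import classify

    r = np.random.default_rng(seed)
    allred = r.integers(0, 9, n)
    til = r.integers(0, 11, n) * 10
    features = pd.DataFrame(
        {"allred_total": allred, "til_percent": til}, dtype=float
    )
    labels = pd.Series([classify(a, t) for a, t in zip(allred, til)])
    return features, labels
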