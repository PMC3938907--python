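import numpy as np
import pytest

from catflow import (
    CategoryScheme,
    MarkovPanelSpec,
    panel_from_values,
    simulate_panel,
)

# transition rows as printed for physical activity (previous low / moderate /
# high); the low row is renormalised to sum to one
ACTIVITY_ROWS = {
    "low": (0.63, 0.20, 0.16),
    "moderate": (0.47, 0.27, 0.26),
    "high": (0.32, 0.24, 0.44),
}


@pytest.fixture
def activity_scheme():
    return CategoryScheme("activity", ("low", "moderate", "high"))


@pytest.fixture
def smoking_scheme():
    return CategoryScheme(
        "smoking", ("never", "current", "ex"), monotone_absorbing_source="never"
    )


@pytest.fixture
def smoking_chain():
    """Row-stochastic smoking-style chain honouring the absorbing source."""
    return np.array(
        [
            [0.90, 0.07, 0.03],
            [0.00, 0.70, 0.30],
            [0.00, 0.15, 0.85],
        ]
    )


@pytest.fixture
def smoking_panel(smoking_scheme, smoking_chain):
    spec = MarkovPanelSpec(
        scheme=smoking_scheme,
        n_subjects=2000,
        waves=(2, 3, 4, 5),
        initial_dist=np.array([0.5, 0.3, 0.2]),
        transition=smoking_chain,
        monotone=True,
    )
    return simulate_panel(spec, seed=20240201)


def activity_counts_panel(scheme, per_row=10000):
    """Two-wave panel whose transition frequencies follow ACTIVITY_ROWS."""
    values = []
    for prev, probs in ACTIVITY_ROWS.items():
        p = np.asarray(probs) / np.sum(probs)
        counts = np.rint(p * per_row).astype(int)
        counts[0] += per_row - counts.sum()
        for lvl, c in zip(scheme.levels, counts):
            values.extend([[prev, lvl]] * int(c))
    return panel_from_values(values, (4, 5), scheme)


@pytest.fixture
def activity_panel(activity_scheme):
    return activity_counts_panel(activity_scheme)
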