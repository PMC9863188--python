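import numpy as np
import pandas as pd
import pytest

from symptomlca import (
    LatentClassModel,
    build_indicator_matrix,
    generate_cohort,
    scenario_library,
)


@pytest.fixture(scope="session")
def high_sep_cohort():
    """Small well-separated cohort used by several diagnostic tests."""
    spec = scenario_library()["high_separation"]
    spec.n = 1500
    return generate_cohort(spec, seed=11, render_records=False)


@pytest.fixture(scope="session")
def high_sep_fit(high_sep_cohort):
    ind = build_indicator_matrix(high_sep_cohort.survey)
    model = LatentClassModel(
        n_classes=4, n_starts=6, random_state=11, tol=1e-6, max_iter=2000
    ).fit(ind)
    return model, ind, high_sep_cohort


@pytest.fixture
def toy_binary_data():
    """All 8 patterns of 3 binary items with fixed counts (n = 36)."""
    patterns = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    counts = [6, 5, 4, 3, 6, 5, 4, 3]
    rows = [p for p, c in zip(patterns, counts) for _ in range(c)]
    return pd.DataFrame(rows, columns=["i1", "i2", "i3"]), patterns, counts


def align_classes(rho_fit, rho_true):
    """Permutation of fitted classes minimising total L1 distance to the truth."""
    from scipy.optimize import linear_sum_assignment

    C = rho_true.shape[0]
    cost = np.zeros((C, C))
    for a in range(C):
        for b in range(C):
            cost[a, b] = np.abs(rho_fit[a] - rho_true[b]).sum()
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(C, dtype=int)
    perm[cols] = rows
    return perm  # fitted index for each true class
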