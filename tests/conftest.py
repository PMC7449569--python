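import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import designdiag as dd

settings.register_profile("fixed", derandomize=True, deadline=None)
settings.load_profile("fixed")


@pytest.fixture
def canonical():
    return dd.make_design("table3_canonical")


@pytest.fixture
def tiny_canonical():
    """Shrunken two-arm design for cheap repeated simulation."""
    return dd.make_design("table3_canonical", n_pop=20, n_samp=10, m_treat=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def fixed_units_design(u_values, m_treat, effect=1.0, name="fixed_units"):
    """Two-arm design over a fixed unit vector: the only randomness is the
    complete assignment, so exact enumeration over assignments is feasible."""
    u = np.asarray(u_values, dtype=float)

    steps = [
        dd.declare_population(len(u), {"u": lambda df, rng: u.copy()}),
        dd.declare_potential_outcomes(
            "Y", dd.ConditionSet("Z", [0, 1]),
            lambda df, z: df["u"].to_numpy() + effect * z),
        dd.declare_inquiry("ATE", "summary", expr="mean(Y_Z_1 - Y_Z_0)"),
        dd.declare_assignment("complete", m=m_treat),
        dd.declare_reveal("Y", "Z"),
        dd.declare_estimator(dd.difference_in_means, "DIM", estimand="ATE",
                             outcome="Y", assignment="Z"),
    ]
    return dd.compose_design(steps, name)


@pytest.fixture
def simple_sims():
    """Hand-built simulation table: estimates {1.2, 0.8} about estimand 1."""
    return pd.DataFrame({
        "run": [0, 1],
        "run_seed": [0, 1],
        "estimator_label": ["E", "E"],
        "estimand_label": ["I", "I"],
        "estimand": [1.0, 1.0],
        "estimate": [1.2, 0.8],
        "std_error": [0.1, 0.1],
        "p_value": [0.01, 0.20],
        "ci_low": [1.0, 0.6],
        "ci_high": [1.4, 1.0],
        "df": [10.0, 10.0],
    })
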