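import numpy as np
import pytest

from stentopt import RESPONSES, TABLE1_SPACE, load_table4, load_table5
from stentopt.rsm import eq5_terms, fit
from stentopt.surrogate import DEFAULT_SIGMA, SurrogateTruth


@pytest.fixture(scope="session")
def table4():
    return load_table4()


@pytest.fixture(scope="session")
def table5():
    return load_table5()


@pytest.fixture(scope="session")
def doe1_models(table4):
    """Reduced ten-term models per response, natural units."""
    return {m.key: fit(table4, m.key, eq5_terms(), units="natural") for m in RESPONSES}


@pytest.fixture(scope="session")
def interior_truth():
    """A ground truth whose surfaces stay strictly inside the physical
    ranges over the whole box, so clamping never distorts recovery."""
    from stentopt.rsm import interaction, intercept, linear, quadratic

    terms = (
        intercept(),
        linear("w"),
        linear("SA"),
        quadratic("SA"),
        interaction("t", "SA"),
    )
    # magnitudes chosen so each response varies well inside its range
    beta = {
        "mean_stress": np.array([30.0, 0.04, -8.0, 2.0, 1e-3]),
        "high_stress_area": np.array([20.0, 0.02, -4.0, 1.0, 5e-4]),
        "apposition": np.array([60.0, 0.05, -6.0, 1.5, 2e-3]),
        "pinching": np.array([1.5, 4e-4, -0.1, 0.03, 1e-5]),
    }
    return SurrogateTruth(
        space=TABLE1_SPACE,
        terms={k: terms for k in beta},
        beta=beta,
        sigma=dict(DEFAULT_SIGMA),
    )
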