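import numpy as np
import pytest

from genetoxbmd import ExpModelParams, StudyDesign, evaluate


@pytest.fixture(scope="session")
def study_design() -> StudyDesign:
    return StudyDesign()


def simulate_xy(
    model_id: str,
    params: ExpModelParams,
    design: StudyDesign,
    sigma: float,
    seed: int,
):
    """Log-normal responses from a known mean curve on the study design."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([[d] * n for d, n in design.group_sizes()])
    mu = np.asarray(evaluate(model_id, params, x), dtype=float)
    if sigma > 0:
        y = mu * np.exp(rng.normal(0.0, sigma, size=x.size))
    else:
        y = mu.copy()
    return x, y
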