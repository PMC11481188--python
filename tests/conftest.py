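import numpy as np
import pandas as pd
import pytest

from cardioage import preprocess, synth


@pytest.fixture(scope="session")
def default_truth():
    return synth.default_ground_truth(seed=7)


@pytest.fixture(scope="session")
def cohort(default_truth):
    """One simulated cohort shared across tests: counts, scaled matrix, ages."""
    expr = synth.generate_expression(default_truth)
    counts = preprocess.filter_low_counts(expr.counts)
    norm = preprocess.tmm_normalize(counts)
    scaled = preprocess.scale_per_transcript(norm.matrix)
    ages = np.asarray(default_truth.sample_ages)
    return {"expr": expr, "counts": counts, "norm": norm, "scaled": scaled, "ages": ages}


@pytest.fixture()
def toy_counts():
    rng = np.random.default_rng(42)
    mat = rng.negative_binomial(5, 0.01, size=(50, 6))
    return pd.DataFrame(
        mat,
        index=[f"T{i}" for i in range(50)],
        columns=[f"S{j}" for j in range(6)],
    )
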