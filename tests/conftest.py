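import numpy as np
import pytest

from mirgenet import generate_cohort
from mirgenet.io import ClassLabels, ExpressionMatrix


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort (14+26, 614 miRNAs, 2000 genes)."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast pipeline-level tests."""
    return generate_cohort(
        p_mirna=150, q_gene=300, n_null_sets=8, n_low_detection=5, seed=7
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_matrix(values, prefix="F", sample_prefix="S", detected=None):
    """Helper building an ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return ExpressionMatrix(
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n)],
        feature_ids=[f"{prefix}{j + 1}" for j in range(m)],
        values=values,
        detected=detected,
    )


def toy_labels(assignment):
    """Labels from a 0/1 sequence (0 -> 'a', 1 -> 'b')."""
    return ClassLabels(
        [f"S{i + 1}" for i in range(len(assignment))],
        ["a" if c == 0 else "b" for c in assignment],
    )
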