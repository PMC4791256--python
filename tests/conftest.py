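import numpy as np
import pytest

import specsel as ss


@pytest.fixture
def toy_matrix() -> ss.SpectralCountMatrix:
    """3 proteins x 2 runs with column sums (8, 5)."""
    return ss.SpectralCountMatrix(
        ("P1", "P2", "P3"), ("r1", "r2"),
        np.array([[1, 0], [2, 2], [5, 3]]),
    )


@pytest.fixture
def two_class_ann() -> ss.SampleAnnotation:
    return ss.SampleAnnotation(
        ("a1", "a2", "b1", "b2"), ("A", "A", "B", "B"), (1, 2, 1, 2))


@pytest.fixture(scope="session")
def planted_small():
    """A small planted experiment shared across tests (expensive stages)."""
    spec = ss.simulate.planted_spec(10, 10.0, n_proteins=150, seed=21)
    m, ann, truth = ss.generate_counts(spec)
    return m, ann, truth
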