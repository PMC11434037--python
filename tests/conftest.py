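import numpy as np
import pytest

from hypoximm.types import ExpressionMatrix


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if (a | b) else 1.0


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    vals = rng.poisson(5.0, size=(20, 6)).astype(float)
    return ExpressionMatrix(
        [f"g{i}" for i in range(20)], [f"s{j}" for j in range(6)], vals,
        "raw_counts",
    )


@pytest.fixture(scope="session")
def strong_slide():
    """One strongly separated synthetic slide, shared across tests."""
    from hypoximm.simulate import SlideSimParams, simulate_slide

    return simulate_slide(SlideSimParams.strong_separation(seed=1))
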