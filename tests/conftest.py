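import numpy as np
import pytest
from hypothesis import settings

from seizurespec import FoldDataset, SimConfig, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation paths they check)


def brute_dft_magnitude(x: np.ndarray) -> np.ndarray:
    """Naive O(N^2) direct-summation DFT magnitude, all N bins."""
    n = x.size
    k = np.arange(n)
    basis = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return np.abs(basis @ x.astype(complex))


def two_pass_population_std(x: np.ndarray) -> float:
    """Definition-level population standard deviation (divisor N)."""
    m = sum(x) / len(x)
    return (sum((v - m) ** 2 for v in x) / len(x)) ** 0.5


def weighted_average_score(spectrum: np.ndarray, weights: np.ndarray) -> float:
    """Direct elementwise multiply-and-sum SCR oracle."""
    num = sum(w * s for w, s in zip(weights, spectrum))
    den = sum(spectrum)
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Three short labeled recordings (0.2 h each), one seizure apiece."""
    return simulate_cohort(SimConfig(duration_h=0.2, seed=11), k=3)


@pytest.fixture(scope="session")
def small_folds(small_cohort):
    return [
        FoldDataset(recording=rec, annotation=ann, fold_id=rec.subject_id)
        for rec, ann in small_cohort
    ]
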