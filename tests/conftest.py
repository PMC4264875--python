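import numpy as np
import pytest

from netrep import synth


@pytest.fixture(scope="session")
def small_gt():
    """12-node, 3-module ground truth with one hub."""
    return synth.build_ground_truth(
        n_nodes=12, n_modules=3, within_strength=0.25,
        between_strength=0.05, n_hubs=1, seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_gt):
    """4 subjects x 4 runs, mild between-subject jitter."""
    return synth.sample_panel(
        small_gt, n_subjects=4, n_runs=4, t_per_run=150,
        subject_jitter_sd=0.05, seed=11,
    )


@pytest.fixture(scope="session")
def five_run_panel(small_gt):
    """3 subjects x 5 runs (the odd-run split-half case)."""
    return synth.sample_panel(
        small_gt, n_subjects=3, n_runs=5, t_per_run=120,
        subject_jitter_sd=0.0, seed=5,
    )


def random_binary_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    upper = np.triu(rng.random((n, n)) < p, 1).astype(float)
    return upper + upper.T


def random_weighted_matrix(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    upper = np.triu((rng.random((n, n)) < p) * rng.random((n, n)), 1)
    return upper + upper.T
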