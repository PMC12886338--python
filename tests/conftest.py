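"""Shared fixtures: phantom cohorts and trained reference runs.

The "standard" cohort (300 subjects, 3 classes, 2 sites, 16x16, 1-4 visits)
and its trained model are session-scoped because several end-to-end tests
share them; everything is deterministically seeded.
"""

import numpy as np
import pytest

from neurofact import (LossWeights, ModelConfig, OptimConfig, PhantomConfig,
                       sample_cohort)
from neurofact.training import evaluate, train

STANDARD_PHANTOM_SEED = 11
STANDARD_TRAIN_SEED = 0


@pytest.fixture(scope="session")
def small_cohort():
    return sample_cohort(PhantomConfig(n_subjects=60, seed=7))


@pytest.fixture(scope="session")
def standard_cohort():
    return sample_cohort(PhantomConfig(seed=STANDARD_PHANTOM_SEED))


@pytest.fixture(scope="session")
def standard_run(standard_cohort):
    """Full training run on the standard phantom with default weights."""
    model, stats, history, split = train(
        standard_cohort, ModelConfig(), LossWeights(), OptimConfig(),
        seed=STANDARD_TRAIN_SEED)
    report = evaluate(model, standard_cohort, split["test"], stats,
                      seed=STANDARD_TRAIN_SEED)
    return {"ds": standard_cohort, "model": model, "stats": stats,
            "history": history, "split": split, "report": report}


def numerical_gradient(fn, x, eps=1e-6):
    """Central finite differences of a scalar function of one array."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (fn(xp) - fn(xm)) / (2 * eps)
    return g
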