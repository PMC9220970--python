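"""Shared fixtures: synthetic corpora and trained models (built once per session)."""

import numpy as np
import pytest

from ssca import (
    NetworkLayout,
    TrainConfig,
    WindowConfig,
    detect_chain_breaks,
    featurize_chain,
    init_mlp,
    make_dataset,
    train,
    trace_from_coords,
)
from ssca.hbond import HbondCriteria, hbond_counts

#: seed defining the synthetic study conditions used throughout the suite
DATASET_SEED = 20260101


def random_walk_trace(rng, n, step=3.8):
    """Unconstrained random walk with fixed step: arbitrary fuzz input."""
    steps = rng.normal(size=(n - 1, 3))
    steps = step * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    return trace_from_coords(np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]))


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation vector."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    return R, rng.uniform(-50, 50, size=3)


def featurize_corpus(corpus, window, criteria=HbondCriteria()):
    """Stack per-chain feature matrices; returns (X, y, groups)."""
    X_parts, y_parts, groups = [], [], []
    for name, trace, labels in corpus:
        breaks = detect_chain_breaks(trace) if len(trace) >= 2 else []
        hb = hbond_counts(trace, criteria) if "hbonds" in window.feature_set else None
        X, centers = featurize_chain(trace, hb, window, breaks=breaks)
        if X.shape[0] == 0:
            continue
        X_parts.append(X)
        y_parts.append("".join(labels[c] for c in centers))
        groups.extend([name] * X.shape[0])
    return np.vstack(X_parts), "".join(y_parts), np.array(groups)


@pytest.fixture(scope="session")
def synthetic_corpus():
    """600 mixed helix/sheet/coil chains: the training corpus."""
    return make_dataset(600, seed=DATASET_SEED)


@pytest.fixture(scope="session")
def trained(synthetic_corpus):
    """Full-feature N=11 model trained on the corpus with a chain-level 80/20 split.

    Returns (result, X, y, groups) so tests can score the held-out windows.
    """
    window = WindowConfig(n=11)
    X, y, groups = featurize_corpus(synthetic_corpus, window)
    model = init_mlp(
        NetworkLayout(input_width=window.width),
        seed=DATASET_SEED,
        window_config=window,
    )
    cfg = TrainConfig(epochs=150, seed=DATASET_SEED)
    result = train(model, X, y, cfg, groups=groups)
    return result, X, y, groups


@pytest.fixture(scope="session")
def trained_model(trained):
    return trained[0].model
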