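"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from m6aflow import SimulationConfig, simulate_networks
from m6aflow.encoding import encode_candidates
from m6aflow.simulate import simulate_training_set


@pytest.fixture(scope="session")
def small_training():
    """A reduced planted training set: candidates, encodings and labels."""
    cfg = SimulationConfig(n_positive_sites=120, n_negative_sites=360)
    candidates, transcriptome, coverage = simulate_training_set(cfg, seed=11)
    y = np.array([1 if c.label == "positive" else 0 for c in candidates])
    return {
        "config": cfg,
        "candidates": candidates,
        "transcriptome": transcriptome,
        "coverage": coverage,
        "X_cov": encode_candidates(candidates),
        "X_seq": encode_candidates(candidates, sequence_only=True),
        "y": y,
    }


@pytest.fixture(scope="session")
def network_fixture():
    """Four overlapping networks with a planted hot module."""
    return simulate_networks(seed=5)
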