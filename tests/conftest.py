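"""Shared fixtures, including the reference-design replicated-chain run.

The replicated run (30 items, difficulties uniform(-2,2), 100,000
standard-normal persons, 500 short chains) is expensive, so it is computed
once per session and shared between the convergence-diagnostics tests and
the acceptance tests.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from margrasch import (default_design, replicated_chains, simulate_latent_rasch,
                       sufficient_statistics)

# acceptance-scale constants (replications scaled down from the original
# 5000 to 500; monitored parameters are b_2 and lambda_10)
N_CHAINS = 500
N_ITER = 110
MONITOR = (("b", 1), ("lam", 10))
REF_SEED = 20240901


def brute_force_esf(b) -> np.ndarray:
    """ESFs by direct enumeration of all subsets (oracle, n <= ~15)."""
    b = np.asarray(b, dtype=float)
    n = b.size
    gamma = np.zeros(n + 1)
    for pattern in itertools.product((0, 1), repeat=n):
        x = np.array(pattern)
        gamma[x.sum()] += np.prod(b**x)
    return gamma


def brute_force_pattern_probs(b, lam) -> dict[tuple, float]:
    """Extended-model pattern probabilities by full enumeration (oracle)."""
    b = np.asarray(b, dtype=float)
    lam = np.asarray(lam, dtype=float)
    raw = {}
    for pattern in itertools.product((0, 1), repeat=b.size):
        x = np.array(pattern)
        raw[pattern] = float(np.prod(b**x) * lam[x.sum()])
    z = sum(raw.values())
    return {p: v / z for p, v in raw.items()}


@pytest.fixture(scope="session")
def reference_dataset():
    """The reference simulation design: one dataset, its truth, its stats."""
    rng = np.random.default_rng(REF_SEED)
    delta = default_design(30, rng=rng)
    X = simulate_latent_rasch(100_000, delta, rng=rng)
    return {"delta": delta, "stats": sufficient_statistics(X)}


@pytest.fixture(scope="session")
def reference_replicated(reference_dataset):
    """(n_chains, n_iter, 2) trajectories of b_2 and lambda_10."""
    return replicated_chains(reference_dataset["stats"], N_CHAINS, N_ITER,
                             MONITOR, seed=REF_SEED + 1)
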