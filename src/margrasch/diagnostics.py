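"""Convergence and fit diagnostics for the Gibbs sampler.

Three instruments: cross-replication ECDF comparison at successive
iterations (a chain is converged once the parameter's distribution stops
changing between iterations), autocorrelation of retained draws, and the
observed versus model-implied item-rest regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sampler import GibbsDraws

__all__ = [
    "convergence_ecdf",
    "first_converged_iteration",
    "autocorrelation",
    "pooled_autocorrelation",
    "ItemRestFit",
    "item_rest_fit",
]

NEGLIGIBLE_AUTOCORR = 0.1


def convergence_ecdf(samples_t: np.ndarray, samples_t1: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic and p-value between cross-replication samples.

    ``samples_t`` and ``samples_t1`` hold one value per replicated chain at
    iterations t and t+1; coinciding ECDFs indicate convergence.
    """
    a = np.asarray(samples_t, dtype=float)
    b = np.asarray(samples_t1, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two replications per iteration")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def first_converged_iteration(traj: np.ndarray, alpha: float = 0.05) -> int:
    """Smallest t (1-based) from which successive-iteration KS tests all pass.

    ``traj`` has shape (n_chains, n_iter); iteration t is compared with
    t+1 for t = 1..n_iter-1 and the first t after the last rejection is
    returned.
    """
    traj = np.asarray(traj, dtype=float)
    n_iter = traj.shape[1]
    last_reject = 0
    for t in range(n_iter - 1):
        _, p = convergence_ecdf(traj[:, t], traj[:, t + 1])
        if p < alpha:
            last_reject = t + 1  # 1-based iteration index
    return last_reject + 1


def autocorrelation(chain: np.ndarray, max_lag: int, burn_in: int = 0) -> np.ndarray:
    """Sample autocorrelation of one chain at lags 0..max_lag."""
    x = np.asarray(chain, dtype=float)[burn_in:]
    if x.size <= max_lag:
        raise ValueError("chain (after burn-in) must be longer than max_lag")
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("degenerate (constant) chain")
    r = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        r[k] = (x[: x.size - k] @ x[k:]) / denom
    return r


def pooled_autocorrelation(traj: np.ndarray, max_lag: int,
                           burn_in: int = 0) -> np.ndarray:
    """Autocorrelation estimated by pooling many replicated chains.

    ``traj`` has shape (n_chains, n_iter); autocovariances are averaged
    over chains (per-chain centring) and normalised by the pooled variance.
    """
    x = np.asarray(traj, dtype=float)[:, burn_in:]
    if x.shape[1] <= max_lag:
        raise ValueError("retained length must exceed max_lag")
    x = x - x.mean(axis=1, keepdims=True)
    denom = float((x * x).sum())
    r = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        r[k] = (x[:, : x.shape[1] - k] * x[:, k:]).sum() / denom
    return r


@dataclass(frozen=True)
class ItemRestFit:
    """Observed vs model-implied item-rest regression curves.

    ``table`` has one row per (item, rest score) cell with counts, the
    observed proportion correct and the posterior-mean implied probability;
    empty cells are flagged rather than dropped.  ``discrepancy[i]`` is the
    count-weighted maximum absolute difference for item i, with sqrt(count)
    weights so that every cell's contribution is on a common (z-like) scale
    — proportional n/m weights would drown misfit that lives in sparse
    rest-score cells, e.g. a guessing floor.
    """

    table: pd.DataFrame
    discrepancy: np.ndarray
    skipped_cells: list = field(default_factory=list)


def item_rest_fit(X: np.ndarray, draws: GibbsDraws) -> ItemRestFit:
    """Compare observed item-rest curves with the fitted model's.

    The model-implied curve for item i at rest score s is the posterior
    mean of b_i τ_s / (1 + b_i τ_s) with τ_s = λ_{s+1}/λ_s taken from each
    retained draw (the item-rest regression depends on the other items
    only through the rest score).
    """
    X = np.asarray(X)
    m, n = X.shape
    if n != draws.n_items:
        raise ValueError("X and draws disagree on the number of items")
    if not np.all(np.isin(X, (0, 1))):
        raise ValueError("X must be complete 0/1 data")
    totals = X.sum(axis=1)
    tau = draws.tau()  # (n_draws, n)
    rows = []
    skipped = []
    disc = np.zeros(n)
    for i in range(n):
        rest = totals - X[:, i]
        b_i = draws.b[:, i][:, None]  # (n_draws, 1)
        u = b_i * tau  # implied odds at each rest score
        implied = (u / (1.0 + u)).mean(axis=0)  # (n,) rest scores 0..n-1
        for s in range(n):
            in_cell = rest == s
            count = int(in_cell.sum())
            if count == 0:
                skipped.append((i, s))
                rows.append({"item": i, "rest_score": s, "count": 0,
                             "observed": np.nan, "implied": implied[s],
                             "empty": True})
                continue
            obs = float(X[in_cell, i].mean())
            rows.append({"item": i, "rest_score": s, "count": count,
                         "observed": obs, "implied": float(implied[s]),
                         "empty": False})
            disc[i] = max(disc[i], np.sqrt(count) * abs(obs - implied[s]))
    return ItemRestFit(pd.DataFrame(rows), disc, skipped)
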