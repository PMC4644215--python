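"""Synthetic response data and quadrature ground truth.

Two generating routes are provided:

* the latent route — draw an ability per person from a population density
  and generate item responses from the Rasch response function; and
* the extended route — draw a sum score from the manifest score
  distribution and then a pattern conditional on the score, which never
  touches a latent variable.

When the score parameters λ are computed from the population density by
numeric integration, the two routes generate from the same manifest law.
The quadrature functions here serve as independent oracles for the
sampler's estimands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .esf import esf_log
from .model import ItemParams, ScoreParams, score_distribution

__all__ = [
    "AbilityDistribution",
    "default_design",
    "simulate_latent_rasch",
    "simulate_extended",
    "lambda_from_ability",
    "quadrature_tau",
]

_GRID_LO, _GRID_HI, _GRID_N = -10.0, 10.0, 4001


@dataclass(frozen=True)
class AbilityDistribution:
    """A named ability density with a log-pdf evaluator and a sampler."""

    name: str
    log_pdf: Callable[[np.ndarray], np.ndarray]
    sample: Callable[[np.random.Generator, int], np.ndarray]
    params: dict = field(default_factory=dict)

    @staticmethod
    def normal(mean: float = 0.0, sd: float = 1.0) -> "AbilityDistribution":
        if sd <= 0:
            raise ValueError("sd must be positive")
        return AbilityDistribution(
            name="normal",
            log_pdf=lambda t: stats.norm.logpdf(t, loc=mean, scale=sd),
            sample=lambda rng, size: rng.normal(mean, sd, size=size),
            params={"mean": mean, "sd": sd},
        )

    def check_normalized(self, tol: float = 1e-8) -> None:
        grid, logw = _grid()
        mass = np.exp(logsumexp(self.log_pdf(grid) + logw))
        if abs(mass - 1.0) > tol:
            raise ValueError(f"density mass {mass} deviates from 1 beyond {tol}")


def _grid(lo: float = _GRID_LO, hi: float = _GRID_HI,
          n: int = _GRID_N) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes and log Simpson weights (n must be odd)."""
    grid = np.linspace(lo, hi, n)
    h = (hi - lo) / (n - 1)
    w = np.full(n, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    return grid, np.log(w * h / 3.0)


def default_design(n_items: int = 30, rng: np.random.Generator | None = None,
                   seed: int | None = None) -> np.ndarray:
    """Item difficulties drawn uniformly between -2 and 2."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.uniform(-2.0, 2.0, size=n_items)


def simulate_latent_rasch(m: int, difficulties: np.ndarray,
                          ability: AbilityDistribution | None = None,
                          rng: np.random.Generator | None = None,
                          seed: int | None = None) -> np.ndarray:
    """Draw an m × n binary response matrix through the latent route.

    Each person's ability is drawn from ``ability`` (standard normal by
    default); responses are independent Bernoulli with success probability
    ``logistic(θ - δ_i)``.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    delta = np.asarray(difficulties, dtype=float)
    if ability is None:
        ability = AbilityDistribution.normal()
    if rng is None:
        rng = np.random.default_rng(seed)
    theta = ability.sample(rng, m)
    # P(correct) = 1 / (1 + exp(δ - θ))
    p = 1.0 / (1.0 + np.exp(delta[None, :] - theta[:, None]))
    return (rng.random((m, delta.size)) < p).astype(np.int8)


def simulate_extended(m: int, items: ItemParams, scores: ScoreParams,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> np.ndarray:
    """Draw responses directly from the extended model, without abilities.

    A sum score is drawn from π, then the pattern given the score is built
    item by item: the last remaining item is correct with probability
    ``b_n γ_{s-1}(b without n) / γ_s(b)``, recursing on the rest.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = items.n_items
    pi = score_distribution(items, scores).pi
    scores_drawn = rng.choice(n + 1, size=m, p=pi)

    # prefix ESFs: esfs[k] covers items 0..k-1
    lg_prefix = [esf_log(items.b[:k]).log_gamma if k >= 1 else np.zeros(1)
                 for k in range(n + 1)]
    X = np.zeros((m, n), dtype=np.int8)
    u = rng.random((m, n))
    for p in range(m):
        s = int(scores_drawn[p])
        for i in range(n - 1, -1, -1):
            # remaining items are 0..i; need score s among them
            if s == 0:
                break
            if s == i + 1:
                X[p, : i + 1] = 1
                break
            lg_wo = lg_prefix[i]  # items 0..i-1
            log_p1 = np.log(items.b[i]) + lg_wo[s - 1] - lg_prefix[i + 1][s]
            if u[p, i] < np.exp(log_p1):
                X[p, i] = 1
                s -= 1
    return X


def lambda_from_ability(difficulties: np.ndarray,
                        ability: AbilityDistribution | None = None) -> ScoreParams:
    """Score parameters implied by a population density, by quadrature.

    ``λ_s = E[exp(sΘ) | all items wrong]``, computed as a ratio of
    log-integrals on a fixed Simpson grid (λ_0 = 1 by construction).
    """
    delta = np.asarray(difficulties, dtype=float)
    if ability is None:
        ability = AbilityDistribution.normal()
    grid, logw = _grid()
    # log of ∫ exp(sθ) Π_i (1+exp(θ-δ_i))^-1 f(θ) dθ for s = 0..n
    log_k = (-np.sum(np.log1p(np.exp(grid[:, None] - delta[None, :])), axis=1)
             + ability.log_pdf(grid) + logw)
    s = np.arange(delta.size + 1)
    log_i = logsumexp(s[:, None] * grid[None, :] + log_k[None, :], axis=1)
    return ScoreParams(np.exp(log_i - log_i[0]))


def quadrature_tau(difficulties: np.ndarray, ability: AbilityDistribution | None,
                   s: int) -> float:
    """E[exp(Θ) | sum score = s] by numeric integration.

    Defined for ``0 <= s <= n-1``; the expectation for a perfect score is
    not an estimand of the model.
    """
    delta = np.asarray(difficulties, dtype=float)
    n = delta.size
    if not 0 <= s <= max(n - 1, 0):
        raise ValueError(f"score {s} out of the estimable range 0..{n - 1}")
    if ability is None:
        ability = AbilityDistribution.normal()
    grid, logw = _grid()
    log_k = (-np.sum(np.log1p(np.exp(grid[:, None] - delta[None, :])), axis=1)
             + ability.log_pdf(grid) + logw)
    num = logsumexp((s + 1) * grid + log_k)
    den = logsumexp(s * grid + log_k)
    return float(np.exp(num - den))
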