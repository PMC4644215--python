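"""The extended marginal Rasch likelihood and its reparametrizations.

The manifest distribution is

    P(x) = Π_i b_i^{x_i} λ_{x_+} / Σ_s γ_s(b) λ_s

with item easiness ``b_i > 0`` and non-negative score parameters
``λ_0..λ_n``.  The λ ratios ``τ_s = λ_{s+1}/λ_s`` are the posterior
expectations of exp(ability) given a sum score of ``s``, which is what
makes this parametrization useful for measurement.

The (b, λ) parameters are identified only up to a joint rescaling; see
:func:`rescale_identify`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .esf import EsfVector, esf_log

__all__ = [
    "ItemParams",
    "ScoreParams",
    "TauParams",
    "ScoreDistribution",
    "log_normalizer",
    "pattern_log_prob",
    "score_distribution",
    "conditional_pattern_log_prob",
    "item_rest_probability",
    "collapse_item",
    "reparameterize",
    "tau_to_scores",
    "rescale_identify",
]


@dataclass(frozen=True)
class ItemParams:
    """Item easiness vector ``b`` (easiness = exp(-difficulty))."""

    b: np.ndarray
    ref_item: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "b", b)
        if b.ndim != 1 or b.size < 1:
            raise ValueError("b must be a non-empty 1-d vector")
        if not np.all(np.isfinite(b)) or np.any(b <= 0):
            raise ValueError("all b_i must be positive and finite")
        if not 0 <= self.ref_item < b.size:
            raise IndexError("ref_item out of range")

    @property
    def n_items(self) -> int:
        return self.b.size

    @property
    def difficulties(self) -> np.ndarray:
        return -np.log(self.b)


@dataclass(frozen=True)
class ScoreParams:
    """Score parameters ``λ_0..λ_n`` (non-negative)."""

    lam: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lam, dtype=float)
        object.__setattr__(self, "lam", lam)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("lam must hold at least λ_0 and λ_1")
        if not np.all(np.isfinite(lam)) or np.any(lam < 0):
            raise ValueError("all λ_s must be non-negative and finite")
        if not np.any(lam > 0):
            raise ValueError("at least one λ_s must be positive")

    @property
    def n_items(self) -> int:
        return self.lam.size - 1


@dataclass(frozen=True)
class TauParams:
    """Score-indexed EAPs of exp(ability): ``τ_s = λ_{s+1}/λ_s``.

    ``available[s]`` is False where the ratio is undefined (zero λ).  τ for
    a perfect score does not exist in the model at all; its absence is
    structural, not numerical.
    """

    tau: np.ndarray
    available: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        object.__setattr__(self, "tau", tau)
        avail = self.available
        if avail is None:
            avail = np.isfinite(tau)
        object.__setattr__(self, "available", np.asarray(avail, dtype=bool))

    def is_monotone(self, atol: float = 0.0) -> bool:
        t = self.tau[self.available]
        return bool(np.all(np.diff(t) >= -atol))


@dataclass(frozen=True)
class ScoreDistribution:
    """Manifest score distribution ``π_s = γ_s λ_s / Σ_t γ_t λ_t``."""

    pi: np.ndarray

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        object.__setattr__(self, "pi", pi)
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be a probability vector")


def _log_lam(lam: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(lam)


def log_normalizer(items: ItemParams, scores: ScoreParams,
                   esf: EsfVector | None = None) -> float:
    """``log Σ_s γ_s(b) λ_s``, the log of the reciprocal of μ."""
    if scores.n_items != items.n_items:
        raise ValueError("lam must have length n_items + 1")
    if esf is None:
        esf = esf_log(items.b)
    return float(logsumexp(esf.log_gamma + _log_lam(scores.lam)))


def pattern_log_prob(x: np.ndarray, items: ItemParams,
                     scores: ScoreParams) -> float:
    """Log-probability of a full response pattern under the extended model.

    Returns ``-inf`` (not an error) when ``λ_{x_+} = 0``: the pattern is
    impossible under the parameters, not invalid input.
    """
    x = np.asarray(x)
    if x.shape != (items.n_items,) or not np.all(np.isin(x, (0, 1))):
        raise ValueError("x must be a binary vector of length n_items")
    s = int(x.sum())
    num = float(x @ np.log(items.b)) + float(_log_lam(scores.lam)[s])
    return num - log_normalizer(items, scores)


def score_distribution(items: ItemParams, scores: ScoreParams) -> ScoreDistribution:
    """``π_s = γ_s(b) λ_s / Σ_t γ_t(b) λ_t``."""
    esf = esf_log(items.b)
    logw = esf.log_gamma + _log_lam(scores.lam)
    logz = logsumexp(logw)
    if not np.isfinite(logz):
        raise ValueError("score distribution undefined: all γ_s λ_s are zero")
    pi = np.exp(logw - logz)
    return ScoreDistribution(pi / pi.sum())


def conditional_pattern_log_prob(x: np.ndarray, items: ItemParams) -> float:
    """Log-probability of a pattern given its sum score: Π b^x / γ_{x_+}.

    This is the conditional-likelihood factor; it does not involve λ.
    """
    x = np.asarray(x)
    if x.shape != (items.n_items,) or not np.all(np.isin(x, (0, 1))):
        raise ValueError("x must be a binary vector of length n_items")
    esf = esf_log(items.b)
    return float(x @ np.log(items.b)) - float(esf.log_gamma[int(x.sum())])


def item_rest_probability(b_i: float, tau_rest: float) -> float:
    """Item-rest regression: P(correct | rest score) = b_i τ / (1 + b_i τ).

    Depends on the other items only through τ at the rest score.
    """
    if b_i <= 0:
        raise ValueError("b_i must be positive")
    if tau_rest < 0:
        raise ValueError("tau_rest must be non-negative")
    u = b_i * tau_rest
    return u / (1.0 + u)


def collapse_item(items: ItemParams, scores: ScoreParams,
                  i: int) -> tuple[ItemParams, ScoreParams]:
    """Marginalize item ``i`` out of the model.

    The remaining items again follow an extended marginal Rasch model with
    ``b' = b without item i`` and ``λ'_s = λ_s + λ_{s+1} b_i``
    (``λ_{n+1} = 0``).
    """
    n = items.n_items
    if n < 2:
        raise ValueError("need at least two items to collapse one")
    if not 0 <= i < n:
        raise IndexError(f"item index {i} out of range")
    lam = scores.lam
    lam_new = lam[:n] + np.append(lam[1:], 0.0)[:n] * items.b[i]
    ref = items.ref_item
    if ref == i:
        ref = 0
    elif ref > i:
        ref -= 1
    return ItemParams(np.delete(items.b, i), ref_item=ref), ScoreParams(lam_new)


def reparameterize(scores: ScoreParams) -> TauParams:
    """λ → τ: ``τ_s = λ_{s+1} / λ_s`` for ``s = 0..n-1``.

    Entries with a zero λ in the ratio are flagged unavailable.
    """
    lam = scores.lam
    avail = lam[:-1] > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = lam[1:] / lam[:-1]
    tau[~avail] = np.nan
    return TauParams(tau, available=avail)


def tau_to_scores(tau: TauParams | np.ndarray, lam0: float = 1.0) -> ScoreParams:
    """Inverse reparametrization: ``λ_s = λ_0 Π_{t<s} τ_t``."""
    t = tau.tau if isinstance(tau, TauParams) else np.asarray(tau, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("tau must be finite and non-negative to invert")
    if lam0 <= 0:
        raise ValueError("λ_0 must be positive")
    lam = lam0 * np.concatenate(([1.0], np.cumprod(t)))
    return ScoreParams(lam)


def rescale_identify(items: ItemParams, scores: ScoreParams,
                     ref_item: int | None = None) -> tuple[ItemParams, ScoreParams]:
    """Map to the identified representative: b[ref] = 1 and λ_0 = 1.

    Applies ``(b, λ_s) → (c·b, λ_s / c^s)`` with ``c = 1/b[ref]`` and then
    divides λ by λ_0.  Pattern probabilities are unchanged; the map is
    idempotent.
    """
    if ref_item is None:
        ref_item = items.ref_item
    if not 0 <= ref_item < items.n_items:
        raise IndexError("ref_item out of range")
    if scores.lam[0] <= 0:
        raise ValueError("λ_0 must be positive to identify by λ_0 = 1")
    c = 1.0 / items.b[ref_item]
    b_new = items.b * c
    b_new[ref_item] = 1.0  # exact, not 1±eps
    lam_new = scores.lam / c ** np.arange(scores.lam.size)
    lam_new = lam_new / lam_new[0]
    return ItemParams(b_new, ref_item=ref_item), ScoreParams(lam_new)
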