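"""Elementary symmetric functions (ESFs) of item easiness vectors.

The ESF of order ``s`` of a positive vector ``b`` is the sum over all
size-``s`` subsets of the products of their elements.  These functions are
the normalising combinatorics of the conditional likelihood of the Rasch
model; everything downstream (pattern probabilities, full conditionals of
the Gibbs sampler) is expressed in terms of them.

All computations are carried out with a running rescale so that no
intermediate value overflows, and results are returned on the log scale.
Scores outside the achievable range have ESF zero (log value ``-inf``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["EsfVector", "esf_log", "esf_drop", "esf_poly_log"]

# rescale threshold: far below overflow, far above underflow after division
_RESCALE_AT = 1e250


@dataclass(frozen=True)
class EsfVector:
    """Log-scale ESF values indexed by score ``s = 0..S_max``.

    ``log_gamma[s]`` is ``log γ_s``; unachievable scores carry ``-inf`` and
    are flagged in ``support_mask``.
    """

    log_gamma: np.ndarray
    support_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lg = np.asarray(self.log_gamma, dtype=float)
        object.__setattr__(self, "log_gamma", lg)
        mask = self.support_mask
        if mask is None:
            mask = np.isfinite(lg)
        object.__setattr__(self, "support_mask", np.asarray(mask, dtype=bool))
        if lg.ndim != 1 or lg.size < 1:
            raise ValueError("log_gamma must be a non-empty 1-d array")
        if not np.isclose(lg[0], 0.0):
            raise ValueError("gamma_0 must equal 1 (log_gamma[0] == 0)")
        if not np.all(np.isfinite(lg[self.support_mask])):
            raise ValueError("log_gamma must be finite on the support")

    @property
    def max_score(self) -> int:
        return self.log_gamma.size - 1

    def gamma(self) -> np.ndarray:
        """ESF values on the natural scale (may overflow for large inputs)."""
        with np.errstate(over="ignore"):
            return np.exp(self.log_gamma)

    def log_at(self, s: int | np.ndarray) -> np.ndarray:
        """``log γ_s`` with out-of-range scores mapped to ``-inf``."""
        s = np.asarray(s)
        out = np.full(s.shape, -np.inf, dtype=float)
        ok = (s >= 0) & (s <= self.max_score)
        out[ok] = self.log_gamma[s[ok]]
        return out


def _validate_positive(b: Sequence[float]) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if b.ndim != 1 or b.size < 1:
        raise ValueError("b must be a non-empty 1-d vector")
    if not np.all(np.isfinite(b)) or np.any(b <= 0):
        raise ValueError("all easiness values must be positive and finite")
    return b


def _esf_core(b: np.ndarray) -> np.ndarray:
    """Log-ESF of ``b`` by the one-item-at-a-time recursion.

    Natural-scale recursion with a per-step rescale; the scalar log offset is
    added back at the end, so intermediates never overflow for any n for
    which the *logs* themselves are representable.
    """
    n = b.size
    g = np.zeros(n + 1)
    g[0] = 1.0
    shift = 0.0
    for i in range(n):
        # gamma_s(b_1..b_{i+1}) = gamma_s(b_1..b_i) + b_{i+1} gamma_{s-1}(..)
        g[1 : i + 2] += b[i] * g[0 : i + 1]
        hi = g[: i + 2].max()
        if hi > _RESCALE_AT:
            g[: i + 2] /= hi
            shift += np.log(hi)
    with np.errstate(divide="ignore"):
        return np.log(g) + shift


def esf_log(b: Sequence[float]) -> EsfVector:
    """ESFs of a positive easiness vector, on the log scale.

    ``exp(log_gamma[s])`` equals the sum over all size-``s`` subsets of
    ``b`` of their products; ``γ_0 = 1`` and ``γ_n = Π b_i``.
    """
    b = _validate_positive(b)
    return EsfVector(_esf_core(b))


def esf_drop(b: Sequence[float], i: int) -> EsfVector:
    """ESFs of ``b`` with item ``i`` removed.

    Recomputes over the reduced vector rather than downdating the recursion,
    which is subject to catastrophic cancellation.
    """
    b = _validate_positive(b)
    if b.size < 2:
        raise ValueError("need at least two items to drop one")
    if not 0 <= i < b.size:
        raise IndexError(f"item index {i} out of range for {b.size} items")
    return EsfVector(_esf_core(np.delete(b, i)))


def esf_poly_log(
    weights: Sequence[Sequence[int]], easiness: Sequence[Sequence[float]]
) -> EsfVector:
    """Score-weighted ESFs for a bank of polytomous items.

    Each item ``i`` has categories ``j = 1..J_i`` with integer weight
    ``a_ij >= 1`` and easiness ``b_ij > 0``; category 0 has weight 0 and
    easiness 1 implicitly.  ``γ_s`` sums ``Π b_ij^{y_ij}`` over all
    category-choice patterns with weighted total score ``s``.  Scores no
    pattern can reach are masked out (``-inf``).
    """
    if len(weights) != len(easiness) or len(weights) == 0:
        raise ValueError("weights and easiness must be equal-length, non-empty")
    aa, bb = [], []
    for a_i, b_i in zip(weights, easiness):
        a_i = np.asarray(a_i)
        if a_i.size == 0 or not np.issubdtype(a_i.dtype, np.integer):
            if not np.all(np.asarray(a_i, float) == np.asarray(a_i, float).astype(int)):
                raise ValueError("category weights must be integers")
            a_i = np.asarray(a_i, float).astype(int)
        if np.any(a_i < 1):
            raise ValueError("category weights must be >= 1")
        b_i = _validate_positive(b_i)
        if a_i.size != b_i.size:
            raise ValueError("weights/easiness length mismatch within an item")
        aa.append(a_i)
        bb.append(b_i)

    s_max = int(sum(a_i.max() for a_i in aa))
    g = np.zeros(s_max + 1)
    g[0] = 1.0
    shift = 0.0
    for a_i, b_i in zip(aa, bb):
        new = g.copy()  # category 0: weight 0, easiness 1
        for a_ij, b_ij in zip(a_i, b_i):
            new[a_ij:] += b_ij * g[: s_max + 1 - a_ij]
        g = new
        hi = g.max()
        if hi > _RESCALE_AT:
            g /= hi
            shift += np.log(hi)
    with np.errstate(divide="ignore"):
        lg = np.log(g) + shift
    return EsfVector(lg, support_mask=g > 0)
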