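"""Incomplete (two-booklet anchor) designs and polytomous items.

Both extensions reuse the complete-design machinery.  In the anchor-test
design, unique items and the per-group score parameters keep their
conjugate scaled-Beta-prime full conditionals; only the anchor items see
two normalizers at once, giving a log-concave "rational" conditional that
is handled with a Metropolis step whose proposal is a scaled Beta prime
with its log-slope matched to the target at the current state.

For polytomous items with known integer category weights, the weighted
total score is sufficient for ability, the normalizer is linear in each
category easiness, and every update is again the same scaled-Beta-prime
primitive — only the linear coefficients change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, logsumexp

from .esf import _esf_core, esf_poly_log
from .sampler import (ChainConfig, sample_scaled_beta_prime,
                      sufficient_statistics)

__all__ = [
    "NEATStats",
    "NEATPrior",
    "NEATDraws",
    "neat_sufficient_statistics",
    "anchor_coefficients",
    "anchor_full_conditional",
    "mh_update_anchor",
    "neat_gibbs_run",
    "PolytomousBank",
    "PolyStats",
    "PolyPrior",
    "PolyDraws",
    "poly_sufficient_statistics",
    "poly_category_scale",
    "poly_sample_category",
    "poly_gibbs_run",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# NEAT design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NEATStats:
    """Sufficient statistics of a two-group anchor-test design.

    Group 1 answers the anchor plus unique set y; group 2 the anchor plus
    unique set z.  Anchor totals are pooled over groups; score counts are
    per group over each booklet's total score.
    """

    anchor_totals: np.ndarray
    y_totals: np.ndarray
    z_totals: np.ndarray
    score_counts_xy: np.ndarray
    score_counts_xz: np.ndarray
    m_xy: int
    m_xz: int

    def __post_init__(self) -> None:
        for name in ("anchor_totals", "y_totals", "z_totals",
                     "score_counts_xy", "score_counts_xz"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=np.int64))
        if self.anchor_totals.size == 0:
            raise ValueError("anchor item set must be non-empty")
        na = self.n_anchor
        if self.score_counts_xy.size != na + self.n_y + 1:
            raise ValueError("group-1 score counts inconsistent with booklet length")
        if self.score_counts_xz.size != na + self.n_z + 1:
            raise ValueError("group-2 score counts inconsistent with booklet length")
        if self.score_counts_xy.sum() != self.m_xy:
            raise ValueError("group-1 score counts must sum to m_xy")
        if self.score_counts_xz.sum() != self.m_xz:
            raise ValueError("group-2 score counts must sum to m_xz")

    @property
    def n_anchor(self) -> int:
        return self.anchor_totals.size

    @property
    def n_y(self) -> int:
        return self.y_totals.size

    @property
    def n_z(self) -> int:
        return self.z_totals.size


def neat_sufficient_statistics(X_xy: np.ndarray, X_xz: np.ndarray,
                               n_anchor: int,
                               anchor_ids_xy: list | None = None,
                               anchor_ids_xz: list | None = None) -> NEATStats:
    """Per-group sufficient statistics for a two-booklet anchor design.

    The first ``n_anchor`` columns of both matrices must be the anchor
    items in the same order; pass the column IDs to have this checked.
    ``X_xz`` may be empty (no second group), in which case the result
    reduces to complete-design statistics for group 1.
    """
    if anchor_ids_xy is not None and anchor_ids_xz is not None:
        if list(anchor_ids_xy)[:n_anchor] != list(anchor_ids_xz)[:n_anchor]:
            raise ValueError("anchor columns differ between the two booklets")
    X_xy = np.asarray(X_xy)
    X_xz = np.asarray(X_xz)
    if X_xz.size == 0:
        X_xz = X_xz.reshape(0, n_anchor)
    for X in (X_xy, X_xz):
        if X.ndim != 2 or X.shape[1] < n_anchor:
            raise ValueError("each group matrix must include the anchor columns")
        if X.size and not np.all(np.isin(X, (0, 1))):
            raise ValueError("responses must be 0/1")
    s1 = sufficient_statistics(X_xy)
    anchor = X_xy[:, :n_anchor].sum(axis=0).astype(np.int64)
    if X_xz.shape[0]:
        s2 = sufficient_statistics(X_xz)
        anchor = anchor + s2.item_totals[:n_anchor]
        z_totals = s2.item_totals[n_anchor:]
        counts_xz = s2.score_counts
        m_xz = s2.m
    else:
        z_totals = np.zeros(X_xz.shape[1] - n_anchor, dtype=np.int64)
        counts_xz = np.zeros(X_xz.shape[1] + 1, dtype=np.int64)
        m_xz = 0
    return NEATStats(anchor, s1.item_totals[n_anchor:], z_totals,
                     s1.score_counts, counts_xz, s1.m, m_xz)


@dataclass(frozen=True)
class NEATPrior:
    alpha_anchor: np.ndarray
    alpha_y: np.ndarray
    alpha_z: np.ndarray
    beta_lam: np.ndarray
    beta_eta: np.ndarray

    @staticmethod
    def flat(stats: NEATStats) -> "NEATPrior":
        return NEATPrior(np.ones(stats.n_anchor), np.ones(stats.n_y),
                         np.ones(stats.n_z),
                         np.ones(stats.score_counts_xy.size),
                         np.ones(stats.score_counts_xz.size))


@dataclass(frozen=True)
class NEATDraws:
    b: np.ndarray      # anchor easiness (n_draws, n_anchor)
    c: np.ndarray      # unique set y
    d: np.ndarray      # unique set z
    lam: np.ndarray    # group-1 score params
    eta: np.ndarray    # group-2 score params
    config: ChainConfig
    anchor_acceptance: np.ndarray = field(default=None)  # type: ignore


def _conj_scale(items: np.ndarray, drop: int, log_lam: np.ndarray) -> float:
    """Scale coefficient of a conjugate item update within one booklet."""
    lg = _esf_core(np.delete(items, drop))
    num = logsumexp(lg + log_lam[1:])
    den = logsumexp(lg + log_lam[:-1])
    return float(np.exp(num - den))


def anchor_coefficients(b: np.ndarray, c: np.ndarray, d: np.ndarray,
                        lam: np.ndarray, eta: np.ndarray,
                        i: int) -> tuple[float, float]:
    """(a_1, a_2): linear coefficients of b_i in each group's normalizer."""
    with np.errstate(divide="ignore"):
        log_lam, log_eta = np.log(lam), np.log(eta)
    a1 = _conj_scale(np.concatenate([b, c]), i, log_lam)
    a2 = _conj_scale(np.concatenate([b, d]), i, log_eta)
    return a1, a2


def anchor_full_conditional(delta: np.ndarray | float, k: float,
                            a1: float, a2: float, m_xy: int,
                            m_xz: int) -> tuple[np.ndarray, np.ndarray]:
    """Log full conditional (up to a constant) and its slope, on the δ scale.

    log f(δ) = -k δ - m_xy ln(1 + a_1 e^{-δ}) - m_xz ln(1 + a_2 e^{-δ});
    the slope tends to -k as δ → ∞ and to (m_xy + m_xz) - k as δ → -∞,
    so the density is log-concave with linear tails.
    """
    delta = np.asarray(delta, dtype=float)
    e = np.exp(-delta)
    logf = -k * delta - m_xy * np.log1p(a1 * e) - m_xz * np.log1p(a2 * e)
    r1 = a1 * e / (1.0 + a1 * e)
    r2 = a2 * e / (1.0 + a2 * e)
    slope = -k + m_xy * r1 + m_xz * r2
    return logf, slope


def _log_sbp_pdf(v: float, k: float, M: float, c: float) -> float:
    """Normalized log-density of the scaled Beta prime at v."""
    return ((k - 1.0) * np.log(v) - M * np.log1p(c * v)
            + k * np.log(c) - betaln(k, M - k))


def mh_update_anchor(b_i: float, k: float, a1: float, a2: float,
                     m_xy: int, m_xz: int,
                     rng: np.random.Generator) -> tuple[float, bool]:
    """One Metropolis step for an anchor easiness parameter.

    The proposal is the complete-design family scaled Beta prime whose
    log-slope at the current value matches the target's; with a_1 = a_2 it
    is the target itself and the step always accepts.  Returns the new
    value and an acceptance indicator.
    """
    M = m_xy + m_xz
    if not 0 < k < M:
        raise ValueError(f"anchor update needs 0 < k < m_xy + m_xz; got k={k}")

    def matched_scale(v: float) -> float:
        r1 = a1 * v / (1.0 + a1 * v)
        r2 = a2 * v / (1.0 + a2 * v)
        q = (m_xy * r1 + m_xz * r2) / M
        if not 0.0 < q < 1.0:
            return np.nan
        return q / ((1.0 - q) * v)

    c_fwd = matched_scale(b_i)
    if not np.isfinite(c_fwd):
        logger.warning("degenerate slope match at b_i=%g; keeping current value", b_i)
        return float(b_i), False
    prop = sample_scaled_beta_prime(k, M, c_fwd, rng)
    c_rev = matched_scale(prop)
    if not np.isfinite(c_rev):
        return float(b_i), False

    def log_target(v: float) -> float:
        return ((k - 1.0) * np.log(v) - m_xy * np.log1p(a1 * v)
                - m_xz * np.log1p(a2 * v))

    log_alpha = (log_target(prop) - log_target(b_i)
                 + _log_sbp_pdf(b_i, k, M, c_rev)
                 - _log_sbp_pdf(prop, k, M, c_fwd))
    if np.log(rng.random()) < log_alpha:
        return float(prop), True
    return float(b_i), False


def _check_neat_propriety(stats: NEATStats, prior: NEATPrior,
                          ref_anchor: int) -> None:
    m = stats.m_xy + stats.m_xz
    checks = [
        ("anchor items", stats.anchor_totals + prior.alpha_anchor, m,
         ref_anchor),
        ("unique items y", stats.y_totals + prior.alpha_y, stats.m_xy, None),
        ("unique items z", stats.z_totals + prior.alpha_z, stats.m_xz, None),
        ("group-1 scores", stats.score_counts_xy + prior.beta_lam,
         stats.m_xy, 0),
        ("group-2 scores", stats.score_counts_xz + prior.beta_eta,
         stats.m_xz, 0),
    ]
    msgs = []
    for name, k, mm, fixed in checks:
        bad = np.nonzero((k <= 0) | (k >= mm))[0]
        if fixed is not None:
            bad = bad[bad != fixed]  # identification constants impose nothing
        if bad.size:
            msgs.append(f"{name}: indices {bad.tolist()} violate 0 < k < {mm}")
    if msgs:
        raise ValueError("improper full conditionals in the NEAT design; "
                         + "; ".join(msgs))


def neat_gibbs_run(stats: NEATStats, prior: NEATPrior | None = None,
                   config: ChainConfig | None = None,
                   rng: np.random.Generator | None = None) -> NEATDraws:
    """Gibbs sampler for the two-booklet anchor design.

    Unique items and the per-group score parameters get conjugate updates
    (the same primitive as the complete design, per booklet); anchor items
    get one Metropolis step per sweep.  Identification fixes one anchor
    item at b = 1 and λ_0 = η_0 = 1 throughout the run.
    """
    config = config or ChainConfig()
    prior = prior or NEATPrior.flat(stats)
    if stats.m_xz <= 0 or stats.n_z == 0 or stats.n_y == 0:
        raise ValueError("neat_gibbs_run needs two non-empty groups with "
                         "unique items; fit a complete design otherwise")
    _check_neat_propriety(stats, prior, config.ref_item)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    na, ny, nz = stats.n_anchor, stats.n_y, stats.n_z
    ref = config.ref_item
    b = rng.uniform(size=na)
    b[ref] = 1.0
    c = rng.uniform(size=ny)
    d = rng.uniform(size=nz)
    lam = rng.uniform(size=na + ny + 1)
    lam[0] = 1.0
    eta = rng.uniform(size=na + nz + 1)
    eta[0] = 1.0
    k_anchor = stats.anchor_totals + prior.alpha_anchor
    k_y = stats.y_totals + prior.alpha_y
    k_z = stats.z_totals + prior.alpha_z
    k_lam = stats.score_counts_xy + prior.beta_lam
    k_eta = stats.score_counts_xz + prior.beta_eta

    n_keep = config.n_iter - config.burn_in
    out = NEATDraws(np.empty((n_keep, na)), np.empty((n_keep, ny)),
                    np.empty((n_keep, nz)), np.empty((n_keep, lam.size)),
                    np.empty((n_keep, eta.size)), config,
                    anchor_acceptance=np.zeros(na))
    accepted = np.zeros(na)
    for it in range(config.n_iter):
        # anchor items: one MH proposal each (reference item stays at 1)
        for i in range(na):
            if i == ref:
                continue
            a1, a2 = anchor_coefficients(b, c, d, lam, eta, i)
            b[i], acc = mh_update_anchor(b[i], k_anchor[i], a1, a2,
                                         stats.m_xy, stats.m_xz, rng)
            accepted[i] += acc
        # unique items: conjugate within their booklet
        with np.errstate(divide="ignore"):
            log_lam = np.log(lam)
        for j in range(ny):
            sc = _conj_scale(np.concatenate([b, c]), na + j, log_lam)
            c[j] = sample_scaled_beta_prime(k_y[j], stats.m_xy, sc, rng)
        with np.errstate(divide="ignore"):
            log_eta = np.log(eta)
        for j in range(nz):
            sc = _conj_scale(np.concatenate([b, d]), na + j, log_eta)
            d[j] = sample_scaled_beta_prime(k_z[j], stats.m_xz, sc, rng)
        # score parameters per group
        for params, log_p, k_vec, items, m_g in (
                (lam, log_lam, k_lam, np.concatenate([b, c]), stats.m_xy),
                (eta, log_eta, k_eta, np.concatenate([b, d]), stats.m_xz)):
            log_gamma = _esf_core(items)
            for t in range(1, params.size):  # index 0 fixed at 1
                rest = log_gamma + log_p
                rest[t] = -np.inf
                sc = float(np.exp(log_gamma[t] - logsumexp(rest)))
                params[t] = sample_scaled_beta_prime(k_vec[t], m_g, sc, rng)
                log_p[t] = np.log(params[t])
        if it >= config.burn_in:
            j = it - config.burn_in
            out.b[j], out.c[j], out.d[j] = b, c, d
            out.lam[j], out.eta[j] = lam, eta
    out.anchor_acceptance[:] = accepted / config.n_iter
    logger.info("anchor MH acceptance rates: %s",
                np.round(out.anchor_acceptance, 3))
    return out


# ---------------------------------------------------------------------------
# Polytomous items with fixed integer scoring weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolytomousBank:
    """Category easiness b_ij and fixed integer weights a_ij (j = 1..J_i).

    Category 0 of every item has weight 0 and easiness 1 implicitly; the
    weighted total score is the sufficient statistic for ability.
    """

    weights: tuple
    easiness: tuple

    def __post_init__(self) -> None:
        w = tuple(np.asarray(a, dtype=np.int64) for a in self.weights)
        e = tuple(np.asarray(b, dtype=float) for b in self.easiness)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "easiness", e)
        if len(w) != len(e) or len(w) == 0:
            raise ValueError("weights and easiness must match and be non-empty")
        for a, b in zip(w, e):
            if a.size != b.size or a.size == 0:
                raise ValueError("per-item weights/easiness must match")
            if np.any(a < 1):
                raise ValueError("category weights must be integers >= 1")
            if np.any(b <= 0) or not np.all(np.isfinite(b)):
                raise ValueError("category easiness must be positive")

    @property
    def n_items(self) -> int:
        return len(self.weights)

    @property
    def max_score(self) -> int:
        return int(sum(a.max() for a in self.weights))

    def achievable(self) -> np.ndarray:
        """Boolean mask over 0..max_score of reachable weighted totals."""
        ok = np.zeros(self.max_score + 1, dtype=bool)
        ok[0] = True
        for a in self.weights:
            new = ok.copy()
            for a_ij in a:
                new[a_ij:] |= ok[: ok.size - a_ij]
            ok = new
        return ok

    def drop(self, i: int) -> "PolytomousBank | None":
        if self.n_items == 1:
            return None
        return PolytomousBank(self.weights[:i] + self.weights[i + 1:],
                              self.easiness[:i] + self.easiness[i + 1:])

    def with_easiness(self, easiness) -> "PolytomousBank":
        return PolytomousBank(self.weights, tuple(easiness))


@dataclass(frozen=True)
class PolyStats:
    """Category counts y_{+ij} and the weighted-score histogram."""

    category_counts: tuple  # per item, counts of categories 1..J_i
    score_counts: np.ndarray  # histogram of y_{++} over 0..max_score
    m: int

    @property
    def n_items(self) -> int:
        return len(self.category_counts)


@dataclass(frozen=True)
class PolyPrior:
    alpha: tuple  # per item, exponents for categories 1..J_i
    beta: np.ndarray  # per achievable score

    @staticmethod
    def flat(weights) -> "PolyPrior":
        alpha = tuple(np.ones(len(a)) for a in weights)
        smax = int(sum(np.max(a) for a in weights))
        return PolyPrior(alpha, np.ones(smax + 1))


@dataclass(frozen=True)
class PolyDraws:
    easiness: tuple  # per item, array (n_draws, J_i)
    lam: np.ndarray  # (n_draws, max_score + 1); zero at unachievable scores
    achievable: np.ndarray
    config: ChainConfig


def poly_sufficient_statistics(X: np.ndarray, weights) -> PolyStats:
    """Counts per item-category and the weighted total-score histogram.

    ``X[p, i]`` is the chosen category 0..J_i of person p on item i; with
    all weights equal to (1,) this reduces to the dichotomous statistics.
    """
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    weights = [np.asarray(a, dtype=np.int64) for a in weights]
    if X.shape[1] != len(weights):
        raise ValueError("X and weights disagree on the number of items")
    m = X.shape[0]
    cat_counts = []
    total = np.zeros(m, dtype=np.int64)
    for i, a in enumerate(weights):
        col = X[:, i]
        if np.any((col < 0) | (col > a.size)):
            raise ValueError(f"item {i}: categories must lie in 0..{a.size}")
        cat_counts.append(np.bincount(col, minlength=a.size + 1)[1:])
        full_w = np.concatenate(([0], a))
        total += full_w[col]
    smax = int(sum(a.max() for a in weights))
    hist = np.bincount(total, minlength=smax + 1)
    return PolyStats(tuple(cat_counts), hist, m)


def _poly_esf(bank: PolytomousBank | None, smax: int) -> np.ndarray:
    if bank is None:  # empty bank: only score 0 achievable
        lg = np.full(smax + 1, -np.inf)
        lg[0] = 0.0
        return lg
    lg = esf_poly_log(bank.weights, bank.easiness).log_gamma
    out = np.full(smax + 1, -np.inf)
    out[: lg.size] = lg
    return out


def poly_category_scale(bank: PolytomousBank, lam: np.ndarray,
                        i: int, j: int) -> float:
    """Linear-coefficient ratio c for the b_ij full conditional.

    The normalizer Σ_s γ_s λ_s is linear in b_ij; c is the coefficient of
    b_ij divided by the b_ij-free remainder (other categories included).
    """
    smax = bank.max_score
    with np.errstate(divide="ignore"):
        log_lam = np.log(np.asarray(lam, dtype=float))
    lg_wo = _poly_esf(bank.drop(i), smax)

    def shifted(a_ij: int) -> float:
        # Σ_s γ_{s-a_ij}(bank without i) λ_s
        return logsumexp(lg_wo[: smax + 1 - a_ij] + log_lam[a_ij:])

    a_i = bank.weights[i]
    b_i = bank.easiness[i]
    num = shifted(int(a_i[j]))
    terms = [logsumexp(lg_wo + log_lam)]
    for h in range(a_i.size):
        if h != j:
            terms.append(np.log(b_i[h]) + shifted(int(a_i[h])))
    den = logsumexp(terms)
    return float(np.exp(num - den))


def poly_sample_category(bank: PolytomousBank, lam: np.ndarray,
                         stats: PolyStats, prior: PolyPrior, i: int, j: int,
                         rng: np.random.Generator) -> float:
    """Conjugate update of one category easiness b_ij."""
    k = stats.category_counts[i][j] + prior.alpha[i][j]
    if not 0 < k < stats.m:
        raise ValueError(f"item {i} category {j + 1}: y_+ij + α_ij = {k} "
                         f"not in (0, m={stats.m})")
    c = poly_category_scale(bank, lam, i, j)
    return sample_scaled_beta_prime(k, stats.m, c, rng)


def _check_poly_propriety(stats: PolyStats, prior: PolyPrior,
                          achievable: np.ndarray, ref_item: int = 0) -> None:
    msgs = []
    for i, counts in enumerate(stats.category_counts):
        k = counts + prior.alpha[i]
        bad = np.nonzero((k <= 0) | (k >= stats.m))[0]
        if i == ref_item:
            bad = bad[bad != 0]  # identification constant
        if bad.size:
            msgs.append(f"item {i} categories {(bad + 1).tolist()}")
    k = stats.score_counts + prior.beta
    bad = np.nonzero(((k <= 0) | (k >= stats.m)) & achievable)[0]
    bad = bad[bad != 0]
    if bad.size:
        msgs.append(f"scores {bad.tolist()}")
    if msgs:
        raise ValueError("improper full conditionals: " + "; ".join(msgs))


def poly_gibbs_run(stats: PolyStats, weights,
                   prior: PolyPrior | None = None,
                   config: ChainConfig | None = None,
                   rng: np.random.Generator | None = None) -> PolyDraws:
    """Gibbs sampler for the fixed-weights polytomous marginal model.

    Sweeps over every item-category pair and then over every achievable
    score on the weighted lattice; λ is defined (and sampled) only on
    achievable scores.  Identification: first category of the reference
    item fixed at easiness 1 and λ_0 = 1 throughout the run.
    """
    config = config or ChainConfig()
    weights = tuple(np.asarray(a, dtype=np.int64) for a in weights)
    prior = prior or PolyPrior.flat(weights)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    template = PolytomousBank(weights, tuple(np.ones(a.size) for a in weights))
    achievable = template.achievable()
    smax = template.max_score
    ref = config.ref_item
    _check_poly_propriety(stats, prior, achievable, ref)

    easiness = [rng.uniform(size=a.size) for a in weights]
    easiness[ref][0] = 1.0
    lam = np.zeros(smax + 1)
    lam[achievable] = rng.uniform(size=int(achievable.sum()))
    lam[0] = 1.0
    k_scores = stats.score_counts + prior.beta

    n_keep = config.n_iter - config.burn_in
    out_e = tuple(np.empty((n_keep, a.size)) for a in weights)
    out_lam = np.empty((n_keep, smax + 1))
    scores_to_update = np.nonzero(achievable)[0]
    scores_to_update = scores_to_update[scores_to_update != 0]
    for it in range(config.n_iter):
        for i in range(len(weights)):
            for j in range(weights[i].size):
                if i == ref and j == 0:
                    continue
                bank = template.with_easiness(easiness)
                easiness[i][j] = poly_sample_category(bank, lam, stats, prior,
                                                      i, j, rng)
        bank = template.with_easiness(easiness)
        log_gamma = _poly_esf(bank, smax)
        with np.errstate(divide="ignore"):
            log_lam = np.log(lam)
        for t in scores_to_update:
            rest = log_gamma + log_lam
            rest[t] = -np.inf
            c = float(np.exp(log_gamma[t] - logsumexp(rest)))
            lam[t] = sample_scaled_beta_prime(k_scores[t], stats.m, c, rng)
            log_lam[t] = np.log(lam[t])
        if it >= config.burn_in:
            jj = it - config.burn_in
            for i in range(len(weights)):
                out_e[i][jj] = easiness[i]
            out_lam[jj] = lam
    return PolyDraws(out_e, out_lam, achievable, config)
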