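"""Posterior ability summaries on the exp(Θ) scale from Gibbs draws.

The EAP of exp(Θ) given a sum score s is the posterior functional
E[λ_{s+1}/λ_s | data]; its variance decomposes into a parameter-uncertainty
part (variance of the ratio across draws) and a finite-test-length part
(mean across draws of the within-draw conditional variance).  The mean is
defined for s ≤ n-1 and the variance for s ≤ n-2 only; higher scores are
structurally unavailable.  A log-normal moment match gives approximate
summaries on the θ scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sampler import GibbsDraws

__all__ = [
    "AbilitySummary",
    "eap_exp_theta",
    "posterior_variance_exp_theta",
    "lognormal_theta_summary",
    "ability_summary",
]


@dataclass(frozen=True)
class AbilitySummary:
    """Per-score posterior summaries; NaN where a quantity is unavailable."""

    table: pd.DataFrame
    caveat: str = ("mu/sigma2 assume an approximately normal posterior of "
                   "ability on the theta scale; exp-scale columns are exact "
                   "posterior functionals")

    def to_csv(self, path, **kw) -> None:
        self.table.to_csv(path, index=False, **kw)


def _ratios(draws: GibbsDraws, s: int, step: int) -> np.ndarray:
    return draws.lam[:, s + step] / draws.lam[:, s]


def eap_exp_theta(draws: GibbsDraws, s: int) -> float:
    """Posterior mean of exp(Θ) for score s: MC average of λ_{s+1}/λ_s."""
    n = draws.n_items
    if not 0 <= s <= n - 1:
        raise ValueError(
            f"EAP of exp-ability is unavailable for score {s}; it exists "
            f"only for scores 0..{n - 1} (a perfect score cannot be estimated)")
    return float(_ratios(draws, s, 1).mean())


def posterior_variance_exp_theta(draws: GibbsDraws, s: int) -> dict:
    """Total posterior variance of exp(Θ) at score s, with its components.

    Returns parameter-uncertainty (between-draw variance of λ_{s+1}/λ_s),
    finite-test-length (mean of λ_{s+2}/λ_s - (λ_{s+1}/λ_s)^2) and their
    sum.  Requires s ≤ n-2.
    """
    n = draws.n_items
    if not 0 <= s <= n - 2:
        raise ValueError(
            f"posterior variance is unavailable for score {s}; it exists "
            f"only for scores 0..{n - 2}")
    r1 = _ratios(draws, s, 1)
    r2 = _ratios(draws, s, 2)
    parameter = float(r1.var())  # population variance over the draws
    finite_test = float((r2 - r1**2).mean())
    return {
        "parameter_uncertainty": parameter,
        "finite_test_length": finite_test,
        "total": parameter + finite_test,
    }


def lognormal_theta_summary(e1: float, e2: float) -> tuple[float, float]:
    """(μ_s, σ²_s) matching E[exp Θ] = e1 and E[exp² Θ] = e2.

    σ² = ln e2 - 2 ln e1 and μ = 2 ln e1 - (ln e2)/2; exact if the θ
    posterior is normal, an approximation otherwise.
    """
    if e1 <= 0:
        raise ValueError("E[exp Θ] must be positive")
    if e2 < e1**2:
        raise ValueError("inconsistent moments: E[exp² Θ] < E[exp Θ]²")
    sigma2 = float(np.log(e2) - 2.0 * np.log(e1))
    mu = float(2.0 * np.log(e1) - np.log(e2) / 2.0)
    return mu, sigma2


def ability_summary(draws: GibbsDraws) -> AbilitySummary:
    """Score-indexed table of exp-scale EAPs, variances and θ approximations.

    Each quantity is computed per retained draw and then aggregated; it is
    never formed from averaged λ, because the estimands are posterior
    functionals of the λ ratios.
    """
    n = draws.n_items
    rows = []
    for s in range(n + 1):
        row: dict = {"score": s}
        if s <= n - 1:
            row["eap_exp_theta"] = eap_exp_theta(draws, s)
        else:
            row["eap_exp_theta"] = np.nan
        if s <= n - 2:
            var = posterior_variance_exp_theta(draws, s)
            row.update(
                var_exp_theta=var["total"],
                var_parameter_uncertainty=var["parameter_uncertainty"],
                var_finite_test_length=var["finite_test_length"],
            )
            e2 = float(_ratios(draws, s, 2).mean())
            e1 = row["eap_exp_theta"]
            if e2 >= e1**2:
                mu, sigma2 = lognormal_theta_summary(e1, e2)
            else:  # can occur without the monotonicity constraint
                mu, sigma2 = np.nan, np.nan
            row.update(mu_theta_approx=mu, sigma2_theta_approx=sigma2)
        else:
            row.update(var_exp_theta=np.nan, var_parameter_uncertainty=np.nan,
                       var_finite_test_length=np.nan, mu_theta_approx=np.nan,
                       sigma2_theta_approx=np.nan)
        rows.append(row)
    return AbilitySummary(pd.DataFrame(rows))
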