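"""Threshold selection: turn continuous doublet scores into binary calls.

The threshold t* minimizes

    FNR(t) + FPR(t) + alpha * LL(n(t) | mu, sigma)^2

where FNR(t) is the fraction of simulated doublets scoring below t, FPR(t)
the fraction of input cells scoring at or above t, n(t) the number of input
cells called doublets, and LL the Gaussian log-density of n(t) given the
expected doublet count mu (heuristic mu = n^2 * 1e-5 when the user supplies
none) with binomial-model standard deviation sqrt(mu * (1 - mu/n)).  The
squared log-likelihood flattens the penalty's minimum; alpha rescales it to
the unit range of the two rates via the log-likelihood at the largest
candidate threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

log = logging.getLogger("vaeda")

__all__ = ["CallResult", "expected_doublets", "call_doublets"]


@dataclass
class CallResult:
    threshold: float
    calls: np.ndarray
    n_called: int
    mu: float
    sigma: float
    cost_curve: dict[str, np.ndarray]  # thresholds, fnr, fpr, penalty, cost

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.n_called != int(self.calls.sum()):
            raise ValueError("n_called must equal sum(calls)")


def expected_doublets(n: int, mu_user: float | None = None) -> tuple[float, float]:
    """Expected doublet count and its standard deviation for n input cells.

    mu defaults to n^2 * 1e-5 (the doublet *fraction* grows as n * 1e-5);
    sigma = sqrt(mu * (1 - mu/n)) from a binomial model.  A user-supplied mu
    overrides the heuristic and must lie in [0, n].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mu_user is not None:
        if not 0.0 <= mu_user <= n:
            raise ValueError(f"expected doublet count must be in [0, {n}]")
        mu = float(mu_user)
    else:
        mu = min(float(n), n**2 * 1e-5)
    sigma = float(np.sqrt(mu * (1.0 - mu / n)))
    return mu, sigma


def call_doublets(
    xi_real: np.ndarray, xi_sim: np.ndarray, mu: float, sigma: float
) -> CallResult:
    """Pick t* on the grid of observed scores and call cells with xi >= t*.

    Candidate thresholds are the sorted unique pooled scores plus one value
    above the maximum (where nothing is called).  Ties in the composite cost
    go to the smallest threshold.
    """
    xi_real = np.asarray(xi_real, dtype=np.float64)
    xi_sim = np.asarray(xi_sim, dtype=np.float64)
    if xi_real.size == 0 or xi_sim.size == 0:
        raise ValueError("both score vectors must be non-empty")
    if sigma <= 0:
        raise ValueError(
            "sigma is 0 (expected doublet count 0 or n); supply a positive expected count"
        )

    grid = np.unique(np.concatenate([xi_real, xi_sim]))
    grid = np.append(grid, grid[-1] + 1e-6)

    sim_sorted = np.sort(xi_sim)
    real_sorted = np.sort(xi_real)
    # count of sim scores < t  /  count of real scores >= t, vectorized
    fnr = np.searchsorted(sim_sorted, grid, side="left") / xi_sim.size
    n_t = xi_real.size - np.searchsorted(real_sorted, grid, side="left")
    fpr = n_t / xi_real.size

    ll = norm.logpdf(n_t.astype(np.float64), loc=mu, scale=sigma)
    ll_max = ll[-1]  # at the largest candidate threshold
    if ll_max == 0.0:
        raise ValueError("log-likelihood at t_max is exactly 0; cannot scale the penalty")
    if ll_max < 0:
        log.debug("LL(n(t_max)) negative (%.3f); using 1/|LL| for alpha", ll_max)
    alpha = 1.0 / abs(ll_max)
    penalty = alpha * ll**2
    cost = fnr + fpr + penalty

    best = int(np.argmin(cost))  # argmin takes the first (= smallest) threshold on ties
    t_star = float(grid[best])
    calls = xi_real >= t_star
    return CallResult(
        threshold=t_star,
        calls=calls,
        n_called=int(calls.sum()),
        mu=mu,
        sigma=sigma,
        cost_curve={"thresholds": grid, "fnr": fnr, "fpr": fpr, "penalty": penalty, "cost": cost},
    )
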