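"""Independent oracles for validating the Gibbs samplers and intervals.

Both latent-count models have fully conjugate structure: conditional on
the latent counts, every parameter integral is a Beta function.  The
posterior is therefore an exact finite mixture over latent-count
configurations, with weights computable in closed form via gammaln — an
enumeration oracle that never runs the samplers it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import betaln, gammaln


def _log_binom(n: int, k: np.ndarray | int) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(np.asarray(k) + 1) - gammaln(n - np.asarray(k) + 1)


def unarchived_posterior_means(
    a: int,
    b: int,
    n2: int,
    prior_pi: tuple[float, float],
    prior_s: tuple[float, float],
    prior_c: tuple[float, float],
) -> dict[str, float]:
    """Exact posterior means of (pi, S, C) with fixed a, b and latent c.

    Enumerates c = 0..n2; for each c the (pi, S, C) integrals are analytic
    beta-function ratios, so the posterior is a mixture of products of
    beta densities with exactly computable weights and component means.
    """
    ap, bp = prior_pi
    as_, bs = prior_s
    ac, bc = prior_c
    n = a + b + n2
    c = np.arange(n2 + 1)
    d = n2 - c
    logw = (
        _log_binom(n2, c)
        + betaln(a + c + ap, n - a - c + bp)
        + betaln(a + as_, c + bs)
        + betaln(d + ac, b + bc)
    )
    w = np.exp(logw - logw.max())
    w /= w.sum()
    pi_mean = float(np.sum(w * (a + c + ap) / (n + ap + bp)))
    s_mean = float(np.sum(w * (a + as_) / (a + c + as_ + bs)))
    c_mean = float(np.sum(w * (d + ac) / (d + b + ac + bc)))
    return {"prevalence": pi_mean, "recall": s_mean, "specificity": c_mean}


def two_classifier_posterior_means(
    table: tuple[int, int, int, int],
    prior_pi: tuple[float, float],
    prior_s1: tuple[float, float],
    prior_c1: tuple[float, float],
    prior_s2: tuple[float, float],
    prior_c2: tuple[float, float],
) -> dict[str, float]:
    """Exact posterior means of (pi, S1, C1, S2, C2) for a small table.

    Enumerates all latent splits (y1, y2, y3, y4) of the four observed
    cells into truly relevant / irrelevant parts; conditional on a split,
    every parameter is beta-distributed, so weights and means are exact.
    Feasible only for small cell counts (product of cell+1 combinations).
    """
    a, b, c, d = table
    n = a + b + c + d
    ap, bp = prior_pi
    a1, b1 = prior_s1
    ac1, bc1 = prior_c1
    a2, b2 = prior_s2
    ac2, bc2 = prior_c2
    names = ("prevalence", "recall_filter", "specificity_filter",
             "recall_coder", "specificity_coder")
    logws = []
    means = []
    for y1, y2, y3, y4 in itertools.product(
        range(a + 1), range(b + 1), range(c + 1), range(d + 1)
    ):
        ysum = y1 + y2 + y3 + y4
        logw = (
            _log_binom(a, y1)
            + _log_binom(b, y2)
            + _log_binom(c, y3)
            + _log_binom(d, y4)
            + betaln(ysum + ap, n - ysum + bp)
            + betaln(y1 + y2 + a1, y3 + y4 + b1)
            + betaln(c + d - y3 - y4 + ac1, a + b - y1 - y2 + bc1)
            + betaln(y1 + y3 + a2, y2 + y4 + b2)
            + betaln(b + d - y2 - y4 + ac2, a + c - y1 - y3 + bc2)
        )
        logws.append(logw)
        means.append(
            (
                (ysum + ap) / (n + ap + bp),
                (y1 + y2 + a1) / (ysum + a1 + b1),
                (c + d - y3 - y4 + ac1) / (n - ysum + ac1 + bc1),
                (y1 + y3 + a2) / (ysum + a2 + b2),
                (b + d - y2 - y4 + ac2) / (n - ysum + ac2 + bc2),
            )
        )
    logws = np.array(logws)
    w = np.exp(logws - logws.max())
    w /= w.sum()
    means = np.array(means)
    vals = w @ means
    return dict(zip(names, map(float, vals)))


def beta_hpd_grid(alpha: float, beta: float, mass: float = 0.95, n_grid: int = 200_001):
    """HPD interval of a beta density by brute-force density-level search."""
    from scipy.stats import beta as beta_dist

    # midpoint grid avoids infinite densities at the boundaries for shapes < 1
    x = (np.arange(n_grid) + 0.5) / n_grid
    pdf = beta_dist.pdf(x, alpha, beta)
    order = np.argsort(pdf)[::-1]
    cdf_mass = np.cumsum(pdf[order]) / pdf.sum()
    keep = order[: int(np.searchsorted(cdf_mass, mass)) + 1]
    return float(x[keep].min()), float(x[keep].max())
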