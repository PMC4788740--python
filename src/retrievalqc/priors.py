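"""Beta prior elicitation and posterior summaries shared by the Gibbs samplers.

Study reports typically state a prior as a mean plus a 95% interval rather
than as beta shape parameters; :func:`elicit_beta` recovers an ``(alpha,
beta)`` pair whose mean and interval best match the stated targets.
Posterior chains are summarized with means and highest-posterior-density
(HPD) intervals computed empirically from the draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import optimize
from scipy.stats import beta as beta_dist

__all__ = [
    "BetaPrior",
    "PosteriorDraws",
    "ElicitationError",
    "elicit_beta",
    "beta_hpd",
    "hpd_interval",
    "summarize_posterior",
    "resolve_prior",
]


class ElicitationError(ValueError):
    """The requested prior mean/interval cannot be matched by a beta density."""


@dataclass(frozen=True)
class BetaPrior:
    """Shape pair of a Beta(alpha, beta) prior on a probability parameter."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"beta shapes must be positive, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def interval(self, mass: float = 0.95, kind: str = "equal_tail") -> tuple[float, float]:
        if kind == "equal_tail":
            tail = (1.0 - mass) / 2.0
            return (
                float(beta_dist.ppf(tail, self.alpha, self.beta)),
                float(beta_dist.ppf(1.0 - tail, self.alpha, self.beta)),
            )
        if kind == "hpd":
            return beta_hpd(self.alpha, self.beta, mass)
        raise ValueError(f"unknown interval kind {kind!r}")

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)


@dataclass
class PosteriorDraws:
    """Named post-burn-in chains from one Gibbs run, plus run metadata."""

    draws: dict[str, np.ndarray]
    n_cycles: int
    burn_in: int
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kept = self.n_cycles - self.burn_in
        thin = int(self.extra.get("thin", 1))
        expected = kept // thin
        for name, chain in self.draws.items():
            chain = np.asarray(chain, dtype=float)
            if chain.ndim != 1 or chain.size != expected:
                raise ValueError(
                    f"chain {name!r} has shape {chain.shape}, expected ({expected},)"
                )
            self.draws[name] = chain

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name]

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    def mean(self, name: str) -> float:
        return float(self.draws[name].mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.draws)


def beta_hpd(alpha: float, beta: float, mass: float = 0.95) -> tuple[float, float]:
    """Exact HPD interval of a Beta(alpha, beta) density.

    Searches over the lower-tail probability ``t`` for the shortest interval
    ``[ppf(t), ppf(t+mass)]``; handles skewed and boundary-peaked shapes.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")

    def width(t: float) -> float:
        return float(
            beta_dist.ppf(t + mass, alpha, beta) - beta_dist.ppf(t, alpha, beta)
        )

    res = optimize.minimize_scalar(width, bounds=(0.0, 1.0 - mass), method="bounded")
    t = float(res.x)
    # boundary-peaked densities: one-sided interval may be shorter still
    for t_edge in (0.0, 1.0 - mass):
        if width(t_edge) < width(t):
            t = t_edge
    return float(beta_dist.ppf(t, alpha, beta)), float(beta_dist.ppf(t + mass, alpha, beta))


def elicit_beta(
    target_mean: float,
    target_interval: tuple[float, float],
    interval_kind: str = "equal_tail",
    mass: float = 0.95,
    tolerance: float = 0.05,
) -> BetaPrior:
    """Fit a Beta(alpha, beta) prior to a stated mean and central interval.

    Minimizes the squared mismatch of the mean and the two interval
    endpoints over (log alpha, log beta), with a vanishing penalty on
    alpha+beta so that among near-ties the weakest (least informative)
    prior wins.  ``interval_kind`` selects equal-tail (default) or HPD
    targets.  Raises :class:`ElicitationError` if the targets are
    infeasible or the best fit misses an endpoint by more than
    ``tolerance``.
    """
    lo, hi = target_interval
    if not 0.0 < target_mean < 1.0:
        raise ElicitationError(f"target mean {target_mean} outside (0, 1)")
    if not 0.0 <= lo < hi <= 1.0:
        raise ElicitationError(f"interval {target_interval} is not a subinterval of [0, 1]")
    if not lo <= target_mean <= hi:
        raise ElicitationError(
            f"interval {target_interval} does not contain the mean {target_mean}"
        )
    if interval_kind not in ("equal_tail", "hpd"):
        raise ValueError(f"unknown interval_kind {interval_kind!r}")

    def endpoints(a: float, b: float) -> tuple[float, float]:
        if interval_kind == "equal_tail":
            tail = (1.0 - mass) / 2.0
            return (
                float(beta_dist.ppf(tail, a, b)),
                float(beta_dist.ppf(1.0 - tail, a, b)),
            )
        return beta_hpd(a, b, mass)

    def loss(logab: np.ndarray) -> float:
        a, b = np.exp(logab)
        if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
            return 1e6
        m = a / (a + b)
        e_lo, e_hi = endpoints(a, b)
        return (
            (m - target_mean) ** 2
            + (e_lo - lo) ** 2
            + (e_hi - hi) ** 2
            + 1e-8 * (a + b)
        )

    # moment-matched start: solve mean and crude variance from interval width
    sd0 = (hi - lo) / 4.0
    v0 = min(sd0**2, target_mean * (1 - target_mean) * 0.99)
    nu0 = target_mean * (1 - target_mean) / v0 - 1.0
    nu0 = max(nu0, 0.1)
    starts = [
        (target_mean * nu0, (1 - target_mean) * nu0),
        (1.0, 1.0),
        (0.5, 0.5 * (1 - target_mean) / target_mean),
    ]
    best = None
    for a0, b0 in starts:
        res = optimize.minimize(
            loss,
            np.log([a0, b0]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = np.exp(best.x)
    fit = BetaPrior(float(a), float(b))
    e_lo, e_hi = endpoints(a, b)
    miss = max(abs(fit.mean - target_mean), abs(e_lo - lo), abs(e_hi - hi))
    if miss > tolerance:
        raise ElicitationError(
            f"best beta fit Beta({a:.3g}, {b:.3g}) misses targets by {miss:.3f} "
            f"(> tolerance {tolerance}); fitted mean {fit.mean:.4f}, "
            f"interval ({e_lo:.4f}, {e_hi:.4f}) vs targets {target_mean}, "
            f"({lo}, {hi})"
        )
    return fit


def resolve_prior(spec: Mapping | BetaPrior) -> BetaPrior:
    """Resolve a config prior block into beta shapes.

    Accepts an explicit ``{"alpha": ..., "beta": ...}`` pair or an
    elicitation target ``{"mean": ..., "interval": [lo, hi],
    "kind": "equal_tail"|"hpd"}``.
    """
    if isinstance(spec, BetaPrior):
        return spec
    if "alpha" in spec and "beta" in spec:
        return BetaPrior(float(spec["alpha"]), float(spec["beta"]))
    if "mean" in spec and "interval" in spec:
        lo, hi = spec["interval"]
        return elicit_beta(
            float(spec["mean"]),
            (float(lo), float(hi)),
            interval_kind=spec.get("kind", "equal_tail"),
        )
    raise ValueError(
        f"prior spec {spec!r} needs either (alpha, beta) or (mean, interval)"
    )


def hpd_interval(draws: Iterable[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``mass`` of the sorted draws.

    For skewed posteriors this is narrower than the equal-tailed interval.
    Requires at least 100 draws for a stable answer.
    """
    x = np.sort(np.asarray(list(draws) if not isinstance(draws, np.ndarray) else draws, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError(f"need >= 100 draws for an HPD interval, got {n}")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    k = math.ceil(mass * n)
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def summarize_posterior(
    draws: PosteriorDraws,
    mass: float = 0.95,
    priors: Mapping[str, BetaPrior] | None = None,
) -> dict[str, dict]:
    """Per-parameter posterior mean and HPD interval (plus prior columns).

    Returns ``{param: {"mean": ..., "hpd": (lo, hi), "prior_mean": ...,
    "prior_interval": ...}}`` shaped like a prior/posterior report table.
    Parameters with no stated prior (quantities derived inside the sampler)
    carry ``None`` in the prior columns.
    """
    out: dict[str, dict] = {}
    for name, chain in draws.draws.items():
        entry: dict = {"mean": float(chain.mean())}
        if chain.size >= 100:
            entry["hpd"] = hpd_interval(chain, mass)
        else:
            entry["hpd"] = (float(chain.min()), float(chain.max()))
        prior = (priors or {}).get(name)
        if prior is not None:
            entry["prior_mean"] = prior.mean
            entry["prior_interval"] = prior.interval(mass)
        else:
            entry["prior_mean"] = None
            entry["prior_interval"] = None
        out[name] = entry
    return out
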