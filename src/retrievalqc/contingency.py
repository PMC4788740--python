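"""Exact (non-Bayesian) retrieval-quality statistics from coded samples.

A keyword search filter splits a corpus into retrieved and unretrieved
strata; human coders label a sample from each stratum as topic-relevant or
not.  Cross-tabulating filter status against coded relevance gives the
2x2 table

    =============  ===============  ==================
    Search filter  Coded relevant   Coded not-relevant
    =============  ===============  ==================
    Retrieved      a (true pos.)    b (false pos.)
    Not retrieved  c (false neg.)   d (true neg.)
    =============  ===============  ==================

from which retrieval precision a/(a+b), retrieval recall a/(a+c),
specificity d/(b+d) and NPV d/(c+d) follow.  When the unretrieved stratum
is huge, recall is instead computed from stratum-level proportions via
Bayes' theorem::

    recall = P * P(retr) / [P * P(retr) + P(relevant|unretr) * (1 - P(retr))]

where ``P`` is precision, ``P(retr)`` the fraction of the archive the
filter retrieves, and ``P(relevant|unretr) = 1 - NPV`` the relevant
fraction among unretrieved messages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "ArchiveSummary",
    "StratifiedSample",
    "UndefinedMetricError",
    "precision",
    "recall_direct",
    "specificity",
    "npv",
    "f_score",
    "recall_bayes",
    "proportion_ci",
    "recall_bayes_ci",
    "recall_bayes_ci_delta",
    "adjust_for_sampling",
    "corrected_precision",
]


class UndefinedMetricError(ZeroDivisionError):
    """A retrieval metric whose denominator is empty for this table."""


def _check_count(name: str, value: int) -> int:
    out = int(value)
    if out != value or out < 0:
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    return out


@dataclass(frozen=True)
class ConfusionTable:
    """Filter-by-coder cross-tabulation counts ``a, b, c, d``.

    ``a``: retrieved and coded relevant; ``b``: retrieved, coded irrelevant;
    ``c``: unretrieved, coded relevant; ``d``: unretrieved, coded irrelevant.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            object.__setattr__(self, name, _check_count(name, getattr(self, name)))
        if self.n == 0:
            raise ValueError("empty table: a+b+c+d must be positive")

    @property
    def n1(self) -> int:
        """Retrieved total a+b."""
        return self.a + self.b

    @property
    def n2(self) -> int:
        """Unretrieved total c+d."""
        return self.c + self.d

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_dict(self) -> dict[str, int]:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}


@dataclass(frozen=True)
class ArchiveSummary:
    """Archive-level stratum proportions feeding the Bayes recall formula."""

    retrieved_total: int | None = None
    archive_total: int | None = None
    p_retr: float | None = None
    p_rel_unretr: float | None = None

    def __post_init__(self) -> None:
        p_retr = self.p_retr
        if p_retr is None:
            if self.retrieved_total is None or self.archive_total is None:
                raise ValueError("need either p_retr or retrieved_total+archive_total")
            if self.archive_total <= 0:
                raise ValueError("archive_total must be positive")
            p_retr = self.retrieved_total / self.archive_total
            object.__setattr__(self, "p_retr", p_retr)
        if not 0.0 <= p_retr <= 1.0:
            raise ValueError(f"p_retr={p_retr} outside [0, 1]")
        if self.p_rel_unretr is not None and not 0.0 <= self.p_rel_unretr <= 1.0:
            raise ValueError(f"p_rel_unretr={self.p_rel_unretr} outside [0, 1]")


@dataclass(frozen=True)
class StratifiedSample:
    """Coding-sample design: messages sampled per stratum out of each population."""

    retrieved_sampled: int
    unretrieved_sampled: int
    retrieved_population: int
    unretrieved_population: int

    def __post_init__(self) -> None:
        for name in (
            "retrieved_sampled",
            "unretrieved_sampled",
            "retrieved_population",
            "unretrieved_population",
        ):
            _check_count(name, getattr(self, name))
        if self.retrieved_sampled > self.retrieved_population:
            raise ValueError("retrieved_sampled exceeds retrieved_population")
        if self.unretrieved_sampled > self.unretrieved_population:
            raise ValueError("unretrieved_sampled exceeds unretrieved_population")

    @property
    def retrieved_fraction(self) -> float:
        return self.retrieved_sampled / self.retrieved_population

    @property
    def unretrieved_fraction(self) -> float:
        return self.unretrieved_sampled / self.unretrieved_population


def precision(table: ConfusionTable) -> float:
    """Retrieval precision a/(a+b): relevant fraction of what was retrieved."""
    if table.n1 == 0:
        raise UndefinedMetricError("precision undefined: no retrieved messages (a+b=0)")
    return table.a / table.n1


def recall_direct(table: ConfusionTable) -> float:
    """Retrieval recall a/(a+c): retrieved fraction of all relevant messages."""
    if table.a + table.c == 0:
        raise UndefinedMetricError("recall undefined: no relevant messages (a+c=0)")
    return table.a / (table.a + table.c)


def specificity(table: ConfusionTable) -> float:
    """d/(b+d): fraction of irrelevant messages the filter discarded."""
    if table.b + table.d == 0:
        raise UndefinedMetricError("specificity undefined: no irrelevant messages (b+d=0)")
    return table.d / (table.b + table.d)


def npv(table: ConfusionTable) -> float:
    """d/(c+d): irrelevant fraction of unretrieved messages (1 - P(relevant|unretr))."""
    if table.n2 == 0:
        raise UndefinedMetricError("NPV undefined: no unretrieved messages (c+d=0)")
    return table.d / table.n2


def f_score(precision: float, recall: float, beta: float = 1.0) -> float:
    """Weighted harmonic mean of precision and recall.

    ``(1+beta^2) P R / (beta^2 P + R)``; ``beta=1`` gives the F1 score.
    The degenerate case P=R=0 is defined as 0 (the limit value).
    """
    if beta < 0:
        raise ValueError(f"beta must be non-negative, got {beta}")
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    denom = beta * beta * precision + recall
    if denom == 0.0:
        return 0.0
    return (1.0 + beta * beta) * precision * recall / denom


def recall_bayes(precision: float, p_retr: float, p_rel_unretr: float) -> float:
    """Retrieval recall from stratum proportions via Bayes' theorem.

    Requires only the precision of the retrieved stratum, the retrieved
    fraction of the archive, and the relevant fraction among unretrieved
    messages — not the (often unobservable) full table.
    """
    for name, v in (
        ("precision", precision),
        ("p_retr", p_retr),
        ("p_rel_unretr", p_rel_unretr),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    num = precision * p_retr
    denom = num + p_rel_unretr * (1.0 - p_retr)
    if denom == 0.0:
        raise UndefinedMetricError("Bayes recall undefined: no relevant mass on either stratum")
    return num / denom


_CI_METHODS = {"wald": "normal", "wilson": "wilson", "clopper-pearson": "beta"}


def proportion_ci(
    successes: int,
    trials: int,
    level: float = 0.95,
    method: str = "wald",
) -> tuple[float, float]:
    """Two-sided binomial proportion confidence interval.

    ``method`` is one of ``wald`` (default; the usual asymptotic normal
    interval), ``wilson``, or ``clopper-pearson`` (exact).  A Wald request
    at a boundary count (0 or ``trials`` successes), where the normal
    interval collapses to a point, falls back to the exact interval with a
    warning.
    """
    successes = _check_count("successes", successes)
    trials = _check_count("trials", trials)
    if trials == 0:
        raise ValueError("trials must be positive")
    if successes > trials:
        raise ValueError("successes cannot exceed trials")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level={level} outside (0, 1)")
    method = method.lower()
    if method not in _CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}")
    if method == "wald" and successes in (0, trials):
        warnings.warn(
            "Wald interval degenerates at boundary counts; using exact "
            "Clopper-Pearson instead",
            UserWarning,
            stacklevel=2,
        )
        method = "clopper-pearson"
    lo, hi = proportion_confint(successes, trials, alpha=1.0 - level, method=_CI_METHODS[method])
    return float(max(lo, 0.0)), float(min(hi, 1.0))


def recall_bayes_ci(
    table: ConfusionTable,
    design: StratifiedSample,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Parametric-bootstrap interval for the Bayes-theorem recall.

    Propagates the binomial sampling variance of the retrieved-stratum
    precision (a out of n1 sampled) and of the unretrieved relevant
    fraction (c out of n2 sampled); ``P(retr)`` is treated as known from
    the archive counts in ``design``.  Resamples both counts binomially,
    recomputes the recall each time, and returns the percentile interval.
    """
    n1s = table.n1
    n2s = table.n2
    if n1s == 0 or n2s == 0:
        raise UndefinedMetricError("bootstrap needs both strata sampled (n1>0 and n2>0)")
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    p_hat = table.a / n1s
    q_hat = table.c / n2s
    p_retr = design.retrieved_population / (
        design.retrieved_population + design.unretrieved_population
    )
    retr_census = design.retrieved_sampled == design.retrieved_population
    unretr_census = design.unretrieved_sampled == design.unretrieved_population
    # a fully coded stratum contributes no sampling variance
    if retr_census and unretr_census:
        point = recall_bayes(p_hat, p_retr, q_hat)
        return point, point
    rng = np.random.default_rng(seed)
    if retr_census:
        p_star = np.full(n_boot, p_hat)
    else:
        p_star = rng.binomial(n1s, p_hat, size=n_boot) / n1s
    if unretr_census:
        q_star = np.full(n_boot, q_hat)
    else:
        q_star = rng.binomial(n2s, q_hat, size=n_boot) / n2s
    num = p_star * p_retr
    denom = num + q_star * (1.0 - p_retr)
    valid = denom > 0
    draws = num[valid] / denom[valid]
    if draws.size == 0:
        raise UndefinedMetricError("all bootstrap replicates degenerate")
    alpha = 1.0 - level
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def recall_bayes_ci_delta(
    table: ConfusionTable,
    design: StratifiedSample,
    level: float = 0.95,
) -> tuple[float, float]:
    """Delta-method (first-order Taylor) interval for the Bayes recall.

    Cross-check variant for :func:`recall_bayes_ci`; same inputs, normal
    interval around the plug-in point estimate.
    """
    from scipy.stats import norm

    n1s, n2s = table.n1, table.n2
    if n1s == 0 or n2s == 0:
        raise UndefinedMetricError("delta method needs both strata sampled")
    p = table.a / n1s
    q = table.c / n2s
    pr = design.retrieved_population / (
        design.retrieved_population + design.unretrieved_population
    )
    point = recall_bayes(p, pr, q)
    denom = p * pr + q * (1.0 - pr)
    dr_dp = pr * q * (1.0 - pr) / denom**2
    dr_dq = -p * pr * (1.0 - pr) / denom**2
    var = dr_dp**2 * p * (1.0 - p) / n1s + dr_dq**2 * q * (1.0 - q) / n2s
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return max(point - half, 0.0), min(point + half, 1.0)


def adjust_for_sampling(
    retrieved_counts: tuple[int, int],
    unretrieved_counts: tuple[int, int],
    design: StratifiedSample,
) -> ConfusionTable:
    """Rescale the retrieved stratum to undo disproportionate sampling.

    Stratified coding samples oversample the retrieved stratum; before the
    strata can share one table, the retrieved counts are rescaled by the
    ratio of the unretrieved to the retrieved sampling fraction (the
    unretrieved stratum is left verbatim).  Cells are rounded
    half-to-even and margins recomputed from the rounded cells.
    """
    a_s, b_s = (_check_count(k, v) for k, v in zip(("a", "b"), retrieved_counts))
    c_s, d_s = (_check_count(k, v) for k, v in zip(("c", "d"), unretrieved_counts))
    if design.retrieved_sampled == 0 or design.unretrieved_sampled == 0:
        raise ValueError("both strata must have a positive number of sampled messages")
    f_r = design.retrieved_fraction
    f_u = design.unretrieved_fraction
    if f_r == 0.0 or f_u == 0.0:
        raise ValueError("sampling fractions must be positive")
    ratio = f_u / f_r
    # round-half-to-even per cell (Python's banker's rounding)
    return ConfusionTable(a=round(a_s * ratio), b=round(b_s * ratio), c=c_s, d=d_s)


def corrected_precision(table: ConfusionTable, coder_recall: float) -> float:
    """Precision corrected for a silver-standard coder.

    When human coding has perfect specificity but imperfect recall ``S2``
    (coders miss some relevant messages but do not invent relevance), the
    naive precision a/(a+b) underestimates the truth; the corrected value
    is ``a / (S2 * (a+b))``.  Inconsistent inputs can push the ratio above
    1; it is then clamped to 1 with a warning.
    """
    if not 0.0 < coder_recall <= 1.0:
        raise ValueError(f"coder_recall must be in (0, 1], got {coder_recall}")
    raw = precision(table) / coder_recall
    if raw > 1.0:
        warnings.warn(
            f"corrected precision {raw:.4f} exceeds 1 (inconsistent a, b, "
            "coder_recall); clamping to 1.0",
            UserWarning,
            stacklevel=2,
        )
        return 1.0
    return raw
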