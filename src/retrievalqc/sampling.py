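"""Stratified coding-sample design for recall estimation.

Estimating retrieval recall requires coding a sample of unretrieved
messages — finding needles in a haystack, since relevant messages are rare
there.  This module simulates, for a grid of unretrieved sample sizes
``k`` (with the retrieved sample size held fixed), the average width of
the recall confidence interval, reproducing the design analysis used to
choose coding sample sizes: CI width shrinks as ``k`` grows, with rapidly
diminishing returns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contingency import (
    ConfusionTable,
    StratifiedSample,
    recall_bayes,
    recall_bayes_ci,
)

__all__ = ["DesignScenario", "simulate_recall_ci", "recommend_sample_sizes"]


@dataclass(frozen=True)
class DesignScenario:
    """Assumed population and sampling grid for the design simulation.

    The implied prevalence is derived from (precision, recall, p_retr) so
    the scenario is internally consistent:
    ``prevalence = precision * p_retr / recall``.
    """

    population_total: int = 4_000_000
    assumed_precision: float = 0.95
    assumed_recall: float = 0.84
    assumed_p_retr: float = 0.0208
    retrieved_sample_size: int = 3000
    unretrieved_sample_sizes: tuple[int, ...] = (
        1000,
        2000,
        4000,
        6000,
        10000,
        20000,
    )
    replicates: int = 200
    n_boot: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_total <= 0:
            raise ValueError("population_total must be positive")
        for name in ("assumed_precision", "assumed_recall", "assumed_p_retr"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        cells = self.population_cells()
        for key, v in cells.items():
            if v < 0:
                raise ValueError(
                    f"infeasible scenario: implied population cell {key} is negative "
                    f"({v}); check precision/recall/p_retr consistency"
                )
        n_unretr = cells["c"] + cells["d"]
        if max(self.unretrieved_sample_sizes) > n_unretr:
            raise ValueError(
                f"unretrieved sample size grid exceeds the unretrieved population {n_unretr}"
            )
        if self.retrieved_sample_size > cells["a"] + cells["b"]:
            raise ValueError("retrieved_sample_size exceeds the retrieved population")

    @property
    def implied_prevalence(self) -> float:
        return self.assumed_precision * self.assumed_p_retr / self.assumed_recall

    def population_cells(self) -> dict[str, int]:
        """Implied population table cells (rounded to integers)."""
        n = self.population_total
        a = self.assumed_precision * self.assumed_p_retr * n
        b = (1.0 - self.assumed_precision) * self.assumed_p_retr * n
        c = a / self.assumed_recall - a
        d = n * (1.0 - self.assumed_p_retr) - c
        return {"a": round(a), "b": round(b), "c": round(c), "d": round(d)}


def _draw_stratum(
    rng: np.random.Generator,
    sample_size: int,
    successes_pop: int,
    stratum_pop: int,
    hypergeometric: bool,
) -> int:
    if hypergeometric:
        return int(
            rng.hypergeometric(successes_pop, stratum_pop - successes_pop, sample_size)
        )
    return int(rng.binomial(sample_size, successes_pop / stratum_pop))


def simulate_recall_ci(
    scenario: DesignScenario,
    level: float = 0.95,
    small_population: int = 100_000,
) -> pd.DataFrame:
    """Mean recall-CI limits and length per unretrieved sample size ``k``.

    For each replicate, draws a stratified coding sample from the implied
    population table (binomially within strata; hypergeometrically when
    the population is below ``small_population``), estimates recall via the
    Bayes-theorem formula with its parametric-bootstrap CI, and averages
    the limits per ``k``.
    """
    cells = scenario.population_cells()
    pop_retr = cells["a"] + cells["b"]
    pop_unretr = cells["c"] + cells["d"]
    hyper = scenario.population_total < small_population
    rng = np.random.default_rng(scenario.seed)
    rows = []
    n_r = scenario.retrieved_sample_size
    for k in scenario.unretrieved_sample_sizes:
        lows = np.empty(scenario.replicates)
        highs = np.empty(scenario.replicates)
        for r in range(scenario.replicates):
            a_s = _draw_stratum(rng, n_r, cells["a"], pop_retr, hyper)
            c_s = _draw_stratum(rng, k, cells["c"], pop_unretr, hyper)
            table = ConfusionTable(a=a_s, b=n_r - a_s, c=c_s, d=k - c_s)
            design = StratifiedSample(
                retrieved_sampled=n_r,
                unretrieved_sampled=k,
                retrieved_population=pop_retr,
                unretrieved_population=pop_unretr,
            )
            if k == pop_unretr and n_r == pop_retr:
                point = recall_bayes(a_s / n_r, pop_retr / scenario.population_total, c_s / k)
                lows[r], highs[r] = point, point
            else:
                lows[r], highs[r] = recall_bayes_ci(
                    table, design, level=level, n_boot=scenario.n_boot, seed=rng
                )
        rows.append(
            {
                "k": k,
                "mean_lower": lows.mean(),
                "mean_upper": highs.mean(),
                "mean_length": (highs - lows).mean(),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SampleSizeRecommendation:
    """Smallest grid sizes achieving the target CI length (or infeasibility)."""

    feasible: bool
    retrieved_n: int | None = None
    unretrieved_k: int | None = None
    achieved_length: float | None = None
    table: pd.DataFrame | None = field(default=None, compare=False)


def recommend_sample_sizes(
    scenario: DesignScenario,
    target_ci_length: float,
    level: float = 0.95,
) -> SampleSizeRecommendation:
    """Smallest unretrieved sample size whose mean CI length meets the target.

    Scans the scenario's ``k`` grid (retrieved sample size held at the
    scenario value); deterministic given the scenario seed.  Returns an
    explicit infeasibility result when no grid point reaches the target.
    """
    if target_ci_length <= 0:
        raise ValueError("target_ci_length must be positive")
    table = simulate_recall_ci(scenario, level=level)
    ok = table[table["mean_length"] <= target_ci_length]
    if ok.empty:
        return SampleSizeRecommendation(feasible=False, table=table)
    best = ok.iloc[0]
    return SampleSizeRecommendation(
        feasible=True,
        retrieved_n=scenario.retrieved_sample_size,
        unretrieved_k=int(best["k"]),
        achieved_length=float(best["mean_length"]),
        table=table,
    )
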