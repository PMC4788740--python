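"""Latent-class Gibbs sampler for two imperfect classifiers.

When neither the search filter nor the human coders are a gold standard,
the observed filter-vs-coder table (a, b, c, d) is modelled by splitting
each cell into its truly relevant and truly irrelevant parts — latent
counts ``y1..y4`` of relevant messages inside a, b, c, d.  Under
conditional independence of the two classifiers given true relevance, the
eight sub-cells are multinomial in five parameters: the prevalence ``pi``,
the filter's recall/specificity ``S1, C1`` and the coder's ``S2, C2``,
each with a beta prior.

Full conditionals (all beta or binomial):

- ``y1 ~ Bin(a,  pi S1 S2 / [pi S1 S2 + (1-pi)(1-C1)(1-C2)])``
- ``y2 ~ Bin(b,  pi S1 (1-S2) / [pi S1 (1-S2) + (1-pi)(1-C1) C2])``
- ``y3 ~ Bin(c,  pi (1-S1) S2 / [pi (1-S1) S2 + (1-pi) C1 (1-C2)])``
- ``y4 ~ Bin(d,  pi (1-S1)(1-S2) / [pi (1-S1)(1-S2) + (1-pi) C1 C2])``
- ``pi ~ Beta(sum(y) + a_pi, n - sum(y) + b_pi)``
- ``S1 ~ Beta(y1+y2+a_S1, y3+y4+b_S1)``;  ``C1 ~ Beta(c+d-y3-y4+a_C1, a+b-y1-y2+b_C1)``
- ``S2 ~ Beta(y1+y3+a_S2, y2+y4+b_S2)``;  ``C2 ~ Beta(b+d-y2-y4+a_C2, a+c-y1-y3+b_C2)``

Each cycle also records the derived precision and NPV of both classifiers,
``precision_j = S_j pi / [S_j pi + (1-C_j)(1-pi)]`` and
``NPV_j = C_j (1-pi) / [C_j (1-pi) + (1-S_j) pi]``, and each F1 score.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .contingency import ConfusionTable, f_score
from .priors import BetaPrior, PosteriorDraws, summarize_posterior

__all__ = ["LatentClassModel", "gibbs_two_classifier"]

_EPS = 1e-12


def _safe_ratio(num: float, denom: float) -> float:
    if denom > _EPS:
        return num / denom
    return 0.5  # degenerate 0/0 cell: uninformative split


class LatentClassModel(BaseEstimator):
    """Bayesian estimator of prevalence and both classifiers' error rates
    from a filter-vs-coder cross-tabulation, without a gold standard.

    Parameters
    ----------
    prior_prevalence, prior_recall_filter, prior_specificity_filter,
    prior_recall_coder, prior_specificity_coder : BetaPrior
        Beta priors on pi, S1, C1, S2, C2.
    n_cycles, burn_in : int
        Gibbs cycles to run and to discard.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    draws_ : PosteriorDraws
        Chains for ``prevalence``, ``recall_filter``, ``specificity_filter``,
        ``recall_coder``, ``specificity_coder``, plus derived
        ``precision_filter``, ``npv_filter``, ``f1_filter`` and coder
        counterparts.
    posterior_mean_ : dict
    summary_ : dict
    """

    def __init__(
        self,
        prior_prevalence: BetaPrior,
        prior_recall_filter: BetaPrior,
        prior_specificity_filter: BetaPrior,
        prior_recall_coder: BetaPrior,
        prior_specificity_coder: BetaPrior,
        n_cycles: int = 100_000,
        burn_in: int = 10_000,
        random_state=None,
    ):
        self.prior_prevalence = prior_prevalence
        self.prior_recall_filter = prior_recall_filter
        self.prior_specificity_filter = prior_specificity_filter
        self.prior_recall_coder = prior_recall_coder
        self.prior_specificity_coder = prior_specificity_coder
        self.n_cycles = n_cycles
        self.burn_in = burn_in
        self.random_state = random_state

    def fit(self, table: ConfusionTable | tuple, y=None):
        if not isinstance(table, ConfusionTable):
            table = ConfusionTable(*map(int, table))
        if self.n_cycles <= self.burn_in:
            raise ValueError("n_cycles must exceed burn_in")
        a, b, c, d = table.a, table.b, table.c, table.d
        n = table.n
        p_pi = self.prior_prevalence
        p_s1 = self.prior_recall_filter
        p_c1 = self.prior_specificity_filter
        p_s2 = self.prior_recall_coder
        p_c2 = self.prior_specificity_coder
        rng = np.random.default_rng(self.random_state)

        pi, s1, c1, s2, c2 = (p.mean for p in (p_pi, p_s1, p_c1, p_s2, p_c2))

        kept = self.n_cycles - self.burn_in
        names = (
            "prevalence",
            "recall_filter",
            "specificity_filter",
            "recall_coder",
            "specificity_coder",
            "precision_filter",
            "npv_filter",
            "f1_filter",
            "precision_coder",
            "npv_coder",
            "f1_coder",
        )
        chains = {k: np.empty(kept, dtype=float) for k in names}

        j = 0
        for cycle in range(self.n_cycles):
            q1 = _safe_ratio(pi * s1 * s2, pi * s1 * s2 + (1 - pi) * (1 - c1) * (1 - c2))
            q2 = _safe_ratio(pi * s1 * (1 - s2), pi * s1 * (1 - s2) + (1 - pi) * (1 - c1) * c2)
            q3 = _safe_ratio(pi * (1 - s1) * s2, pi * (1 - s1) * s2 + (1 - pi) * c1 * (1 - c2))
            q4 = _safe_ratio(
                pi * (1 - s1) * (1 - s2), pi * (1 - s1) * (1 - s2) + (1 - pi) * c1 * c2
            )
            y1 = rng.binomial(a, q1) if a else 0
            y2 = rng.binomial(b, q2) if b else 0
            y3 = rng.binomial(c, q3) if c else 0
            y4 = rng.binomial(d, q4) if d else 0
            ysum = y1 + y2 + y3 + y4
            pi = rng.beta(ysum + p_pi.alpha, n - ysum + p_pi.beta)
            s1 = rng.beta(y1 + y2 + p_s1.alpha, y3 + y4 + p_s1.beta)
            c1 = rng.beta(c + d - y3 - y4 + p_c1.alpha, a + b - y1 - y2 + p_c1.beta)
            s2 = rng.beta(y1 + y3 + p_s2.alpha, y2 + y4 + p_s2.beta)
            c2 = rng.beta(b + d - y2 - y4 + p_c2.alpha, a + c - y1 - y3 + p_c2.beta)
            if cycle >= self.burn_in:
                chains["prevalence"][j] = pi
                chains["recall_filter"][j] = s1
                chains["specificity_filter"][j] = c1
                chains["recall_coder"][j] = s2
                chains["specificity_coder"][j] = c2
                prec1 = _safe_ratio(s1 * pi, s1 * pi + (1 - c1) * (1 - pi))
                npv1 = _safe_ratio(c1 * (1 - pi), c1 * (1 - pi) + (1 - s1) * pi)
                prec2 = _safe_ratio(s2 * pi, s2 * pi + (1 - c2) * (1 - pi))
                npv2 = _safe_ratio(c2 * (1 - pi), c2 * (1 - pi) + (1 - s2) * pi)
                chains["precision_filter"][j] = prec1
                chains["npv_filter"][j] = npv1
                chains["f1_filter"][j] = f_score(prec1, s1, 1.0)
                chains["precision_coder"][j] = prec2
                chains["npv_coder"][j] = npv2
                chains["f1_coder"][j] = f_score(prec2, s2, 1.0)
                j += 1

        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) else None
        self.table_ = table
        self.draws_ = PosteriorDraws(
            draws=chains, n_cycles=self.n_cycles, burn_in=self.burn_in, seed=seed
        )
        self.posterior_mean_ = {k: float(v.mean()) for k, v in chains.items()}
        self.summary_ = summarize_posterior(
            self.draws_,
            priors={
                "prevalence": p_pi,
                "recall_filter": p_s1,
                "specificity_filter": p_c1,
                "recall_coder": p_s2,
                "specificity_coder": p_c2,
            },
        )
        return self


def gibbs_two_classifier(
    table: ConfusionTable | tuple,
    priors: dict[str, BetaPrior],
    n_cycles: int = 100_000,
    burn_in: int = 10_000,
    seed=None,
) -> PosteriorDraws:
    """Functional wrapper over :class:`LatentClassModel`.

    ``priors`` maps ``{"pi", "S1", "C1", "S2", "C2"}`` to beta priors.
    """
    model = LatentClassModel(
        prior_prevalence=priors["pi"],
        prior_recall_filter=priors["S1"],
        prior_specificity_filter=priors["C1"],
        prior_recall_coder=priors["S2"],
        prior_specificity_coder=priors["C2"],
        n_cycles=n_cycles,
        burn_in=burn_in,
        random_state=seed,
    )
    return model.fit(table).draws_
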