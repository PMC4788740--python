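"""Gibbs sampler for filter recall when unretrieved messages were not archived.

Many collections keep only the messages a search filter retrieved, so the
false-negative cell ``c`` of the filter-vs-coder table is unobservable; all
that is known is the retrieved total ``n1``, the (approximate) unretrieved
total ``n2``, and a confidence interval for the coded-sample precision of
the retrieved stratum.  Following the latent-class tradition of Bayesian
diagnostic-test models without a gold standard, the model treats ``c`` as a
latent count and places beta priors on the prevalence ``pi`` of relevant
messages, the filter recall ``S`` and the filter specificity ``C``.

Each Gibbs cycle:

1. draw precision uniformly on its confidence interval and set
   ``a = round(precision * n1)``, ``b = n1 - a``;
2. draw the latent count ``c ~ Binomial(n2, q)`` with
   ``q = (1-S) pi / [(1-S) pi + C (1-pi)]`` — the conditional probability
   that an unretrieved message is relevant — and set ``d = n2 - c``;
3. draw ``pi ~ Beta(a+c+alpha_pi, n-a-c+beta_pi)``;
4. draw ``S ~ Beta(a+alpha_S, c+beta_S)``;
5. draw ``C ~ Beta(d+alpha_C, b+beta_C)``;
6. record the cycle's pi, S, C, precision, plus the derived NPV and the F1
   score of the cycle's precision and recall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .contingency import f_score
from .priors import BetaPrior, PosteriorDraws, summarize_posterior

__all__ = ["UnarchivedEvidence", "UnarchivedRecallModel", "gibbs_unarchived"]

_EPS = 1e-12


@dataclass(frozen=True)
class UnarchivedEvidence:
    """Observable inputs when only retrieved messages were archived."""

    n1: int
    n2: int
    precision_interval: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("n1 and n2 must be non-negative")
        lo, hi = self.precision_interval
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError(f"precision interval {self.precision_interval} outside [0, 1]")


class UnarchivedRecallModel(BaseEstimator):
    """Bayesian estimator of prevalence, filter recall and specificity
    from retrieved-only evidence.

    Parameters
    ----------
    prior_prevalence, prior_recall, prior_specificity : BetaPrior
        Beta priors on pi, S and C.
    n_cycles, burn_in : int
        Gibbs cycles to run and to discard.
    precision_mode : {"per_cycle", "fixed"}
        Whether the coded-sample precision is redrawn from its interval
        every cycle (default; propagates its uncertainty into every
        posterior) or drawn once at initialization.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    draws_ : PosteriorDraws
        Post-burn-in chains for ``prevalence``, ``recall``,
        ``specificity``, ``precision``, ``npv`` and ``f1``.
    posterior_mean_ : dict
        Posterior mean per recorded parameter.
    summary_ : dict
        Mean + HPD table from :func:`summarize_posterior`.
    """

    def __init__(
        self,
        prior_prevalence: BetaPrior,
        prior_recall: BetaPrior,
        prior_specificity: BetaPrior,
        n_cycles: int = 100_000,
        burn_in: int = 10_000,
        precision_mode: str = "per_cycle",
        thin: int = 1,
        random_state=None,
    ):
        self.prior_prevalence = prior_prevalence
        self.prior_recall = prior_recall
        self.prior_specificity = prior_specificity
        self.n_cycles = n_cycles
        self.burn_in = burn_in
        self.precision_mode = precision_mode
        self.thin = thin
        self.random_state = random_state

    def fit(self, evidence: UnarchivedEvidence, y=None):
        if not isinstance(evidence, UnarchivedEvidence):
            n1, n2, interval = evidence
            evidence = UnarchivedEvidence(int(n1), int(n2), tuple(interval))
        if self.n_cycles <= self.burn_in:
            raise ValueError("n_cycles must exceed burn_in")
        if self.precision_mode not in ("per_cycle", "fixed"):
            raise ValueError(f"unknown precision_mode {self.precision_mode!r}")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        pp, ps, pc = self.prior_prevalence, self.prior_recall, self.prior_specificity
        rng = np.random.default_rng(self.random_state)
        n1, n2 = evidence.n1, evidence.n2
        n = n1 + n2
        p_lo, p_hi = evidence.precision_interval

        pi, s, c_spec = pp.mean, ps.mean, pc.mean
        prec_fixed = rng.uniform(p_lo, p_hi) if p_lo < p_hi else p_lo

        kept = (self.n_cycles - self.burn_in) // self.thin
        names = ("prevalence", "recall", "specificity", "precision", "npv", "f1")
        chains = {k: np.empty(kept, dtype=float) for k in names}

        j = 0
        for cycle in range(self.n_cycles):
            if self.precision_mode == "per_cycle" and p_lo < p_hi:
                prec = rng.uniform(p_lo, p_hi)
            else:
                prec = prec_fixed
            # round-half-to-even, as for the sampling-fraction adjustment
            a = round(prec * n1)
            b = n1 - a
            num = (1.0 - s) * pi
            denom = num + c_spec * (1.0 - pi)
            q = num / denom if denom > _EPS else 0.5
            c_lat = rng.binomial(n2, q) if n2 > 0 else 0
            d = n2 - c_lat
            pi = rng.beta(a + c_lat + pp.alpha, n - a - c_lat + pp.beta)
            s = rng.beta(a + ps.alpha, c_lat + ps.beta)
            c_spec = rng.beta(d + pc.alpha, b + pc.beta)
            if cycle >= self.burn_in and (cycle - self.burn_in) % self.thin == 0:
                npv_den = c_spec * (1.0 - pi) + (1.0 - s) * pi
                chains["prevalence"][j] = pi
                chains["recall"][j] = s
                chains["specificity"][j] = c_spec
                chains["precision"][j] = prec
                chains["npv"][j] = c_spec * (1.0 - pi) / npv_den if npv_den > _EPS else 1.0
                chains["f1"][j] = f_score(prec, s, 1.0)
                j += 1

        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) else None
        self.evidence_ = evidence
        self.draws_ = PosteriorDraws(
            draws={k: v[:j] for k, v in chains.items()},
            n_cycles=self.burn_in + j * self.thin,
            burn_in=self.burn_in,
            seed=seed,
            extra={"thin": self.thin, "precision_mode": self.precision_mode},
        )
        self.posterior_mean_ = {k: float(v[:j].mean()) for k, v in chains.items()}
        self.summary_ = summarize_posterior(
            self.draws_,
            priors={
                "prevalence": pp,
                "recall": ps,
                "specificity": pc,
            },
        )
        return self


def gibbs_unarchived(
    evidence: UnarchivedEvidence,
    priors: dict[str, BetaPrior],
    n_cycles: int = 100_000,
    burn_in: int = 10_000,
    seed=None,
    precision_mode: str = "per_cycle",
) -> PosteriorDraws:
    """Functional wrapper over :class:`UnarchivedRecallModel`.

    ``priors`` maps ``{"pi": ..., "S": ..., "C": ...}`` to beta priors.
    """
    model = UnarchivedRecallModel(
        prior_prevalence=priors["pi"],
        prior_recall=priors["S"],
        prior_specificity=priors["C"],
        n_cycles=n_cycles,
        burn_in=burn_in,
        precision_mode=precision_mode,
        random_state=seed,
    )
    return model.fit(evidence).draws_
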