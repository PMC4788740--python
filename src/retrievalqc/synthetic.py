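"""Synthetic corpora and classifier outcomes with known ground truth.

Every estimator in the package is testable without platform access: this
module plants a known prevalence of topic-relevant messages, a filter with
known recall/specificity, and coders with known error rates, so parameter
recovery can be checked end to end.  Text generation is deliberately
simple (bag-of-terms templates); the statistical structure — not realism —
is the contract.  Ambiguous decoy terms (think "smoking ribs" in a tobacco
corpus) are planted in a fraction of irrelevant messages so a naive term
filter exhibits false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .contingency import ConfusionTable
from .filter_engine import Message

__all__ = [
    "GroundTruthConfig",
    "Vocabulary",
    "LabeledCorpus",
    "generate_labeled_corpus",
    "simulate_outcomes",
    "outcome_table",
]


@dataclass(frozen=True)
class GroundTruthConfig:
    """True prevalence and classifier operating characteristics to plant."""

    n_messages: int = 10_000
    prevalence: float = 0.028
    filter_recall: float = 0.93
    filter_specificity: float = 0.999
    coder_recall: float = 0.96
    coder_specificity: float = 0.998
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_messages <= 0:
            raise ValueError("n_messages must be positive")
        for name in (
            "prevalence",
            "filter_recall",
            "filter_specificity",
            "coder_recall",
            "coder_specificity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class Vocabulary:
    """Term pools for text generation."""

    relevant_terms: tuple[str, ...] = (
        "vapestick",
        "cloudpen",
        "nicomist",
        "vaping",
        "ecig",
    )
    decoys: tuple[str, ...] = ("smoking ribs", "smoking hot", "vapor trail")
    background: tuple[str, ...] = (
        "coffee",
        "morning",
        "weather",
        "football",
        "music",
        "traffic",
        "lunch",
        "movie",
    )

    def __post_init__(self) -> None:
        if not (self.relevant_terms and self.background):
            raise ValueError("relevant and background vocabularies must be non-empty")


@dataclass
class LabeledCorpus:
    """Messages plus per-id ground truth (and optional simulated outcomes)."""

    messages: list[Message]
    truth: dict[str, bool]
    outcomes: pd.DataFrame | None = None
    config: GroundTruthConfig | None = None


def generate_labeled_corpus(
    config: GroundTruthConfig,
    vocabulary: Vocabulary | None = None,
    decoy_fraction: float = 0.05,
    start: datetime | None = None,
) -> LabeledCorpus:
    """Generate a corpus whose relevance labels are Bernoulli(prevalence).

    Relevant messages embed one or two relevant terms among background
    words; a ``decoy_fraction`` of irrelevant messages embed an ambiguous
    decoy phrase.  Timestamps spread uniformly over one calendar month.
    Deterministic for a given config seed.
    """
    vocab = vocabulary or Vocabulary()
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction outside [0, 1]")
    rng = np.random.default_rng(config.seed)
    n = config.n_messages
    relevant = rng.random(n) < config.prevalence
    start = start or datetime(2012, 10, 1, tzinfo=timezone.utc)
    offsets = rng.integers(0, 30 * 24 * 3600, size=n)
    messages: list[Message] = []
    truth: dict[str, bool] = {}
    bg = vocab.background
    for i in range(n):
        words = list(rng.choice(bg, size=4))
        if relevant[i]:
            k = min(1 + int(rng.random() < 0.3), len(vocab.relevant_terms))
            terms = rng.choice(vocab.relevant_terms, size=k, replace=False)
            pos = rng.integers(0, len(words) + 1)
            words[pos:pos] = list(terms)
        elif vocab.decoys and rng.random() < decoy_fraction:
            pos = rng.integers(0, len(words) + 1)
            words.insert(pos, str(rng.choice(vocab.decoys)))
        mid = f"m{i:07d}"
        messages.append(
            Message(
                id=mid,
                timestamp=start + timedelta(seconds=int(offsets[i])),
                text=" ".join(words),
                author=f"@user{int(rng.integers(0, max(n // 10, 1))):06d}",
            )
        )
        truth[mid] = bool(relevant[i])
    return LabeledCorpus(messages=messages, truth=truth, config=config)


def simulate_outcomes(
    labels: np.ndarray | list[bool],
    config: GroundTruthConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate filter flags and coder labels from ground truth.

    Conditionally independent Bernoulli mechanisms given truth: a relevant
    message is flagged by the filter with probability ``filter_recall`` and
    coded relevant with probability ``coder_recall``; an irrelevant one is
    (wrongly) flagged with ``1 - filter_specificity`` and coded relevant
    with ``1 - coder_specificity``.
    """
    truth = np.asarray(labels, dtype=bool)
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    u1 = rng.random(truth.size)
    u2 = rng.random(truth.size)
    filter_flag = np.where(
        truth, u1 < config.filter_recall, u1 < 1.0 - config.filter_specificity
    )
    coder_label = np.where(
        truth, u2 < config.coder_recall, u2 < 1.0 - config.coder_specificity
    )
    return pd.DataFrame(
        {"truth": truth, "filter_flag": filter_flag, "coder_label": coder_label}
    )


def outcome_table(outcomes: pd.DataFrame) -> ConfusionTable:
    """Cross-tabulate simulated filter flags against coder labels."""
    f = outcomes["filter_flag"].to_numpy()
    c = outcomes["coder_label"].to_numpy()
    return ConfusionTable(
        a=int((f & c).sum()),
        b=int((f & ~c).sum()),
        c=int((~f & c).sum()),
        d=int((~f & ~c).sum()),
    )
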