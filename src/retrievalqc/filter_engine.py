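"""Boolean keyword search filters over tweet-like message corpora.

A search filter is a set of keywords (grouped into categories such as
device / brand / behavior) combined with boolean search rules (AND, OR,
NOT), co-occurrence exclusion pairs that veto messages where two terms
appear together (e.g. "atomizer" with "perfume"), and account-handle rules
that retrieve a message authored by or mentioning a listed handle
regardless of its terms.

Matching is case-insensitive and token based: ``word`` mode matches the
keyword's token sequence at word boundaries (multi-token surfaces behave
as exact phrases), ``phrase`` is an alias making the n-gram intent
explicit, ``hashtag`` matches the tag with or without the leading ``#``,
and ``handle`` matches the author field or an ``@mention`` in the text.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Keyword",
    "SearchFilter",
    "Message",
    "FilterCompileError",
    "CompiledFilter",
    "KeywordSearchFilter",
    "compile_filter",
    "apply_filter",
    "screen_keywords",
]

MATCH_MODES = ("word", "phrase", "handle", "hashtag")

_TOKEN_RE = re.compile(r"[#@]?\w+", re.UNICODE)


def _casefold(text: str) -> str:
    return unicodedata.normalize("NFKC", text).casefold()


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(_casefold(text))


@dataclass(frozen=True)
class Keyword:
    """One search term with its category and match mode."""

    surface: str
    category: str = "uncategorized"
    mode: str = "word"

    def __post_init__(self) -> None:
        if not self.surface or not self.surface.strip():
            raise ValueError("keyword surface form must be non-empty")
        if self.mode not in MATCH_MODES:
            raise ValueError(f"unknown match mode {self.mode!r}; choose from {MATCH_MODES}")
        if self.mode == "handle" and not self.surface.startswith("@"):
            raise ValueError(f"handle keyword {self.surface!r} must start with '@'")


@dataclass(frozen=True)
class Message:
    """One corpus record: id, timestamp, free text, author handle."""

    id: str
    timestamp: datetime | str | None
    text: str
    author: str = ""


@dataclass
class SearchFilter:
    """Keyword set plus boolean include rule and exclusion veto pairs.

    ``rule`` is a nested boolean expression over keyword surfaces:
    ``"term"`` (leaf), ``{"any": [...]}`` (OR), ``{"all": [...]}`` (AND),
    ``{"not": expr}``.  When omitted, the rule defaults to "any declared
    non-handle keyword matches".  ``exclusions`` are pairs of surfaces
    whose co-occurrence vetoes retrieval.  Handle-mode keywords retrieve
    unconditionally.
    """

    keywords: Sequence[Keyword]
    rule: object | None = None
    exclusions: Sequence[tuple[str, str]] = field(default_factory=list)
    name: str = "search-filter"


class FilterCompileError(ValueError):
    """The filter definition references an undeclared keyword or is malformed."""


def _keyword_predicate(kw: Keyword) -> Callable[[list[str], str], bool]:
    if kw.mode in ("word", "phrase"):
        pattern = [t.lstrip("#@") for t in _tokenize(kw.surface)]
        if not pattern:
            raise FilterCompileError(f"keyword {kw.surface!r} has no tokens")
        k = len(pattern)

        def pred(tokens: list[str], author: str) -> bool:
            stripped = [t.lstrip("#@") for t in tokens]
            return any(stripped[i : i + k] == pattern for i in range(len(stripped) - k + 1))

        return pred
    if kw.mode == "hashtag":
        tag = _casefold(kw.surface).lstrip("#")

        def pred(tokens: list[str], author: str) -> bool:
            return any(t.lstrip("#") == tag for t in tokens)

        return pred
    # handle: author match or @mention in text
    handle = _casefold(kw.surface).lstrip("@")

    def pred(tokens: list[str], author: str) -> bool:
        if _casefold(author).lstrip("@") == handle:
            return True
        return any(t == "@" + handle for t in tokens)

    return pred


class CompiledFilter:
    """Deterministic predicate over :class:`Message` with match provenance."""

    def __init__(self, definition: SearchFilter):
        self.definition = definition
        self._predicates: dict[str, Callable] = {}
        self._modes: dict[str, str] = {}
        for kw in definition.keywords:
            key = _casefold(kw.surface)
            self._predicates[key] = _keyword_predicate(kw)
            self._modes[key] = kw.mode
        self._handles = [k for k, m in self._modes.items() if m == "handle"]
        self._rule = self._compile_rule(
            definition.rule
            if definition.rule is not None
            else {"any": [k for k, m in self._modes.items() if m != "handle"]}
        )
        self._exclusions = []
        for pair in definition.exclusions:
            if len(pair) != 2:
                raise FilterCompileError(f"exclusion {pair!r} is not a pair")
            for term in pair:
                if _casefold(term) not in self._predicates:
                    raise FilterCompileError(
                        f"exclusion references undeclared keyword {term!r}"
                    )
            self._exclusions.append(tuple(_casefold(t) for t in pair))

    def _compile_rule(self, expr) -> Callable[[Mapping[str, bool]], bool]:
        if isinstance(expr, str):
            key = _casefold(expr)
            if key not in self._predicates:
                raise FilterCompileError(f"rule references undeclared keyword {expr!r}")
            return lambda hits: hits[key]
        if isinstance(expr, Mapping):
            if len(expr) != 1:
                raise FilterCompileError(f"rule node {expr!r} must have exactly one operator")
            op, operand = next(iter(expr.items()))
            if op == "any":
                subs = [self._compile_rule(e) for e in operand]
                return lambda hits: any(s(hits) for s in subs)
            if op == "all":
                subs = [self._compile_rule(e) for e in operand]
                return lambda hits: all(s(hits) for s in subs)
            if op == "not":
                sub = self._compile_rule(operand)
                return lambda hits: not sub(hits)
            raise FilterCompileError(f"unknown boolean operator {op!r}")
        raise FilterCompileError(f"malformed rule node {expr!r}")

    def match(self, message: Message) -> tuple[bool, list[str]]:
        """Return (retrieved?, list of matched keyword surfaces)."""
        tokens = _tokenize(message.text)
        hits = {
            key: pred(tokens, message.author) for key, pred in self._predicates.items()
        }
        matched = sorted(k for k, v in hits.items() if v)
        if any(hits[h] for h in self._handles):
            return True, matched
        if not self._rule(hits):
            return False, matched
        for t1, t2 in self._exclusions:
            if hits[t1] and hits[t2]:
                return False, matched
        return True, matched

    def __call__(self, message: Message) -> bool:
        return self.match(message)[0]


def compile_filter(definition: SearchFilter) -> CompiledFilter:
    """Compile a filter definition into a deterministic message predicate."""
    return CompiledFilter(definition)


def apply_filter(
    corpus: Iterable[Message],
    matcher: CompiledFilter,
) -> tuple[list[Message], list[Message], dict[str, list[str]], int]:
    """Partition a corpus into (retrieved, unretrieved) with provenance.

    Returns ``(retrieved, unretrieved, provenance, n_malformed)`` where
    ``provenance`` maps message id to the matched keyword surfaces and
    malformed records (non-Message, missing text) are skipped and counted,
    never silently dropped.
    """
    retrieved: list[Message] = []
    unretrieved: list[Message] = []
    provenance: dict[str, list[str]] = {}
    malformed = 0
    for msg in corpus:
        if not isinstance(msg, Message) or not isinstance(msg.text, str):
            malformed += 1
            continue
        hit, matched = matcher.match(msg)
        provenance[msg.id] = matched
        (retrieved if hit else unretrieved).append(msg)
    return retrieved, unretrieved, provenance, malformed


class KeywordSearchFilter:
    """Transformer-style wrapper: ``transform`` flags each message.

    Compiles at construction; ``transform(corpus)`` returns a DataFrame
    with columns ``id``, ``retrieved``, ``matched`` aligned with the
    corpus order.  Stateless across calls, so ``fit`` is a no-op.
    """

    def __init__(self, definition: SearchFilter):
        self.definition = definition
        self.matcher_ = compile_filter(definition)

    def fit(self, corpus=None, y=None):
        return self

    def transform(self, corpus: Iterable[Message]) -> pd.DataFrame:
        rows = []
        for msg in corpus:
            hit, matched = self.matcher_.match(msg)
            rows.append({"id": msg.id, "retrieved": hit, "matched": matched})
        return pd.DataFrame(rows, columns=["id", "retrieved", "matched"])

    def get_params(self, deep: bool = True) -> dict:
        return {"definition": self.definition}

    def set_params(self, **params):
        if "definition" in params:
            self.definition = params["definition"]
            self.matcher_ = compile_filter(self.definition)
        return self


def _to_utc(ts) -> pd.Timestamp:
    t = pd.Timestamp(ts)
    if t.tzinfo is None:
        return t.tz_localize(timezone.utc)
    return t.tz_convert(timezone.utc)


def screen_keywords(
    corpus: Sequence[Message],
    keywords: Sequence[Keyword],
    coded_labels: Mapping[str, bool] | None = None,
    freq_threshold: float = 10.0,
    precision_threshold: float = 0.30,
) -> pd.DataFrame:
    """Per-keyword frequency and precision screening.

    For each keyword: matches per calendar month over the corpus span and,
    where coded relevance labels are available for matching messages, the
    precision among coded matches.  A keyword is flagged ``discard`` when
    its monthly frequency falls below ``freq_threshold`` (default 10 per
    month) or its coded precision falls below ``precision_threshold``
    (default 0.30, i.e. more than 70% of its matches are irrelevant).
    Without labels, precision is reported as NaN and only the frequency
    rule applies.
    """
    if not corpus:
        raise ValueError("empty corpus")
    stamps = [_to_utc(m.timestamp) for m in corpus if m.timestamp is not None]
    if stamps:
        first = min(stamps).tz_localize(None).to_period("M")
        last = max(stamps).tz_localize(None).to_period("M")
        months = pd.period_range(first, last, freq="M").size
    else:
        months = 1
    rows = []
    for kw in keywords:
        pred = _keyword_predicate(kw)
        match_ids = [
            m.id for m in corpus if pred(_tokenize(m.text), m.author)
        ]
        n_matches = len(match_ids)
        freq_per_month = n_matches / months
        prec = float("nan")
        if coded_labels is not None:
            coded = [coded_labels[i] for i in match_ids if i in coded_labels]
            if coded:
                prec = sum(coded) / len(coded)
        low_freq = freq_per_month < freq_threshold
        low_prec = prec == prec and prec < precision_threshold  # NaN-safe
        reason = []
        if low_freq:
            reason.append(f"frequency {freq_per_month:.1f}/month < {freq_threshold}")
        if low_prec:
            reason.append(f"precision {prec:.2f} < {precision_threshold}")
        rows.append(
            {
                "surface": kw.surface,
                "category": kw.category,
                "mode": kw.mode,
                "matches": n_matches,
                "months": months,
                "freq_per_month": freq_per_month,
                "precision": prec,
                "discard": bool(low_freq or low_prec),
                "reason": "; ".join(reason),
            }
        )
    return pd.DataFrame(rows)
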