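"""Corpus, filter-definition and config readers/writers.

Corpora are one record per line: JSON-object lines (fields ``id``,
``timestamp``, ``text``, ``author``) or delimited text with a header.
Filter definitions are YAML/JSON with keywords grouped by category, a
nested boolean rule, and exclusion pairs.  Ground-truth sidecars are
JSON-lines keyed by message id.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .filter_engine import Keyword, Message, SearchFilter

__all__ = [
    "read_corpus",
    "write_corpus",
    "read_truth",
    "write_truth",
    "read_filter_definition",
    "read_config",
    "CorpusFormatError",
]

logger = logging.getLogger("retrievalqc")

_REQUIRED_FIELDS = ("id", "text")


class CorpusFormatError(ValueError):
    """Unreadable corpus: unknown format or too many malformed records."""


def _message_from_record(rec: Mapping) -> Message | None:
    if not all(k in rec and rec[k] not in (None, "") for k in _REQUIRED_FIELDS):
        return None
    return Message(
        id=str(rec["id"]),
        timestamp=rec.get("timestamp"),
        text=str(rec["text"]),
        author=str(rec.get("author", "")),
    )


def read_corpus(path: str | Path, format: str = "jsonl") -> tuple[list[Message], int]:
    """Read a corpus file; returns (messages, n_malformed).

    ``format`` is ``jsonl`` (default) or ``csv``/``tsv``.  Malformed
    records are skipped and counted; more than 50% malformed aborts with
    diagnostics.  An empty file yields an empty corpus with a warning.
    """
    path = Path(path)
    messages: list[Message] = []
    malformed = 0
    total = 0
    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                total += 1
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError:
                    malformed += 1
                    continue
                msg = _message_from_record(rec) if isinstance(rec, Mapping) else None
                if msg is None:
                    malformed += 1
                else:
                    messages.append(msg)
    elif format in ("csv", "tsv"):
        delim = "\t" if format == "tsv" else ","
        with path.open(encoding="utf-8", newline="") as fh:
            for rec in csv.DictReader(fh, delimiter=delim):
                total += 1
                msg = _message_from_record(rec)
                if msg is None:
                    malformed += 1
                else:
                    messages.append(msg)
    else:
        raise CorpusFormatError(f"unknown corpus format {format!r}")
    if total == 0:
        logger.warning("corpus file %s is empty", path)
    elif malformed > total / 2:
        raise CorpusFormatError(
            f"{malformed}/{total} records malformed in {path}; refusing to continue"
        )
    elif malformed:
        logger.warning("skipped %d malformed record(s) in %s", malformed, path)
    return messages, malformed


def write_corpus(messages: Iterable[Message], path: str | Path) -> None:
    """Write messages as JSON lines (timestamps serialized to ISO 8601)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for m in messages:
            ts = m.timestamp
            if hasattr(ts, "isoformat"):
                ts = ts.isoformat()
            fh.write(
                json.dumps(
                    {"id": m.id, "timestamp": ts, "text": m.text, "author": m.author},
                    ensure_ascii=False,
                )
                + "\n"
            )


def write_truth(truth: Mapping[str, bool], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for mid, rel in truth.items():
            fh.write(json.dumps({"id": mid, "relevant": bool(rel)}) + "\n")


def read_truth(path: str | Path) -> dict[str, bool]:
    out: dict[str, bool] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rec = json.loads(line)
                out[str(rec["id"])] = bool(rec["relevant"])
    return out


def read_filter_definition(path: str | Path) -> SearchFilter:
    """Load a filter definition from YAML/JSON.

    Schema::

        name: my-filter
        keywords:
          device: [{surface: "e-cig", mode: word}, ...]   # by category
          brand:  [...]
        rule: {any: [...]}          # optional boolean expression
        exclusions: [[atomizer, perfume], ...]
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "keywords" not in raw:
        raise ValueError(f"filter definition {path} must be a mapping with 'keywords'")
    keywords: list[Keyword] = []
    for category, entries in raw["keywords"].items():
        for entry in entries:
            if isinstance(entry, str):
                entry = {"surface": entry}
            keywords.append(
                Keyword(
                    surface=entry["surface"],
                    category=str(category),
                    mode=entry.get("mode", "word"),
                )
            )
    exclusions = [tuple(pair) for pair in raw.get("exclusions", [])]
    return SearchFilter(
        keywords=keywords,
        rule=raw.get("rule"),
        exclusions=exclusions,
        name=str(raw.get("name", path.stem)),
    )


def read_config(path: str | Path) -> dict:
    """Load a run config (YAML or JSON) into a plain dict."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config {path} must be a mapping")
    return dict(cfg)
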