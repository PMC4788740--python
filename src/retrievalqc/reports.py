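"""Assessment reports: machine-readable JSON plus a human-readable
markdown document covering the data-preparation reporting checklist
(data source, search-filter development, coding assumptions, sampling
frame and sizes, and how precision/recall were estimated).

Reports are deterministic functions of (config, seed): no wall-clock
timestamps; every report embeds the seed and a hash of the resolved
configuration so two identical runs produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = ["AssessmentReport", "config_hash", "emit_report", "ReportValidationError"]

CHECKLIST_FIELDS = (
    "data_source",
    "filter_provenance",
    "coding_assumptions",
    "sampling_design",
)


class ReportValidationError(ValueError):
    """A required checklist or mode-specific field is missing."""


def config_hash(config: Mapping) -> str:
    """Stable short hash of a resolved configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


@dataclass
class AssessmentReport:
    """One filter-assessment run, ready for serialization.

    ``mode`` is ``classical``, ``unarchived`` or ``latent_class``;
    Bayesian modes must state their resolved priors.  ``estimates`` maps
    quantity name to ``{"value": ..., "interval": (lo, hi)}`` (interval
    optional).
    """

    mode: str
    data_source: str
    filter_provenance: str
    coding_assumptions: str
    sampling_design: Mapping
    estimates: Mapping[str, Mapping]
    seed: int | None = None
    config: Mapping = field(default_factory=dict)
    priors: Mapping | None = None

    def validate(self) -> None:
        for name in CHECKLIST_FIELDS:
            if not getattr(self, name):
                raise ReportValidationError(f"checklist field {name!r} is empty")
        if self.mode not in ("classical", "unarchived", "latent_class"):
            raise ReportValidationError(f"unknown assessment mode {self.mode!r}")
        if self.mode != "classical" and not self.priors:
            raise ReportValidationError(
                f"mode {self.mode!r} requires the resolved priors block"
            )
        if not self.estimates:
            raise ReportValidationError("no estimates to report")

    def to_dict(self) -> dict:
        self.validate()
        return {
            "mode": self.mode,
            "checklist": {
                "data_source": self.data_source,
                "filter_provenance": self.filter_provenance,
                "coding_assumptions": self.coding_assumptions,
                "sampling_design": dict(self.sampling_design),
            },
            "estimates": {k: dict(v) for k, v in self.estimates.items()},
            "priors": {k: dict(v) for k, v in (self.priors or {}).items()} or None,
            "seed": self.seed,
            "config_hash": config_hash(self.config),
        }

    def to_markdown(self) -> str:
        doc = self.to_dict()
        lines = [
            f"# Search-filter assessment ({self.mode})",
            "",
            "## Data source",
            self.data_source,
            "",
            "## Search filter",
            self.filter_provenance,
            "",
            "## Human-coding assumptions",
            self.coding_assumptions,
            "",
            "## Sampling design",
        ]
        for k, v in doc["checklist"]["sampling_design"].items():
            lines.append(f"- {k}: {v}")
        if doc["priors"]:
            lines += ["", "## Priors (resolved beta shapes)"]
            lines.append("| parameter | alpha | beta | prior mean |")
            lines.append("|---|---|---|---|")
            for name, p in doc["priors"].items():
                mean = p["alpha"] / (p["alpha"] + p["beta"])
                lines.append(
                    f"| {name} | {p['alpha']:.4g} | {p['beta']:.4g} | {mean:.3f} |"
                )
        lines += ["", "## Estimates", "", "| quantity | estimate | 95% interval |", "|---|---|---|"]
        for name, est in doc["estimates"].items():
            interval = est.get("interval")
            itxt = f"({interval[0]:.3f}, {interval[1]:.3f})" if interval else "-"
            lines.append(f"| {name} | {est['value']:.4f} | {itxt} |")
        lines += [
            "",
            f"Seed: {doc['seed']}; config hash: `{doc['config_hash']}`.",
            "",
        ]
        return "\n".join(lines)


def emit_report(
    report: AssessmentReport,
    out_dir: str | Path,
    stem: str = "assessment",
    formats: tuple[str, ...] = ("json", "md"),
) -> list[Path]:
    """Write the report in the requested formats; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        path = out_dir / f"{stem}.{fmt}"
        if fmt == "json":
            path.write_text(
                json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
        elif fmt == "md":
            path.write_text(report.to_markdown(), encoding="utf-8")
        else:
            raise ValueError(f"unknown report format {fmt!r}")
        written.append(path)
    return written
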