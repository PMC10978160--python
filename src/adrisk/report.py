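"""End-to-end assessment and report rendering.

:func:`assess` runs the full pipeline — catalog -> hazard groups ->
monitoring summaries -> MRL scoring -> classification against the ARL —
for all 16 (group, preparation-mode) strata.  Strata without monitoring
data are listed as skipped, never silently dropped.  Reports serialise
losslessly to JSON (schema-versioned) and render to a human-readable
markdown layout with groups as columns and parameters as rows.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import __version__
from .arl import PrepMode, arl_profile
from .catalog import ADGroup, DrugRecord
from .config import AssessConfig
from .errors import AdriskError, EmptyStratumError
from .monitoring import MonitoringCampaign, MonitoringSummary, summarize_group
from .scoring import (
    PARAMETERS,
    MRLProfile,
    RISK_LEVEL_LEGEND,
    RiskAssessment,
    RiskLevel,
    classify,
    compute_mrl,
)

__all__ = [
    "StratumResult",
    "AssessmentReport",
    "assess",
    "render_report",
    "report_from_json",
    "file_digest",
]

SCHEMA_VERSION = "1"

_PARAM_LABELS = {
    "n_detected_ads": "Number of detected ADs",
    "surface_spread": "Surface contamination spread",
    "pct_surfaces": "Percentage of contaminated surfaces",
    "glove_spread": "Glove contamination spread",
    "pct_gloves": "Percentage of contaminated gloves",
}


@dataclass(frozen=True)
class StratumResult:
    """Outcome for one (group, preparation mode) cell: either a full
    assessment or an explicit skip with its reason."""

    group: ADGroup
    prep_mode: PrepMode
    status: str  # "assessed" | "skipped"
    summary: Optional[MonitoringSummary] = None
    mrl_profile: Optional[MRLProfile] = None
    arl: Optional[int] = None
    assessment: Optional[RiskAssessment] = None
    skip_reason: Optional[str] = None


@dataclass(frozen=True)
class AssessmentReport:
    entries: tuple[StratumResult, ...]
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    version: str = __version__
    schema_version: str = SCHEMA_VERSION

    def entry(self, group: ADGroup, mode: PrepMode) -> StratumResult:
        for e in self.entries:
            if e.group is group and e.prep_mode is mode:
                return e
        raise KeyError((group, mode))


def file_digest(path: Union[str, Path]) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _resolved_config_dict(config: AssessConfig) -> dict:
    """Echo the fully resolved configuration for auditability."""
    matrix = {}
    for (group, mode, fm), score in config.matrix.scores.items():
        matrix.setdefault(group.value, {}).setdefault(mode.value, {})[fm.value] = score
    bins = {
        key: {
            "edges": list(getattr(config.bins, key).edges),
            "inclusive": list(getattr(config.bins, key).inclusive),
        }
        for key in ("n_detected", "surface_spread", "pct_surfaces", "pct_gloves")
    }
    agv = {
        "default": vars(config.agv.default).copy(),
        "per_drug": {d: vars(v).copy() for d, v in config.agv.per_drug.items()},
    }
    return {
        "rpn_matrix": matrix,
        "bins": bins,
        "agv": agv,
        "spread_stat": config.spread_stat,
        "risk_level_legend": {lv.value: text for lv, text in RISK_LEVEL_LEGEND.items()},
    }


def assess(
    catalog: Sequence[DrugRecord],
    campaign: MonitoringCampaign,
    config: AssessConfig,
    input_digests: Optional[dict] = None,
) -> AssessmentReport:
    """Assess every (group, mode) stratum of a campaign.

    Empty strata become ``status="skipped"`` entries carrying the reason;
    any other stratum failure propagates with stratum context attached.
    """
    arls = arl_profile(config.matrix)
    entries: list[StratumResult] = []
    for group in ADGroup:
        for mode in PrepMode:
            try:
                summary = summarize_group(
                    campaign, group, mode, catalog, spread_stat=config.spread_stat
                )
            except EmptyStratumError as exc:
                entries.append(
                    StratumResult(
                        group=group,
                        prep_mode=mode,
                        status="skipped",
                        skip_reason=str(exc),
                    )
                )
                continue
            except AdriskError as exc:
                raise type(exc)(
                    f"stratum ({group.value}, {mode.value}): {exc}"
                ) from exc
            profile = compute_mrl(summary, config.bins, config.agv)
            arl = arls[(group, mode)]
            verdict = classify(profile.mrl, arl, group=group, prep_mode=mode)
            entries.append(
                StratumResult(
                    group=group,
                    prep_mode=mode,
                    status="assessed",
                    summary=summary,
                    mrl_profile=profile,
                    arl=arl,
                    assessment=verdict,
                )
            )
    return AssessmentReport(
        entries=tuple(entries),
        config=_resolved_config_dict(config),
        input_digests=dict(input_digests or {}),
    )


# --- serialisation ----------------------------------------------------


def _summary_to_dict(s: MonitoringSummary) -> dict:
    return {
        "group": s.group.value,
        "prep_mode": s.prep_mode.value,
        "n_detected_ads": s.n_detected_ads,
        "surface_spread": s.surface_spread,
        "pct_surfaces_positive": s.pct_surfaces_positive,
        "glove_spread": s.glove_spread,
        "pct_gloves_positive": s.pct_gloves_positive,
        "n_surface_records": s.n_surface_records,
        "n_glove_records": s.n_glove_records,
        "surface_spread_analyte": s.surface_spread_analyte,
        "glove_spread_analyte": s.glove_spread_analyte,
    }


def _summary_from_dict(d: dict) -> MonitoringSummary:
    d = dict(d)
    d["group"] = ADGroup(d["group"])
    d["prep_mode"] = PrepMode(d["prep_mode"])
    return MonitoringSummary(**d)


def _entry_to_dict(e: StratumResult) -> dict:
    out: dict = {
        "group": e.group.value,
        "prep_mode": e.prep_mode.value,
        "status": e.status,
    }
    if e.status == "skipped":
        out["skip_reason"] = e.skip_reason
        return out
    assert e.summary and e.mrl_profile and e.assessment
    out["summary"] = _summary_to_dict(e.summary)
    out["rpns"] = dict(e.mrl_profile.rpns)
    out["mrl"] = e.mrl_profile.mrl
    out["arl"] = e.arl
    out["delta"] = e.assessment.delta
    out["level"] = e.assessment.level.value
    return out


def _entry_from_dict(d: dict) -> StratumResult:
    group = ADGroup(d["group"])
    mode = PrepMode(d["prep_mode"])
    if d["status"] == "skipped":
        return StratumResult(
            group=group,
            prep_mode=mode,
            status="skipped",
            skip_reason=d.get("skip_reason"),
        )
    summary = _summary_from_dict(d["summary"])
    profile = MRLProfile(group=group, prep_mode=mode, rpns=d["rpns"], mrl=d["mrl"])
    verdict = RiskAssessment(
        mrl=d["mrl"],
        arl=d["arl"],
        delta=d["delta"],
        level=RiskLevel(d["level"]),
        group=group,
        prep_mode=mode,
    )
    return StratumResult(
        group=group,
        prep_mode=mode,
        status="assessed",
        summary=summary,
        mrl_profile=profile,
        arl=d["arl"],
        assessment=verdict,
    )


def report_to_dict(report: AssessmentReport) -> dict:
    return {
        "schema_version": report.schema_version,
        "version": report.version,
        "input_digests": dict(report.input_digests),
        "config": report.config,
        "entries": [_entry_to_dict(e) for e in report.entries],
    }


def report_from_json(text: str) -> AssessmentReport:
    d = json.loads(text)
    return AssessmentReport(
        entries=tuple(_entry_from_dict(e) for e in d["entries"]),
        config=d.get("config", {}),
        input_digests=d.get("input_digests", {}),
        version=d.get("version", __version__),
        schema_version=d.get("schema_version", SCHEMA_VERSION),
    )


def _render_markdown(report: AssessmentReport) -> str:
    lines: list[str] = ["# AD preparation risk assessment", ""]
    for mode in PrepMode:
        entries = [e for e in report.entries if e.prep_mode is mode]
        lines.append(f"## {mode.value.capitalize()} preparation")
        lines.append("")
        header = ["Parameter (RPN)"] + [e.group.value for e in entries]
        lines.append("| " + " | ".join(header) + " |")
        lines.append("|" + "---|" * len(header))

        def row(label: str, cells: list[str]) -> str:
            return "| " + " | ".join([label] + cells) + " |"

        for param in PARAMETERS:
            cells = [
                str(e.mrl_profile.rpns[param]) if e.status == "assessed" else "skipped"
                for e in entries
            ]
            lines.append(row(_PARAM_LABELS[param], cells))
        lines.append(
            row(
                "Measured risk level (MRL)",
                [
                    str(e.mrl_profile.mrl) if e.status == "assessed" else "skipped"
                    for e in entries
                ],
            )
        )
        lines.append(
            row(
                "Acceptable risk level (ARL)",
                [str(e.arl) if e.status == "assessed" else "skipped" for e in entries],
            )
        )
        lines.append(
            row(
                "Assessed risk",
                [
                    e.assessment.level.value if e.status == "assessed" else "skipped"
                    for e in entries
                ],
            )
        )
        lines.append("")
    lines.append("### Legend")
    lines.append("")
    for level, text in RISK_LEVEL_LEGEND.items():
        lines.append(f"- `{level.value}`: {text}")
    lines.append("")
    return "\n".join(lines)


def render_report(report: AssessmentReport, format: str = "json") -> str:
    """Render a report as schema-versioned JSON or as markdown tables."""
    if format == "json":
        return json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n"
    if format == "markdown":
        return _render_markdown(report)
    raise ValueError(f"unknown report format {format!r}; use 'json' or 'markdown'")
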