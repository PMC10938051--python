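"""Aggregate findings into deterministic text or JSON reports."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import __version__
from .checks import CheckConfig, Finding, SEVERITY_ORDER
from .tree_model import DatasetTree, TreeStats, tree_stats

#: shape of the JSON report; bump schema_version on breaking changes
REPORT_SCHEMA_VERSION = 1
REPORT_SCHEMA = {
    "schema_version": "int",
    "tool": {"name": "str", "version": "str"},
    "config": "mapping of CheckConfig fields",
    "stats": "mapping of TreeStats fields",
    "summary": {
        "total": "int",
        "by_check": "check_id -> count",
        "by_severity": "severity -> count",
    },
    "findings": [
        {
            "check_id": "str",
            "recommendation": "str",
            "severity": "info|warning|error",
            "paths": ["str"],
            "message": "str",
            "suggestion": "mapping or null",
        }
    ],
}


@dataclass
class Report:
    config: CheckConfig
    stats: TreeStats
    findings: list[Finding]
    tool_name: str = "arklint"
    tool_version: str = __version__

    @property
    def summary(self) -> dict:
        by_check: dict[str, int] = {}
        by_severity: dict[str, int] = {}
        for f in self.findings:
            by_check[f.check_id] = by_check.get(f.check_id, 0) + 1
            by_severity[f.severity] = by_severity.get(f.severity, 0) + 1
        return {
            "total": len(self.findings),
            "by_check": dict(sorted(by_check.items())),
            "by_severity": dict(sorted(by_severity.items())),
        }

    def max_severity(self) -> str | None:
        if not self.findings:
            return None
        return max((f.severity for f in self.findings), key=SEVERITY_ORDER.get)


def build_report(
    tree: DatasetTree, config: CheckConfig, findings: list[Finding]
) -> Report:
    return Report(config=config, stats=tree_stats(tree), findings=findings)


def render_report(report: Report, format: str = "text") -> str:
    """Render a report as grouped plain text or as schema-stable JSON.

    Output is byte-deterministic for a given report: findings come
    pre-sorted from the engine and summaries are emitted in sorted order.
    """
    if format == "json":
        return json.dumps(
            {
                "schema_version": REPORT_SCHEMA_VERSION,
                "tool": {"name": report.tool_name, "version": report.tool_version},
                "config": report.config.to_dict(),
                "stats": report.stats.as_dict(),
                "summary": report.summary,
                "findings": [f.as_dict() for f in report.findings],
            },
            indent=2,
            sort_keys=False,
        )
    if format != "text":
        raise ValueError(f"unknown report format {format!r}; use 'text' or 'json'")

    lines: list[str] = []
    stats = report.stats
    lines.append(
        f"{report.tool_name} {report.tool_version} — "
        f"{stats.n_files} files, {stats.n_folders} folders, "
        f"max depth {stats.max_depth}, longest path {stats.max_path_length} chars"
    )
    summary = report.summary
    if summary["total"] == 0:
        lines.append("0 issues found.")
        return "\n".join(lines) + "\n"
    sev = ", ".join(f"{n} {s}" for s, n in sorted(summary["by_severity"].items()))
    lines.append(f"{summary['total']} issues found ({sev}).")
    by_check: dict[str, list[Finding]] = {}
    for f in report.findings:
        by_check.setdefault(f.check_id, []).append(f)
    for check_id in sorted(by_check):
        group = by_check[check_id]
        rec = group[0].recommendation
        lines.append("")
        lines.append(f"[{check_id}] ({rec}) — {len(group)} finding(s)")
        for f in group:
            lines.append(f"  {f.severity}: {f.message}")
            for p in f.paths:
                lines.append(f"    {p}")
            if f.suggestion:
                lines.append(f"    suggestion: {json.dumps(f.suggestion, sort_keys=True)}")
    return "\n".join(lines) + "\n"
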