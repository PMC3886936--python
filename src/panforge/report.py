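"""Machine- and human-readable summaries of a pipeline run.

All reported percentages are rounded half away from zero to one decimal,
the convention used for the headline counts this pipeline reproduces (e.g.
a presence histogram {1:230, 2:2312, 3:1515, 4:1551, 5:1653, 6:1731} totals
8,992 groups of which 7,031 = 78.2% are mosaic).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

SCHEMA_VERSION = "1.0"


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (not banker's rounding)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def pct(part: float, whole: float, ndigits: int = 1) -> float:
    """Percentage of part in whole, rounded half away from zero."""
    if whole == 0:
        return 0.0
    return round_half_away(100.0 * part / whole, ndigits)


def presence_summary(histogram: dict[int, int]) -> dict[str, Any]:
    """Totals and mosaic tally of a strain-presence histogram.

    A mosaic group contains genes from >= 2 but not all strains.
    """
    n_strains = max(histogram) if histogram else 0
    total = sum(histogram.values())
    mosaic = sum(v for k, v in histogram.items() if 2 <= k < n_strains)
    return {
        "histogram": {str(k): int(v) for k, v in sorted(histogram.items())},
        "total": total,
        "mosaic": mosaic,
        "mosaic_pct": pct(mosaic, total),
    }


def dose_table_totals(per_strain_counts: dict[str, dict[str, int]]) -> dict[str, int]:
    """Per-category and overall gene-dose totals across strains.

    Input: strain -> category -> gene count (e.g. DGAT type per strain).
    """
    totals: dict[str, int] = {}
    for counts in per_strain_counts.values():
        for cat, k in counts.items():
            totals[cat] = totals.get(cat, 0) + k
    totals["total"] = sum(v for k, v in totals.items() if k != "total")
    return totals


def summarize_run(
    presence_histogram: dict[int, int] | None = None,
    pan_core: dict[str, int] | None = None,
    top_paralog_sizes: dict[str, list[int]] | None = None,
    hgt_calls: dict[str, str] | None = None,
    origin_calls: dict[str, str] | None = None,
    n_genes_total: int | None = None,
    marker_passes: list[str] | None = None,
    enrichment_flags: list[dict] | None = None,
) -> dict[str, Any]:
    """Assemble the run summary; missing stages leave explicit gaps."""
    summary: dict[str, Any] = {"schema_version": SCHEMA_VERSION, "missing_stages": []}

    if presence_histogram is not None:
        summary["presence"] = presence_summary(presence_histogram)
    else:
        summary["missing_stages"].append("presence")

    if pan_core is not None:
        total = sum(pan_core.values())
        summary["pan_core"] = {
            "counts": dict(pan_core),
            "total": total,
            "pct": {k: pct(v, total) for k, v in pan_core.items()},
        }
    else:
        summary["missing_stages"].append("pan_core")

    if top_paralog_sizes is not None:
        summary["paralogs"] = {s: list(v) for s, v in top_paralog_sizes.items()}
    else:
        summary["missing_stages"].append("paralogs")

    for key, calls in (("hgt", hgt_calls), ("origin", origin_calls)):
        if calls is None:
            summary["missing_stages"].append(key)
            continue
        tally: dict[str, int] = {}
        for call in calls.values():
            tally[call] = tally.get(call, 0) + 1
        block: dict[str, Any] = {"tally": tally, "n_families": len(calls)}
        if n_genes_total:
            positive = sum(
                v for k, v in tally.items() if k not in {"vertical", "unresolved"}
            )
            block["positive_pct_of_genes"] = pct(positive, n_genes_total)
        summary[key] = block

    summary["markers"] = {"pass_list": marker_passes or [], "n_pass": len(marker_passes or [])}
    summary["enrichment"] = {
        "flags": enrichment_flags or [],
        "n_flagged": len(enrichment_flags or []),
    }
    return summary


def write_summary(summary: dict, json_path: str | Path, text_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    if text_path is None:
        return
    lines = [f"panforge run summary (schema {summary.get('schema_version')})"]
    if "presence" in summary:
        p = summary["presence"]
        lines.append(
            f"homologous groups: {p['total']} total; mosaic {p['mosaic']}"
            f" ({p['mosaic_pct']}%)"
        )
    if "pan_core" in summary:
        c = summary["pan_core"]["counts"]
        lines.append(
            "pan-core classes: "
            + ", ".join(f"{k}={v}" for k, v in sorted(c.items()))
        )
    if "hgt" in summary:
        lines.append(f"HGT calls: {summary['hgt']['tally']}")
    if "origin" in summary:
        lines.append(f"origin calls: {summary['origin']['tally']}")
    lines.append(f"markers passing: {summary['markers']['n_pass']}")
    lines.append(f"enrichment rows flagged: {summary['enrichment']['n_flagged']}")
    if summary.get("missing_stages"):
        lines.append("missing stages: " + ", ".join(summary["missing_stages"]))
    Path(text_path).write_text("\n".join(lines) + "\n")
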