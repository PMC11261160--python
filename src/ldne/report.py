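"""Human-readable and machine-readable report writers.

Estimate tables use the ``point (lower-upper)`` convention with ``inf``
for indeterminate bounds; TSV cells are rounded to the nearest integer,
JSON keeps full precision.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

from .adjust import AdjustedEstimate


def fmt_value(v: float) -> str:
    return "inf" if math.isinf(v) else str(int(round(v)))


def fmt_cell(point: float, lower: float, upper: float) -> str:
    return f"{fmt_value(point)} ({fmt_value(lower)}-{fmt_value(upper)})"


def estimate_table(
    rows: list[tuple[str, int, AdjustedEstimate]]
) -> str:
    """TSV table of adjustment chains, one row per sample.

    Cohort rows get columns raw/adj1/adj2/ne; mixed rows raw/adj1/adj2.
    """
    any_cohort = any(adj.kind == "cohort" for _, _, adj in rows)
    header = ["sample", "n", "raw", "adj1", "adj2"] + (["ne"] if any_cohort else [])
    lines = ["\t".join(header)]
    for label, n, adj in rows:
        cells = [label, str(n)]
        for stage in ("raw", "adj1", "adj2"):
            cells.append(fmt_cell(*adj.stage(stage)))
        if any_cohort:
            cells.append(fmt_cell(*adj.stage("ne")) if "ne" in adj.values else "")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def write_estimate_report(
    rows: list[tuple[str, int, AdjustedEstimate]],
    out_dir: str | Path,
    config: dict[str, Any] | None = None,
) -> tuple[Path, Path]:
    """Write estimates.tsv and estimates.json; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = out / "estimates.tsv"
    tsv.write_text(estimate_table(rows))
    payload = {
        "config": config or {},
        "samples": {
            label: {"n": n, **adj.to_dict(), "raw_detail": adj.raw.to_dict()}
            for label, n, adj in rows
        },
    }
    js = out / "estimates.json"
    js.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return tsv, js
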