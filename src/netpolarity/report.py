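"""Rendering of analysis reports: machine-readable TSV and summary tables.

Two styles:

* ``long-tsv`` — one row per result at full precision (``repr`` of the
  float), re-parseable without loss.
* ``summary-tables`` — per-analysis summary tables with p-values rounded in
  the conventional style (three decimals at or above 0.001, otherwise
  scientific notation with three significant digits) and significance
  marks ``*``, ``**``, ``***`` at 0.05, 0.01, 0.001.

Rendering is pure: the same report always produces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .pipeline import AnalysisReport, PairedComparisonResult
from .stats import TestResult

__all__ = ["format_p", "significance_marks", "render_long_tsv",
           "render_summary_tables", "render_report"]


def format_p(p: float) -> str:
    """Round a p-value in the conventional reporting style."""
    if p != p:  # NaN
        return ""
    if p >= 0.001:
        return f"{p:.3f}"
    mantissa, exp = f"{p:.2e}".split("e")
    return f"{mantissa}e{int(exp):+03d}"


def significance_marks(p: float) -> str:
    if p != p:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def render_long_tsv(report: AnalysisReport, path: str | Path) -> None:
    """Write every entry as one full-precision TSV row."""
    if not report.entries:
        raise ValueError("cannot render an empty report")
    frame = report.to_frame()
    frame.to_csv(path, sep="\t", index=False)


def _styled_p(p: float | None) -> str:
    if p is None:
        return ""
    return format_p(p) + significance_marks(p)


def render_summary_tables(report: AnalysisReport, outdir: str | Path) -> list[Path]:
    """Write one summary table per analysis kind under ``outdir``."""
    if not report.entries:
        raise ValueError("cannot render an empty report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    groups: dict[str, list[dict]] = {}
    for e in report.entries:
        row: dict = {"variable": e.variable, "subset": e.subset,
                     "control": e.control}
        r = e.result
        if isinstance(r, PairedComparisonResult):
            row.update(n=r.n_informative, greater=r.n_greater,
                       less=r.n_less, ties=r.n_tie, P=_styled_p(r.p_value))
        elif isinstance(r, TestResult):
            row.update(n=str(r.n), statistic=f"{r.statistic:.3f}",
                       P=_styled_p(r.p_value))
            for key in ("median_a", "median_b", "mean_a", "mean_b"):
                if key in r.extras:
                    row[key] = f"{r.extras[key]:.4g}"
        else:
            row["P"] = ""
        if e.note:
            row["note"] = e.note
        groups.setdefault(e.analysis, []).append(row)
    written = []
    for analysis, rows in groups.items():
        path = outdir / f"{analysis}.tsv"
        pd.DataFrame(rows).fillna("").to_csv(path, sep="\t", index=False)
        written.append(path)
    return written


def render_report(report: AnalysisReport, outdir: str | Path) -> dict[str, object]:
    """Write both styles under ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    long_path = outdir / "report_long.tsv"
    render_long_tsv(report, long_path)
    tables = render_summary_tables(report, outdir / "tables")
    return {"long": long_path, "tables": tables}
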