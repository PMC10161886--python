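"""End-of-run HTML report.

A summary page with one row per sample (five status glyphs plus three
thumbnails: the centered-sample image and the 2D and line-scan heat-map
overlays) and a single-page detail sheet per sample with acquisition
parameters and decision provenance.  Output is deterministic: byte-identical
HTML for identical journal content.
"""
from __future__ import annotations

import html
from pathlib import Path
from typing import Dict, List

from .orchestrator import ExecutionRecord, build_stack, replay_journal

GLYPHS = {
    "success": "&#10004;",      # check mark
    "failed": "&#10008;",       # cross
    "skipped": "&#128056;",     # frog
    "in_progress": "&#127939;", # runner
    "unknown": "&#10134;",      # minus
}

_THUMBS = [("alc_image", "ALC sample"), ("grid_2d", "2D grid"), ("grid_line", "Line scan")]

_STYLE = """
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; }
td, th { border: 1px solid #999; padding: 4px 8px; text-align: center; }
img.thumb { height: 72px; }
img.large { max-width: 480px; }
.placeholder { color: #999; font-style: italic; }
"""


def _thumb(record: ExecutionRecord, kind: str, cls: str = "thumb") -> str:
    path = record.artifacts.get(kind)
    if path is None:
        return '<span class="placeholder">not available</span>'
    return f'<img class="{cls}" src="{html.escape(path)}" alt="{kind}">'


def _status_cell(record: ExecutionRecord, step: str) -> str:
    st = record.steps.get(step)
    status = st.status if st is not None else "unknown"
    title = html.escape(st.message) if st is not None and st.message else status
    return f'<td title="{title}">{GLYPHS.get(status, GLYPHS["unknown"])}</td>'


def _summary_page(records: List[ExecutionRecord], steps: List[str]) -> str:
    rows = []
    for rec in records:
        cells = "".join(_status_cell(rec, s) for s in steps)
        thumbs = "".join(f"<td>{_thumb(rec, kind)}</td>" for kind, _ in _THUMBS)
        note = ""
        daq = rec.steps.get("daq")
        if daq is not None and daq.status == "skipped":
            note = " (skipped: no spots above threshold)"
        rows.append(
            f'<tr><td><a href="sample_{rec.row}.html">{html.escape(rec.sample)}</a>'
            f"{note}</td>{cells}{thumbs}</tr>"
        )
    head = "".join(f"<th>{s}</th>" for s in steps)
    thumb_head = "".join(f"<th>{label}</th>" for _, label in _THUMBS)
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>Automated collection report</title><style>{_STYLE}</style></head><body>"
        f"<h1>Automated collection report</h1>"
        f"<p>{len(records)} sample(s)</p>"
        f"<table><tr><th>Sample</th>{head}{thumb_head}</tr>"
        + "".join(rows)
        + "</table></body></html>"
    )


def _detail_page(rec: ExecutionRecord) -> str:
    steps = build_stack(rec.method)
    status_rows = "".join(
        f"<tr><td>{s}</td>{_status_cell(rec, s)}"
        f"<td>{html.escape(rec.steps.get(s).message) if rec.steps.get(s) else ''}</td></tr>"
        for s in steps
    )
    manifest_rows = ""
    for m in rec.manifests:
        manifest_rows += (
            f"<tr><td>{html.escape(str(m.get('folder')))}</td>"
            f"<td>{m.get('exposure_time_s')}</td><td>{m.get('oscillation_deg')}</td>"
            f"<td>{m.get('total_range_deg')}</td><td>{m.get('chi')}</td>"
            f"<td>{m.get('phi')}</td></tr>"
        )
    if not manifest_rows:
        manifest_rows = '<tr><td colspan="6" class="placeholder">no datasets collected</td></tr>'
    decision = ""
    if rec.decision is not None:
        decision = (
            f"<p>Grid decision: outcome <b>{html.escape(str(rec.decision.get('outcome')))}</b>, "
            f"best 2D box {rec.decision.get('best_2d_index')}, "
            f"best line box {rec.decision.get('best_line_index')}, "
            f"peak counts {rec.decision.get('peak_2d')} / {rec.decision.get('peak_line')}</p>"
        )
    thumbs = "".join(
        f"<h3>{label}</h3>{_thumb(rec, kind, cls='large')}" for kind, label in _THUMBS
    )
    return (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{html.escape(rec.sample)}</title><style>{_STYLE}</style></head><body>"
        f"<h1>{html.escape(rec.sample)} (row {rec.row + 1}, {rec.method})</h1>"
        f"<table><tr><th>Step</th><th>Status</th><th>Message</th></tr>{status_rows}</table>"
        f"{decision}"
        f"<h2>Datasets</h2><table><tr><th>Folder</th><th>Exposure (s)</th>"
        f"<th>Oscillation (&deg;)</th><th>Range (&deg;)</th><th>&chi; (&deg;)</th>"
        f"<th>&phi; (&deg;)</th></tr>{manifest_rows}</table>"
        f"{thumbs}"
        '<p><a href="report.html">back to summary</a></p>'
        "</body></html>"
    )


def build_report(records: List[ExecutionRecord], out_dir) -> Dict[str, str]:
    """Write ``report.html`` plus one ``sample_<row>.html`` per record into
    ``out_dir`` (assets are referenced relatively).  Returns the page map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = sorted(records, key=lambda r: r.row)
    steps = [s for s in ("safety_check", "mount", "optical_center", "diff_center", "daq")]
    pages = {"report.html": _summary_page(records, steps)}
    for rec in records:
        pages[f"sample_{rec.row}.html"] = _detail_page(rec)
    for name, content in pages.items():
        with open(out / name, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(content)
    return pages


def build_report_from_journal(journal_path, out_dir) -> Dict[str, str]:
    records, _ = replay_journal(journal_path)
    return build_report(records, out_dir)
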