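"""Static cohort report assembly (JSON + self-contained HTML).

Aggregates the outputs of the pipeline stages — cohort summary, per-region
density profiles, distribution tests, junction-structure fractions,
reciprocal-balance counts, motif-enrichment table — into one JSON document
plus a dependency-free HTML page with inline-SVG histograms and a
junction-structure pie.  Every number in the report is copied from a stage
output; nothing is recomputed here.  The JSON is byte-deterministic for
identical inputs; sections whose stage output is missing are marked absent
rather than failing the build.
"""

from __future__ import annotations

import hashlib
import html
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__

__all__ = ["build_report", "ReportSchemaError"]

SECTIONS = (
    "cohort_summary",
    "density_profiles",
    "test_results",
    "junction_fractions",
    "reciprocal_counts",
    "enrichment",
)


class ReportSchemaError(ValueError):
    """A stage output does not have the expected structure."""


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "to_dict"):  # DataFrame
        return _jsonable(obj.to_dict(orient="list"))
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _validate(name: str, payload) -> None:
    requirements = {
        "density_profiles": (dict, "mapping of profile name -> binned counts"),
        "test_results": (dict, "mapping of test name -> result"),
        "junction_fractions": (dict, "mapping mechanism -> fraction"),
        "reciprocal_counts": (dict, "mapping count name -> value"),
    }
    if name in requirements:
        typ, desc = requirements[name]
        if not isinstance(payload, typ):
            raise ReportSchemaError(f"section {name!r}: expected {desc}")


def _svg_hist(profile: dict, title: str) -> str:
    fig, ax = plt.subplots(figsize=(5, 2.2))
    starts = profile.get("bin_start", [])
    counts = profile.get("count", [])
    if starts and counts:
        width = (profile["bin_end"][0] - profile["bin_start"][0]) * 0.9
        ax.bar(starts, counts, width=width, align="edge", color="#4878b0")
    ax.set_title(title, fontsize=8)
    ax.tick_params(labelsize=6)
    import io

    buf = io.StringIO()
    with plt.rc_context({"svg.hashsalt": "phbreak"}):
        fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def _svg_pie(fractions: dict) -> str:
    fig, ax = plt.subplots(figsize=(3, 3))
    labels = sorted(fractions)
    ax.pie(
        [fractions[k] for k in labels],
        labels=[f"{k} ({100 * fractions[k]:.1f}%)" for k in labels],
        textprops={"fontsize": 7},
    )
    ax.set_title("junction primary structure", fontsize=8)
    import io

    buf = io.StringIO()
    with plt.rc_context({"svg.hashsalt": "phbreak"}):
        fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def build_report(stage_outputs: dict, out_dir, seed: int | None = None) -> dict[str, str]:
    """Assemble stage outputs into ``report.json`` and ``report.html``.

    ``stage_outputs`` maps section names (see ``SECTIONS``) to in-memory
    stage results (dicts, dataclasses or DataFrames) or to paths of JSON
    files written by the CLI stages.  Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc: dict = {"sections": {}, "absent_sections": []}
    for name in SECTIONS:
        payload = stage_outputs.get(name)
        if payload is None:
            doc["absent_sections"].append(name)
            continue
        if isinstance(payload, (str, Path)):
            with open(payload) as handle:
                payload = json.load(handle)
        payload = _jsonable(payload)
        _validate(name, payload)
        doc["sections"][name] = payload
    body = json.dumps(doc["sections"], sort_keys=True)
    doc["provenance"] = {
        "package": "phbreak",
        "version": __version__,
        "seed": seed,
        "content_sha256": hashlib.sha256(body.encode()).hexdigest(),
    }
    json_path = out / "report.json"
    json_path.write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>phbreak cohort report</title>",
        "<style>body{font-family:sans-serif;max-width:60em;margin:auto}"
        "table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:2px 8px;font-size:13px}</style></head><body>",
        "<h1>Breakpoint cohort report</h1>",
        f"<p>phbreak {html.escape(__version__)}; seed "
        f"{html.escape(str(seed))}; content sha256 "
        f"{doc['provenance']['content_sha256'][:16]}…</p>",
    ]
    for name in SECTIONS:
        parts.append(f"<h2>{html.escape(name.replace('_', ' '))}</h2>")
        if name not in doc["sections"]:
            parts.append("<p><em>section absent (stage output not provided)</em></p>")
            continue
        payload = doc["sections"][name]
        if name == "density_profiles":
            for pname, profile in sorted(payload.items()):
                parts.append(_svg_hist(profile, pname))
        elif name == "junction_fractions" and isinstance(payload, dict):
            fracs = {k: v for k, v in payload.items() if isinstance(v, (int, float))}
            if fracs:
                parts.append(_svg_pie(fracs))
            parts.append(_html_table(payload))
        else:
            parts.append(_html_table(payload))
    parts.append("</body></html>")
    html_path = out / "report.html"
    html_path.write_text("\n".join(parts))
    return {"json": str(json_path), "html": str(html_path)}


def _html_table(payload) -> str:
    if not isinstance(payload, dict):
        return f"<pre>{html.escape(json.dumps(payload, indent=2))}</pre>"
    rows = "".join(
        f"<tr><th>{html.escape(str(k))}</th>"
        f"<td>{html.escape(json.dumps(_jsonable(v), sort_keys=True))}</td></tr>"
        for k, v in sorted(payload.items())
    )
    return f"<table>{rows}</table>"
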