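"""Locus diagrams (SVG), standalone HTML reports, and plain-text summaries.

Each protein is drawn as a rectangle whose width is strictly proportional to
its residue count, filled with its role color.  The protein label underneath
is green when the assignment's BMC type equals the called modal type, red
when it is typed otherwise, and grey when untyped.  The cascading layout
wraps rows after a configured number of genes (default 10); the linear
layout draws a single row.  Rendering is deterministic.
"""

from __future__ import annotations

import urllib.parse
import xml.etree.ElementTree as ET
from typing import Sequence

from .annotate import BestAssignment
from .errors import BmcTyperError, InvalidSequenceError
from .fingerprint import TypeAssignment, closest_table, type_call_table
from .roles import ROLE_COLORS

#: pixels per residue
SCALE = 0.4
BAR_HEIGHT = 16
ROW_HEIGHT = 58
GAP = 5
MARGIN = 10
DEFAULT_ROW_WIDTH = 10

SWISSMODEL_URL = "https://swissmodel.expasy.org/interactive?"


def swissmodel_link(seq: str) -> str:
    """Deterministic homology-modelling submission URL for one sequence."""
    if not seq:
        raise InvalidSequenceError("cannot build a SWISS-MODEL link for an empty sequence")
    return SWISSMODEL_URL + urllib.parse.urlencode({"seq": seq})


def _label_color(assignment: BestAssignment, type_call: TypeAssignment) -> str:
    if assignment.bmc_type is None:
        return "grey"
    if type_call.bmc_type is not None and assignment.bmc_type == type_call.bmc_type:
        return "green"
    if type_call.bmc_type is None:
        # no modal type called: typed assignments cannot match it
        return "red"
    return "red"


def render_locus_svg(records: Sequence, assignments: Sequence[BestAssignment],
                     type_call: TypeAssignment, layout: str = "cascading",
                     row_width: int = DEFAULT_ROW_WIDTH) -> str:
    """Render one locus as an SVG document (one bar per protein)."""
    if len(records) != len(assignments):
        raise BmcTyperError(
            f"{len(records)} records but {len(assignments)} assignments")
    if layout not in ("linear", "cascading"):
        raise BmcTyperError(f"unknown layout {layout!r}")
    per_row = row_width if layout == "cascading" else max(len(records), 1)

    rows: list[list[int]] = [list(range(i, min(i + per_row, len(records))))
                             for i in range(0, len(records), per_row)]
    width = MARGIN * 2 + max(
        (sum(len(records[i].seq) * SCALE + GAP for i in row) for row in rows),
        default=0)
    height = MARGIN * 2 + ROW_HEIGHT * len(rows)
    svg = ET.Element("svg", xmlns="http://www.w3.org/2000/svg",
                     version="1.1", width=f"{width:.0f}", height=f"{height:.0f}")
    for r, row in enumerate(rows):
        x = float(MARGIN)
        y = MARGIN + r * ROW_HEIGHT
        for i in row:
            rec, a = records[i], assignments[i]
            w = len(rec.seq) * SCALE
            ET.SubElement(svg, "rect", x=f"{x:.2f}", y=f"{y:.2f}",
                          width=f"{w:.2f}", height=str(BAR_HEIGHT),
                          fill=ROLE_COLORS[a.role], stroke="black",
                          **{"stroke-width": "0.5"})
            t1 = ET.SubElement(svg, "text", x=f"{x:.2f}", y=f"{y + BAR_HEIGHT + 12:.2f}",
                               fill=_label_color(a, type_call),
                               **{"font-size": "9", "font-family": "sans-serif"})
            t1.text = rec.id
            t2 = ET.SubElement(svg, "text", x=f"{x:.2f}", y=f"{y + BAR_HEIGHT + 24:.2f}",
                               fill=_label_color(a, type_call),
                               **{"font-size": "9", "font-family": "sans-serif"})
            t2.text = a.profile_name or "-"
            x += w + GAP
    return ET.tostring(svg, encoding="unicode")


def render_locus_html(records: Sequence, assignments: Sequence[BestAssignment],
                      type_call: TypeAssignment,
                      closest: Sequence | None = None,
                      layout: str = "cascading",
                      row_width: int = DEFAULT_ROW_WIDTH) -> str:
    """Self-contained HTML wrapper: inline SVG diagram plus result tables."""
    svg = render_locus_svg(records, assignments, type_call, layout, row_width)
    rows = []
    for rec, a in zip(records, assignments):
        rows.append(
            "<tr><td>{}</td><td>{}</td><td>{}</td><td>{}</td><td>{}</td>"
            "<td><a href=\"{}\">model</a></td></tr>".format(
                rec.id, a.profile_name or "-", a.role.value, a.bmc_type or "-",
                "" if a.bitscore is None else f"{a.bitscore:.1f}",
                swissmodel_link(rec.seq)))
    closest_html = ""
    if closest:
        items = "".join(f"<li>{tid}: {s.value:.4f} (inventory {s.inventory_component:.4f}, "
                        f"order {s.order_component:.4f})</li>" for tid, s in closest)
        closest_html = f"<h2>Closest BMC types</h2><ol>{items}</ol>"
    vote = ", ".join(f"{t}: {n}" for t, n in type_call.vote_table.items()) or "none"
    sig = (f"<p>Signature-enzyme types: {', '.join(type_call.signature_types)}</p>"
           if type_call.signature_types else "")
    return f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>BMC locus report</title></head>
<body>
<h1>BMC locus analysis</h1>
<p>Type call: <b>{type_call.bmc_type or type_call.status}</b>
 (status {type_call.status}, confidence {type_call.confidence:.3f})</p>
<p>Votes: {vote}</p>
{sig}
{svg}
<h2>Assignments</h2>
<table border="1">
<tr><th>protein</th><th>profile</th><th>role</th><th>type</th><th>bits</th><th>link</th></tr>
{''.join(rows)}
</table>
{closest_html}
</body></html>
"""


def text_summary(records: Sequence, assignments: Sequence[BestAssignment],
                 type_call: TypeAssignment,
                 closest: Sequence | None = None,
                 shell_summary: dict | None = None) -> str:
    """Plain-text analysis summary: type call, assignments, closest types,
    shell-protein counts."""
    out = ["== BMC type assignment =="]
    out.append(type_call_table(type_call).rstrip())
    out.append("")
    out.append("== Locus assignments ==")
    for rec, a in zip(records, assignments):
        bits = "" if a.bitscore is None else f" ({a.bitscore:.1f} bits)"
        out.append(f"{rec.id}\t{a.profile_name or '-'}{bits}")
    if closest is not None:
        out.append("")
        out.append("== Closest BMC types ==")
        out.append(closest_table(closest).rstrip())
    if shell_summary is not None:
        out.append("")
        out.append("== Shell protein summary ==")
        for role, n in shell_summary.items():
            out.append(f"{role.value}\t{n}")
    return "\n".join(out) + "\n"
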