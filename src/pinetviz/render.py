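"""SVG/PNG/table export of a styled, laid-out subnetwork.

The SVG is deliberately boring and byte-stable: edges first (one
``<line>`` per visible non-loop interaction, sorted by canonical key),
then nodes (one ``<circle>`` — or square/diamond when shapes encode the
organism — sorted by accession), then labels, then the legend group.
No timestamps or random ids are emitted, so identical inputs give
identical bytes.

PNG output re-draws the same element vocabulary (line, circle, rect,
polygon, text) through Pillow at an integer scale factor; it is an
optional convenience and SVG remains the contractual format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from lxml import etree

from .errors import RenderError
from .io import Dataset
from .layout import LayoutResult
from .query import Subnetwork
from .rules import StyleState

__all__ = ["RenderOptions", "render_svg", "render_table", "rasterize_png"]

SVG_NS = "http://www.w3.org/2000/svg"
_SHAPES = ("circle", "square", "diamond")


@dataclass(frozen=True)
class RenderOptions:
    """Canvas and typography settings for SVG export."""

    width: float = 1000.0
    height: float = 1000.0
    font_family: str = "sans-serif"
    font_size: int = 10
    shape_by_organism: bool = False
    show_legend: bool = True
    background: str | None = "#ffffff"


def _num(x: float) -> str:
    """Fixed-precision coordinate text (2 decimals, no trailing zeros)."""
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def render_svg(
    subnetwork: Subnetwork,
    layout: LayoutResult,
    style: StyleState,
    options: RenderOptions | None = None,
    dataset: Dataset | None = None,
) -> str:
    """Serialize the current view to SVG 1.1 text.

    Hidden nodes are omitted together with their incident edges;
    self-interactions are never drawn (they appear only in the table and
    CSV exports).  ``dataset`` is needed only when
    ``options.shape_by_organism`` is set.
    """
    options = options or RenderOptions()
    for acc in sorted(subnetwork.proteins):
        if style.node_style[acc]["visible"] and acc not in layout.positions:
            raise RenderError(f"no layout position for displayed protein {acc!r}")
    if options.shape_by_organism and dataset is None:
        raise RenderError("shape_by_organism requires the dataset")

    root = etree.Element(
        f"{{{SVG_NS}}}svg",
        nsmap={None: SVG_NS},
        attrib={
            "width": _num(options.width),
            "height": _num(options.height),
            "version": "1.1",
        },
    )
    if options.background:
        etree.SubElement(
            root,
            f"{{{SVG_NS}}}rect",
            attrib={
                "x": "0",
                "y": "0",
                "width": _num(options.width),
                "height": _num(options.height),
                "fill": options.background,
            },
        )

    visible_nodes = [
        acc for acc in sorted(subnetwork.proteins) if style.node_style[acc]["visible"]
    ]
    vis = set(visible_nodes)

    edges_g = etree.SubElement(root, f"{{{SVG_NS}}}g", attrib={"id": "edges"})
    for rec in subnetwork.sorted_interactions():
        es = style.edge_style[rec.key]
        if rec.is_self_loop or not es["visible"]:
            continue
        if rec.endpoint_a not in vis or rec.endpoint_b not in vis:
            continue
        xa, ya = layout.positions[rec.endpoint_a]
        xb, yb = layout.positions[rec.endpoint_b]
        etree.SubElement(
            edges_g,
            f"{{{SVG_NS}}}line",
            attrib={
                "x1": _num(xa),
                "y1": _num(ya),
                "x2": _num(xb),
                "y2": _num(yb),
                "stroke": es["color"],
                "stroke-width": _num(es["width"]),
                "data-key": f"{rec.endpoint_a}--{rec.endpoint_b}",
            },
        )

    shape_of: dict[str, str] = {}
    if options.shape_by_organism:
        orgs = sorted({dataset.proteins[acc].organism for acc in visible_nodes})
        shape_of = {org: _SHAPES[i % len(_SHAPES)] for i, org in enumerate(orgs)}

    nodes_g = etree.SubElement(root, f"{{{SVG_NS}}}g", attrib={"id": "nodes"})
    for acc in visible_nodes:
        ns = style.node_style[acc]
        x, y = layout.positions[acc]
        r = float(ns["size"])
        shape = "circle"
        if options.shape_by_organism:
            shape = shape_of[dataset.proteins[acc].organism]
        if shape == "circle":
            etree.SubElement(
                nodes_g,
                f"{{{SVG_NS}}}circle",
                attrib={
                    "cx": _num(x),
                    "cy": _num(y),
                    "r": _num(r),
                    "fill": ns["color"],
                    "data-accession": acc,
                },
            )
        elif shape == "square":
            etree.SubElement(
                nodes_g,
                f"{{{SVG_NS}}}rect",
                attrib={
                    "x": _num(x - r),
                    "y": _num(y - r),
                    "width": _num(2 * r),
                    "height": _num(2 * r),
                    "fill": ns["color"],
                    "data-accession": acc,
                },
            )
        else:  # diamond
            pts = f"{_num(x)},{_num(y - r)} {_num(x + r)},{_num(y)} {_num(x)},{_num(y + r)} {_num(x - r)},{_num(y)}"
            etree.SubElement(
                nodes_g,
                f"{{{SVG_NS}}}polygon",
                attrib={"points": pts, "fill": ns["color"], "data-accession": acc},
            )

    labels_g = etree.SubElement(root, f"{{{SVG_NS}}}g", attrib={"id": "labels"})
    for acc in visible_nodes:
        ns = style.node_style[acc]
        if ns["label"] is None:
            continue
        x, y = layout.positions[acc]
        el = etree.SubElement(
            labels_g,
            f"{{{SVG_NS}}}text",
            attrib={
                "x": _num(x + float(ns["size"]) + 2.0),
                "y": _num(y + options.font_size / 2.0 - 1.0),
                "font-family": options.font_family,
                "font-size": str(options.font_size),
                "fill": "#000000",
            },
        )
        el.text = str(ns["label"])

    if options.show_legend and style.legend:
        legend_g = etree.SubElement(root, f"{{{SVG_NS}}}g", attrib={"id": "legend"})
        x0 = options.width - 150.0
        for i, (value, color) in enumerate(style.legend):
            y0 = 20.0 + 16.0 * i
            etree.SubElement(
                legend_g,
                f"{{{SVG_NS}}}rect",
                attrib={
                    "x": _num(x0),
                    "y": _num(y0),
                    "width": "10",
                    "height": "10",
                    "fill": color,
                },
            )
            el = etree.SubElement(
                legend_g,
                f"{{{SVG_NS}}}text",
                attrib={
                    "x": _num(x0 + 14.0),
                    "y": _num(y0 + 9.0),
                    "font-family": options.font_family,
                    "font-size": str(options.font_size),
                    "fill": "#000000",
                },
            )
            el.text = str(value)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def render_table(
    subnetwork: Subnetwork,
    dataset: Dataset,
    sort_by: str = "accession",
    descending: bool = False,
) -> tuple[list[str], list[dict]]:
    """The table view: one row per displayed interaction.

    Returns ``(columns, rows)``.  Rows are pre-ordered by canonical
    endpoint pair, then stably sorted by ``sort_by`` (``accession``,
    ``score``, an evidence source, or a feature column, which sorts by
    the first endpoint's annotation); ties therefore stay in endpoint
    order.
    """
    columns = ["endpoint_a", "endpoint_b", "organism_a", "organism_b", "score"]
    columns += dataset.evidence_columns
    valid = {"accession", "score", *dataset.evidence_columns, *dataset.feature_columns}
    if sort_by not in valid:
        raise RenderError(
            f"unknown sort column {sort_by!r}; available: {', '.join(sorted(valid))}"
        )
    rows = []
    for rec in subnetwork.sorted_interactions():
        row: dict = {
            "endpoint_a": rec.endpoint_a,
            "endpoint_b": rec.endpoint_b,
            "organism_a": dataset.proteins[rec.endpoint_a].organism,
            "organism_b": dataset.proteins[rec.endpoint_b].organism,
            "score": rec.score,
        }
        for col in dataset.evidence_columns:
            row[col] = rec.evidence.get(col)
        rows.append(row)

    if sort_by == "accession":
        key = lambda r: (r["endpoint_a"], r["endpoint_b"])  # noqa: E731
    elif sort_by == "score":
        key = lambda r: r["score"]  # noqa: E731
    elif sort_by in dataset.evidence_columns:
        # absent evidence sorts after any present value
        key = lambda r: (r[sort_by] is None, r[sort_by] if r[sort_by] is not None else 0.0)  # noqa: E731
    else:
        key = lambda r: dataset.proteins[r["endpoint_a"]].features.get(sort_by, "")  # noqa: E731
    rows.sort(key=key, reverse=descending)
    return columns, rows


def rasterize_png(svg_text: str, scale: float = 1.0) -> bytes:
    """Rasterize an exported SVG to PNG bytes at ``scale`` times its size.

    Redraws the known element vocabulary (rect, line, circle, polygon,
    text) with Pillow; raises a clear error advising SVG export when
    Pillow is unavailable.
    """
    if scale <= 0:
        raise RenderError("scale must be positive")
    try:
        from PIL import Image, ImageDraw
    except ImportError:  # pragma: no cover - depends on optional extra
        raise RenderError(
            "PNG rasterization requires the optional 'pillow' dependency; "
            "use SVG export instead"
        )
    root = etree.fromstring(svg_text.encode("utf-8"))
    width = int(round(float(root.get("width")) * scale))
    height = int(round(float(root.get("height")) * scale))
    img = Image.new("RGB", (width, height), "#ffffff")
    draw = ImageDraw.Draw(img)

    def s(v: float) -> float:
        return v * scale

    for el in root.iter():
        tag = etree.QName(el).localname
        if tag == "rect":
            x, y = s(float(el.get("x"))), s(float(el.get("y")))
            w, h = s(float(el.get("width"))), s(float(el.get("height")))
            draw.rectangle([x, y, x + w, y + h], fill=el.get("fill"))
        elif tag == "line":
            draw.line(
                [
                    s(float(el.get("x1"))),
                    s(float(el.get("y1"))),
                    s(float(el.get("x2"))),
                    s(float(el.get("y2"))),
                ],
                fill=el.get("stroke"),
                width=max(1, int(round(float(el.get("stroke-width", "1")) * scale))),
            )
        elif tag == "circle":
            cx, cy = s(float(el.get("cx"))), s(float(el.get("cy")))
            r = s(float(el.get("r")))
            draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=el.get("fill"))
        elif tag == "polygon":
            pts = [
                tuple(s(float(c)) for c in p.split(","))
                for p in el.get("points").split()
            ]
            draw.polygon(pts, fill=el.get("fill"))
        elif tag == "text" and el.text:
            draw.text(
                (s(float(el.get("x"))), s(float(el.get("y"))) - 8 * scale),
                el.text,
                fill=el.get("fill", "#000000"),
            )

    import io as _io

    buf = _io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()
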