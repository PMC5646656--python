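"""Normative karyo-idiograms: one column per homolog pair, arms drawn on
either side of a common centromere baseline.

The short arm extends above the baseline and the long arm below, each
proportional to its relative length under one global scale; a small
triangular nick at the baseline marks the centromere.  Telocentric pairs
have no upper column.  Pairs are displayed in morphology-class order
(M, SM, ST, T) and by decreasing total length within a class, which is
also how measured tables conventionally number them.
"""

from __future__ import annotations

import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

from .core import CLASS_ORDER, ChromosomeClass, Karyotype, pair_metrics

__all__ = ["IdiogramColumn", "IdiogramLayout", "layout_idiogram", "render_svg"]


@dataclass(frozen=True)
class IdiogramColumn:
    """One pair's drawing geometry, in layout units."""

    pair_index: int
    cls: ChromosomeClass
    x: float          # left edge of the column
    upper: float      # short-arm extent above the baseline
    lower: float      # long-arm extent below the baseline


@dataclass(frozen=True)
class IdiogramLayout:
    species: str
    columns: tuple[IdiogramColumn, ...]
    scale: float          # layout units per relative-length unit
    column_width: float
    gap: float

    @property
    def width(self) -> float:
        return len(self.columns) * (self.column_width + self.gap) + self.gap

    @property
    def max_upper(self) -> float:
        return max(c.upper for c in self.columns)

    @property
    def max_lower(self) -> float:
        return max(c.lower for c in self.columns)

    def to_json(self) -> str:
        return json.dumps({
            "species": self.species,
            "scale": self.scale,
            "column_width": self.column_width,
            "gap": self.gap,
            "columns": [
                {**asdict(c), "cls": c.cls.value} for c in self.columns
            ],
        }, indent=1)


def layout_idiogram(karyotype: Karyotype, scale: float = 20.0,
                    column_width: float = 12.0, gap: float = 6.0,
                    ar_source: str = "reported") -> IdiogramLayout:
    """Compute column geometry for a karyotype.

    Every pair must be classifiable (valid arms); ``scale`` converts
    relative-length units to layout units.
    """
    if not karyotype.pairs:
        raise ValueError(f"empty karyotype for {karyotype.species!r}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    classed = [(p, pair_metrics(p, ar_source).cls) for p in karyotype.pairs]
    order = {c: k for k, c in enumerate(CLASS_ORDER)}
    # round totals so float summation noise cannot reorder equal-length pairs;
    # the stable sort then keeps them in table order
    classed.sort(key=lambda pc: (order[pc[1]], -round(pc[0].total, 6)))
    columns = []
    for k, (p, cls) in enumerate(classed):
        columns.append(IdiogramColumn(
            pair_index=p.pair_index,
            cls=cls,
            x=gap + k * (column_width + gap),
            upper=p.short_arm * scale,
            lower=p.long_arm * scale,
        ))
    return IdiogramLayout(species=karyotype.species, columns=tuple(columns),
                          scale=scale, column_width=column_width, gap=gap)


def render_svg(layout: IdiogramLayout, path: Optional[Union[str, Path]] = None,
               short_color: str = "#1f4e9c", long_color: str = "#c0392b",
               mirror: bool = False) -> str:
    """Render a layout as an SVG 1.1 document; returns the SVG text.

    One ``<g>`` element per pair carries the short-arm rectangle (above the
    baseline), the long-arm rectangle (below) and the centromere nicks —
    triangular indents on both sides of the column at the baseline.  With
    ``mirror=True`` each pair is drawn as two side-by-side homolog columns.
    """
    if not layout.columns:
        raise ValueError("empty layout")
    margin = 24.0
    baseline = margin + layout.max_upper
    height = baseline + layout.max_lower + margin
    ncols = 2 if mirror else 1
    width = layout.gap + len(layout.columns) * ncols * (layout.column_width + layout.gap)

    svg = ET.Element("svg", {
        "xmlns": "http://www.w3.org/2000/svg",
        "version": "1.1",
        "viewBox": f"0 0 {width:.2f} {height:.2f}",
    })
    title = ET.SubElement(svg, "title")
    title.text = f"Karyo-idiogram: {layout.species}"
    ET.SubElement(svg, "line", {
        "x1": "0", "y1": f"{baseline:.2f}", "x2": f"{width:.2f}",
        "y2": f"{baseline:.2f}", "stroke": "#999999", "stroke-width": "0.5",
    })
    w = layout.column_width
    nick = w / 4.0
    for k, col in enumerate(layout.columns):
        g = ET.SubElement(svg, "g", {
            "id": f"pair-{col.pair_index}",
            "data-class": col.cls.value,
        })
        xs = [layout.gap + (k * ncols + m) * (w + layout.gap) for m in range(ncols)]
        for x in xs:
            if col.upper > 0:
                ET.SubElement(g, "rect", {
                    "x": f"{x:.2f}", "y": f"{baseline - col.upper:.2f}",
                    "width": f"{w:.2f}", "height": f"{col.upper:.2f}",
                    "fill": short_color,
                })
            ET.SubElement(g, "rect", {
                "x": f"{x:.2f}", "y": f"{baseline:.2f}",
                "width": f"{w:.2f}", "height": f"{col.lower:.2f}",
                "fill": long_color,
            })
            # centromere nicks: triangular indents at the baseline
            for x0, dx in ((x, nick), (x + w, -nick)):
                pts = (f"{x0:.2f},{baseline - nick:.2f} "
                       f"{x0 + dx:.2f},{baseline:.2f} "
                       f"{x0:.2f},{baseline + nick:.2f}")
                ET.SubElement(g, "polygon", {"points": pts, "fill": "#ffffff"})
    text = ET.tostring(svg, encoding="unicode")
    doc = '<?xml version="1.0" encoding="UTF-8"?>\n' + text + "\n"
    if path is not None:
        Path(path).write_text(doc)
    return doc
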