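"""Multi-track SVG genome report.

Track order: external gene predictions (one lane per source), ORFs on the
plus then minus strand colored by pNeg/pS, mapping coverage, then six bar
charts (synonymous / tolerated / unfavorable substitution counts per
window, one trio per strand). Mirror-discarded ORFs are outlined in red;
suspect-start ORFs carry a red square at their 5' end. Rendering is pure
and deterministic: identical inputs give byte-identical SVG.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from orfdiv.io_formats import GenomeRecord, TrackFeature
from orfdiv.microdiversity import OrfDiversityStats
from orfdiv.pileup_caller import PileupColumn

# monotone pNeg/pS color scale: green (0) -> grey (1) -> orange (1.5) -> red
_SCALE = [
    (0.0, (0x2C, 0xA0, 0x2C)),
    (1.0, (0x99, 0x99, 0x99)),
    (1.5, (0xFF, 0x7F, 0x0E)),
    (3.0, (0xD6, 0x27, 0x28)),
]
_NA_COLOR = "#d9d9d9"


def color_for_ratio(ratio: float) -> str:
    """Hex fill color for a pNeg/pS value (NaN grey, Inf saturated red)."""
    if math.isnan(ratio):
        return _NA_COLOR
    if math.isinf(ratio):
        ratio = _SCALE[-1][0]
    r = min(max(ratio, _SCALE[0][0]), _SCALE[-1][0])
    for (x0, c0), (x1, c1) in zip(_SCALE, _SCALE[1:]):
        if r <= x1:
            t = 0.0 if x1 == x0 else (r - x0) / (x1 - x0)
            rgb = tuple(round(a + t * (b - a)) for a, b in zip(c0, c1))
            return "#{:02x}{:02x}{:02x}".format(*rgb)
    return _NA_COLOR


@dataclass(frozen=True)
class ReportLayout:
    """Geometry and options of the rendered report."""

    width: int = 1000
    margin: int = 60
    lane_height: int = 26
    orf_lane_height: int = 40
    coverage_height: int = 70
    bar_height: int = 36
    window_nt: int = 15


def coverage_profile(columns: Sequence[PileupColumn], genome_length: int) -> np.ndarray:
    """Per-position depth vector; uncovered positions are 0."""
    cov = np.zeros(genome_length, dtype=np.int64)
    for col in columns:
        cov[col.pos] = col.depth
    return cov


def _fmt(x: float) -> str:
    return f"{x:.2f}"


class _Report:
    def __init__(self, layout: ReportLayout, genome_length: int):
        self.layout = layout
        self.L = genome_length
        self.root = ET.Element("svg", {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
        })
        self.y = 10.0

    def x(self, pos: float) -> float:
        return self.layout.margin + pos / self.L * self.layout.width

    def label(self, text: str) -> None:
        el = ET.SubElement(self.root, "text", {
            "x": "5", "y": _fmt(self.y + 12), "font-size": "11",
            "font-family": "sans-serif",
        })
        el.text = text
        self.y += 16

    def axis(self) -> None:
        ET.SubElement(self.root, "line", {
            "x1": _fmt(self.x(0)), "x2": _fmt(self.x(self.L)),
            "y1": _fmt(self.y), "y2": _fmt(self.y),
            "stroke": "#000000", "stroke-width": "0.5",
        })


def _feature_rects(rep: _Report, start: int, end: int, wraps: bool, h: float) -> list[dict]:
    """One rect, or two joined segments for an origin-wrapping feature."""
    if not wraps:
        return [{"x0": start, "x1": end}]
    return [{"x0": start, "x1": rep.L}, {"x0": 0, "x1": end}]


def render_report(
    genome: GenomeRecord,
    external_tracks: Sequence[tuple[str, Sequence[TrackFeature]]],
    stats: Sequence[OrfDiversityStats],
    coverage: np.ndarray,
    window_counts: dict[tuple[str, str], np.ndarray],
    layout: ReportLayout = ReportLayout(),
    path: Optional[str] = None,
) -> str:
    """Render the full report; returns the SVG text (and writes ``path``)."""
    rep = _Report(layout, len(genome))
    rep.label(f"{genome.id} ({len(genome)} nt{', circular' if genome.circular else ''})")

    # external prediction lanes
    for source, feats in external_tracks:
        rep.label(f"predictions: {source}")
        for i, f in enumerate(feats):
            g = ET.SubElement(rep.root, "g", {"id": f"ext-{source}-{i}"})
            ET.SubElement(g, "rect", {
                "x": _fmt(rep.x(f.start)), "y": _fmt(rep.y),
                "width": _fmt(rep.x(f.end) - rep.x(f.start)),
                "height": _fmt(layout.lane_height * 0.6),
                "fill": "#6baed6" if f.strand == "+" else "#fd8d3c",
                "stroke": "#000000", "stroke-width": "0.5",
            })
        rep.y += layout.lane_height

    # ORF lanes, one per strand, colored by pNeg/pS
    for strand in "+-":
        rep.label(f"ORFs ({strand} strand), fill = pNeg/pS")
        lane = [s for s in stats if s.orf.strand == strand]
        for s in lane:
            orf = s.orf
            discarded = "mirror_discarded" in s.flags
            g = ET.SubElement(rep.root, "g", {"id": f"orf-{orf.id}"})
            h = layout.orf_lane_height * 0.45
            y0 = rep.y + (orf.frame % 3) * 2.0
            segs = _feature_rects(rep, orf.start, orf.end, orf.wraps_origin, h)
            for seg in segs:
                ET.SubElement(g, "rect", {
                    "x": _fmt(rep.x(seg["x0"])), "y": _fmt(y0),
                    "width": _fmt(rep.x(seg["x1"]) - rep.x(seg["x0"])),
                    "height": _fmt(h),
                    "fill": color_for_ratio(s.pneg_ps),
                    "stroke": "#d62728" if discarded else "#333333",
                    "stroke-width": "2" if discarded else "0.5",
                })
            if len(segs) == 2:  # dashed connector for a wrapped ORF
                ET.SubElement(g, "line", {
                    "x1": _fmt(rep.x(rep.L)), "x2": _fmt(rep.x(0)),
                    "y1": _fmt(y0 - 2), "y2": _fmt(y0 - 2),
                    "stroke": "#888888", "stroke-dasharray": "4,3",
                    "stroke-width": "1",
                })
            if "suspect_start" in s.flags:
                # red square at the 5' end
                from orfdiv.orf_model import orf_genome_pos
                p5 = orf_genome_pos(orf, 0, rep.L)
                ET.SubElement(g, "rect", {
                    "x": _fmt(rep.x(p5) - 3), "y": _fmt(y0 - 4),
                    "width": "6", "height": "6",
                    "fill": "#d62728", "class": "start-marker",
                })
        rep.y += layout.orf_lane_height

    # coverage
    rep.label("mapping coverage")
    cov_max = max(int(coverage.max()), 1) if len(coverage) else 1
    pts = []
    for pos in range(len(coverage)):
        yv = rep.y + layout.coverage_height * (1 - coverage[pos] / cov_max)
        pts.append(f"{_fmt(rep.x(pos + 0.5))},{_fmt(yv)}")
    ET.SubElement(rep.root, "polyline", {
        "id": "coverage",
        "points": " ".join(pts),
        "fill": "none", "stroke": "#1f77b4", "stroke-width": "1",
    })
    el = ET.SubElement(rep.root, "text", {
        "x": "5", "y": _fmt(rep.y + 10), "font-size": "9", "font-family": "sans-serif",
    })
    el.text = f"max {cov_max}"
    rep.y += layout.coverage_height + 6

    # six bar charts: 3 substitution classes per strand
    group_colors = {"SYN": "#2ca02c", "POS": "#9467bd", "NEG": "#d62728"}
    group_names = {"SYN": "synonymous", "POS": "tolerated", "NEG": "unfavorable"}
    all_max = max((int(v.max()) for v in window_counts.values() if len(v)), default=0) or 1
    for strand in "+-":
        for group in ("SYN", "POS", "NEG"):
            series = window_counts[(strand, group)]
            rep.label(f"{group_names[group]} ({strand} strand), per {layout.window_nt} nt")
            g = ET.SubElement(rep.root, "g", {"id": f"bars-{strand}-{group}"})
            for w in np.flatnonzero(series):
                x0 = rep.x(w * layout.window_nt)
                x1 = rep.x(min((w + 1) * layout.window_nt, rep.L))
                h = layout.bar_height * series[w] / all_max
                ET.SubElement(g, "rect", {
                    "x": _fmt(x0), "y": _fmt(rep.y + layout.bar_height - h),
                    "width": _fmt(x1 - x0), "height": _fmt(h),
                    "fill": group_colors[group],
                })
            rep.y += layout.bar_height
            rep.axis()
            rep.y += 4

    rep.root.set("width", str(layout.width + 2 * layout.margin))
    rep.root.set("height", _fmt(rep.y + 10))
    svg = '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(rep.root, encoding="unicode") + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(svg)
    return svg
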