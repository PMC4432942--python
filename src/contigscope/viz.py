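"""Declarative bubble-plot and contig-track specifications, and a
standalone interactive HTML renderer.

A plot has four user-controllable dimensions — x-axis, y-axis, point size
and point color — one mark per visible contig. Mark *area* is
proportional to the size column (perceptually standard for bubble plots),
so radius = r_min + (r_max − r_min)·sqrt(v / v_max). Search hits are
drawn ringed in black; hidden groups and contigs outside the current
selection are omitted but counted, and non-positive values on a log10
axis are dropped with a logged count rather than offset. The tested
contract is the spec payload (a documented JSON layout); pixel-level
interactivity is delegated to the embedded renderer.

Contig tracks show gene models as strand-colored glyphs laid out greedily
into non-overlapping lanes, with a per-feature detail table.
"""

from __future__ import annotations

import html
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .errors import PlotError
from .ingest import Dataset, canonical_column, render_value
from .query import SearchResult, Selection
from .style import ColorScheme, bin_index
from .taxonomy import TaxonPartition

logger = logging.getLogger(__name__)

R_MIN = 2.0   # display units
R_MAX = 40.0
FALLBACK_COLOR = "#999999"


@dataclass(frozen=True)
class AxisSpec:
    """One plot axis: column, linear or log10 scale, optional fixed range."""

    column: str
    scale: str = "linear"
    range: tuple[float, float] | None = None

    def __post_init__(self):
        if self.scale not in ("linear", "log10"):
            raise PlotError(f"unknown axis scale {self.scale!r}")


@dataclass(frozen=True)
class Mark:
    """One plotted contig."""

    contig_id: str
    x: float
    y: float
    radius: float
    color: str
    outlined: bool = False
    emphasized: bool = False
    hover_fields: tuple[tuple[str, str], ...] = ()


@dataclass
class PlotSpec:
    """Declarative bubble plot, decoupled from any rendering backend."""

    x_axis: AxisSpec
    y_axis: AxisSpec
    marks: list[Mark]
    legend: list[tuple[str, str, bool]]  # (group, color, visible)
    title: str = ""
    size_column: str = ""
    dropped_log: int = 0     # non-positive values dropped from a log axis
    dropped_missing: int = 0  # missing x/y values
    hidden: int = 0          # contigs of hidden groups
    filtered: int = 0        # contigs outside the selection

    def to_dict(self) -> dict:
        return {
            "kind": "bubble-plot",
            "title": self.title,
            "x_axis": asdict(self.x_axis),
            "y_axis": asdict(self.y_axis),
            "size_column": self.size_column,
            "legend": [list(entry) for entry in self.legend],
            "counts": {
                "marks": len(self.marks),
                "dropped_log": self.dropped_log,
                "dropped_missing": self.dropped_missing,
                "hidden": self.hidden,
                "filtered": self.filtered,
            },
            "marks": [
                {
                    "contig_id": m.contig_id,
                    "x": m.x,
                    "y": m.y,
                    "radius": m.radius,
                    "color": m.color,
                    "outlined": m.outlined,
                    "emphasized": m.emphasized,
                    "hover": [list(kv) for kv in m.hover_fields],
                }
                for m in self.marks
            ],
        }


@dataclass(frozen=True)
class TrackGlyph:
    """One gene-model glyph on a contig track."""

    start: int
    end: int
    lane: int
    orientation: str  # forward | reverse
    ftype: str
    selected: bool = False
    label: str = ""


@dataclass
class TrackSpec:
    """Contig detail track: glyphs in lanes plus per-feature tables."""

    contig_id: str
    window: tuple[int, int]
    glyphs: list[TrackGlyph]
    table_fields: list[dict] = field(default_factory=list)
    title: str = ""

    def to_dict(self) -> dict:
        return {
            "kind": "contig-track",
            "contig_id": self.contig_id,
            "title": self.title,
            "window": list(self.window),
            "glyphs": [asdict(g) for g in self.glyphs],
            "table_fields": self.table_fields,
        }


# ---------------------------------------------------------------------------
# bubble plot
# ---------------------------------------------------------------------------

def build_plot_spec(
    dataset: Dataset,
    x: AxisSpec | str,
    y: AxisSpec | str,
    size_column: str | None = None,
    partition: TaxonPartition | None = None,
    scheme: ColorScheme | None = None,
    color_column: str | None = None,
    selection: Selection | None = None,
    search: SearchResult | None = None,
    hidden_groups: Sequence[str] = (),
    emphasize_hits: bool = False,
    title: str = "",
) -> PlotSpec:
    """Assemble the bubble-plot specification.

    Exclusion precedence per contig: outside *selection* (counted as
    filtered) → hidden group → missing x/y/size value → non-positive value
    on a log axis. The counts satisfy
    ``marks + filtered + hidden + dropped = total contigs``.
    """
    if isinstance(x, str):
        x = AxisSpec(x)
    if isinstance(y, str):
        y = AxisSpec(y)
    table = dataset.table
    if len(table) == 0:
        raise PlotError("empty dataset")
    for axis in (x, y):
        if table.spec(axis.column).kind != "numeric":
            raise PlotError(f"axis column {axis.column!r} is not numeric")
    if size_column is None:
        size_column = canonical_column(table, "length")
        if size_column is None:
            raise PlotError("no size column designated or found")
    if table.spec(size_column).kind != "numeric":
        raise PlotError(f"size column {size_column!r} is not numeric")

    ids = table.contig_ids
    xv = table.values(x.column).astype(float)
    yv = table.values(y.column).astype(float)
    sv = table.values(size_column).astype(float)

    hidden_set = set(hidden_groups)
    hover_specs = [
        c for c in table.columns if c.role in ("info", "filter", "color")
    ]
    color_vals = (
        table.values(color_column) if color_column is not None else None
    )

    # v_max over contigs eligible for plotting (selection/visibility applied)
    def _visible(i: int, cid: str) -> bool:
        if selection is not None and cid not in selection:
            return False
        if partition is not None and partition.assignment.get(cid) in hidden_set:
            return False
        return True

    vis_sizes = [
        sv[i] for i, cid in enumerate(ids)
        if _visible(i, cid) and not math.isnan(sv[i])
    ]
    v_max = max(vis_sizes) if vis_sizes else 1.0
    if v_max <= 0:
        v_max = 1.0

    marks: list[Mark] = []
    filtered = hidden = dropped_log = dropped_missing = 0
    for i, cid in enumerate(ids):
        if selection is not None and cid not in selection:
            filtered += 1
            continue
        if partition is not None and partition.assignment.get(cid) in hidden_set:
            hidden += 1
            continue
        if math.isnan(xv[i]) or math.isnan(yv[i]) or math.isnan(sv[i]):
            dropped_missing += 1
            continue
        if (x.scale == "log10" and xv[i] <= 0) or (
            y.scale == "log10" and yv[i] <= 0
        ):
            dropped_log += 1
            continue
        radius = R_MIN + (R_MAX - R_MIN) * math.sqrt(max(sv[i], 0.0) / v_max)
        color = _mark_color(cid, i, partition, scheme, color_vals)
        hit = search is not None and cid in search.per_contig_hits
        hover = tuple(
            (spec.name, render_value(table.df[spec.name].iloc[i]))
            for spec in hover_specs
        )
        marks.append(
            Mark(
                contig_id=cid,
                x=float(xv[i]),
                y=float(yv[i]),
                radius=radius,
                color=color,
                outlined=hit,
                emphasized=hit and emphasize_hits,
                hover_fields=hover,
            )
        )
    if dropped_log:
        logger.warning(
            "dropped %d contig(s) with non-positive values on a log10 axis",
            dropped_log,
        )

    legend: list[tuple[str, str, bool]] = []
    if partition is not None:
        for grp in partition.groups:
            color = (
                scheme.color_of(grp) if scheme is not None else None
            ) or FALLBACK_COLOR
            legend.append((grp, color, grp not in hidden_set))

    return PlotSpec(
        x_axis=x,
        y_axis=y,
        marks=marks,
        legend=legend,
        title=title,
        size_column=size_column,
        dropped_log=dropped_log,
        dropped_missing=dropped_missing,
        hidden=hidden,
        filtered=filtered,
    )


def _mark_color(cid, i, partition, scheme, color_vals) -> str:
    if scheme is None:
        return FALLBACK_COLOR
    if scheme.mode == "ordinal":
        key = (
            partition.assignment.get(cid)
            if partition is not None
            else (color_vals[i] if color_vals is not None else None)
        )
        return scheme.color_of(key) or FALLBACK_COLOR
    if scheme.mode == "binned":
        if color_vals is None:
            return FALLBACK_COLOR
        v = float(color_vals[i])
        if math.isnan(v):
            return FALLBACK_COLOR
        return scheme.color_of(bin_index(v, scheme.bin_edges)) or FALLBACK_COLOR
    return FALLBACK_COLOR


# ---------------------------------------------------------------------------
# contig track
# ---------------------------------------------------------------------------

def build_contig_track(
    dataset: Dataset,
    contig_id: str,
    window: tuple[int, int] | None = None,
    selected_feature: int | None = None,
) -> TrackSpec:
    """Lay out the gene models of one contig into non-overlapping lanes.

    Features overlapping the window (inclusive-coordinate interval
    intersection) are included; lanes are assigned greedily in start
    order. A contig with no annotations yields an empty glyph list.
    """
    if contig_id not in set(dataset.contig_ids):
        raise PlotError(f"unknown contig {contig_id!r}")
    feats = sorted(
        dataset.features_of(contig_id), key=lambda f: (f.start, f.end)
    )
    if window is None:
        if feats:
            hi = max(f.end for f in feats)
        else:
            hi = 1
        seq = (dataset.sequences or {}).get(contig_id)
        if seq:
            hi = max(hi, len(seq))
        window = (1, hi)
    lo, hi = window
    if lo > hi:
        raise PlotError(f"invalid window {window}")

    in_window = [f for f in feats if f.start <= hi and f.end >= lo]
    lane_ends: list[int] = []  # last occupied end position per lane
    glyphs: list[TrackGlyph] = []
    table_fields: list[dict] = []
    for idx, feat in enumerate(in_window):
        lane = next(
            (j for j, end in enumerate(lane_ends) if feat.start > end), None
        )
        if lane is None:
            lane = len(lane_ends)
            lane_ends.append(feat.end)
        else:
            lane_ends[lane] = feat.end
        orientation = "reverse" if feat.strand == "-" else "forward"
        label = ";".join(feat.attributes.get("ID", ())) or feat.ftype
        selected = selected_feature is not None and idx == selected_feature
        glyphs.append(
            TrackGlyph(
                start=feat.start,
                end=feat.end,
                lane=lane,
                orientation=orientation,
                ftype=feat.ftype,
                selected=selected,
                label=label,
            )
        )
        if selected:
            table_fields.append(
                {
                    "feature": label,
                    "type": feat.ftype,
                    "start": feat.start,
                    "end": feat.end,
                    "strand": feat.strand,
                    **{k: ",".join(v) for k, v in feat.attributes.items()},
                }
            )
    return TrackSpec(
        contig_id=contig_id,
        window=window,
        glyphs=glyphs,
        table_fields=table_fields,
        title=f"Contig {contig_id}",
    )


# ---------------------------------------------------------------------------
# HTML rendering
# ---------------------------------------------------------------------------

def spec_to_json(spec: PlotSpec | TrackSpec) -> str:
    """Canonical JSON payload (sorted keys, compact separators) — the
    backend-independent, byte-stable serialization of a spec."""
    return json.dumps(spec.to_dict(), sort_keys=True, separators=(",", ":"))


def render_html(spec: PlotSpec | TrackSpec, path) -> None:
    """Write a self-contained interactive HTML document.

    The full spec is embedded verbatim as a JSON payload
    (``<script type="application/json" id="contigscope-data">``); a small
    inline script draws it to SVG with pan/zoom (drag + wheel) and hover
    tooltips. Re-rendering the same spec produces a byte-identical
    document.
    """
    payload = spec_to_json(spec)
    title = html.escape(getattr(spec, "title", "") or "contigscope")
    doc = _HTML_TEMPLATE.replace("__TITLE__", title).replace(
        "__PAYLOAD__", payload.replace("</", "<\\/")
    )
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(doc)


_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>__TITLE__</title>
<style>
 body { font-family: sans-serif; margin: 1em; }
 #plot { border: 1px solid #ccc; cursor: grab; }
 #tooltip { position: absolute; background: #fffbe6; border: 1px solid #888;
            padding: 4px 6px; font-size: 12px; display: none;
            pointer-events: none; }
 .legend span.swatch { display: inline-block; width: 12px; height: 12px;
                       margin-right: 4px; }
 .legend li.hidden { opacity: 0.35; }
</style>
</head>
<body>
<h2>__TITLE__</h2>
<div id="root"></div>
<div id="tooltip"></div>
<script type="application/json" id="contigscope-data">__PAYLOAD__</script>
<script>
(function () {
  var spec = JSON.parse(
    document.getElementById("contigscope-data").textContent);
  var root = document.getElementById("root");
  var tip = document.getElementById("tooltip");
  var W = 900, H = 560, PAD = 50;
  var svgNS = "http://www.w3.org/2000/svg";

  function scaleOf(axis, values) {
    var vals = values.filter(function (v) {
      return axis.scale !== "log10" || v > 0; });
    var tr = axis.scale === "log10"
      ? function (v) { return Math.log10(v); }
      : function (v) { return v; };
    var lo, hi;
    if (axis.range) { lo = tr(axis.range[0]); hi = tr(axis.range[1]); }
    else {
      lo = Math.min.apply(null, vals.map(tr));
      hi = Math.max.apply(null, vals.map(tr));
    }
    if (!(hi > lo)) { hi = lo + 1; }
    return { lo: lo, hi: hi, tr: tr };
  }

  function drawBubble() {
    var svg = document.createElementNS(svgNS, "svg");
    svg.setAttribute("id", "plot");
    svg.setAttribute("width", W);
    svg.setAttribute("height", H);
    var xs = spec.marks.map(function (m) { return m.x; });
    var ys = spec.marks.map(function (m) { return m.y; });
    var sx = scaleOf(spec.x_axis, xs), sy = scaleOf(spec.y_axis, ys);
    var view = { x0: 0, y0: 0, k: 1 };
    var g = document.createElementNS(svgNS, "g");
    svg.appendChild(g);
    spec.marks.forEach(function (m) {
      var c = document.createElementNS(svgNS, "circle");
      var px = PAD + (sx.tr(m.x) - sx.lo) / (sx.hi - sx.lo) * (W - 2 * PAD);
      var py = H - PAD - (sy.tr(m.y) - sy.lo) / (sy.hi - sy.lo) * (H - 2 * PAD);
      c.setAttribute("cx", px);
      c.setAttribute("cy", py);
      c.setAttribute("r", m.radius);
      c.setAttribute("fill", m.color);
      c.setAttribute("fill-opacity", m.emphasized ? "1.0" : "0.75");
      if (m.outlined) {
        c.setAttribute("stroke", "#000");
        c.setAttribute("stroke-width", "2");
      }
      c.addEventListener("mousemove", function (ev) {
        tip.style.display = "block";
        tip.style.left = (ev.pageX + 12) + "px";
        tip.style.top = (ev.pageY + 12) + "px";
        tip.innerHTML = "<b>" + m.contig_id + "</b><br>" +
          m.hover.map(function (kv) {
            return kv[0] + ": " + kv[1]; }).join("<br>");
      });
      c.addEventListener("mouseleave", function () {
        tip.style.display = "none"; });
      g.appendChild(c);
    });
    var drag = null;
    svg.addEventListener("mousedown", function (ev) {
      drag = [ev.clientX - view.x0, ev.clientY - view.y0]; });
    window.addEventListener("mouseup", function () { drag = null; });
    svg.addEventListener("mousemove", function (ev) {
      if (!drag) { return; }
      view.x0 = ev.clientX - drag[0];
      view.y0 = ev.clientY - drag[1];
      apply();
    });
    svg.addEventListener("wheel", function (ev) {
      ev.preventDefault();
      view.k *= ev.deltaY < 0 ? 1.1 : 0.9;
      apply();
    });
    function apply() {
      g.setAttribute("transform", "translate(" + view.x0 + "," + view.y0 +
        ") scale(" + view.k + ")");
    }
    root.appendChild(svg);
    if (spec.legend.length) {
      var ul = document.createElement("ul");
      ul.className = "legend";
      spec.legend.forEach(function (entry) {
        var li = document.createElement("li");
        if (!entry[2]) { li.className = "hidden"; }
        li.innerHTML = '<span class="swatch" style="background:' + entry[1] +
          '"></span>' + entry[0];
        ul.appendChild(li);
      });
      root.appendChild(ul);
    }
  }

  function drawTrack() {
    var svg = document.createElementNS(svgNS, "svg");
    svg.setAttribute("id", "plot");
    svg.setAttribute("width", W);
    var lanes = spec.glyphs.reduce(function (a, g) {
      return Math.max(a, g.lane + 1); }, 1);
    var laneH = 26;
    svg.setAttribute("height", lanes * laneH + 40);
    var lo = spec.window[0], hi = spec.window[1];
    spec.glyphs.forEach(function (gl) {
      var r = document.createElementNS(svgNS, "rect");
      var x1 = PAD + (Math.max(gl.start, lo) - lo) / (hi - lo + 1) * (W - 2 * PAD);
      var x2 = PAD + (Math.min(gl.end, hi) - lo + 1) / (hi - lo + 1) * (W - 2 * PAD);
      r.setAttribute("x", x1);
      r.setAttribute("y", 10 + gl.lane * laneH);
      r.setAttribute("width", Math.max(x2 - x1, 1));
      r.setAttribute("height", laneH - 8);
      r.setAttribute("fill", gl.selected ? "#F5C518" :
        (gl.orientation === "forward" ? "#C0392B" : "#222222"));
      var t = document.createElementNS(svgNS, "title");
      t.textContent = gl.label + " (" + gl.start + ".." + gl.end + " " +
        gl.orientation + ")";
      r.appendChild(t);
      svg.appendChild(r);
    });
    root.appendChild(svg);
  }

  if (spec.kind === "bubble-plot") { drawBubble(); } else { drawTrack(); }
})();
</script>
</body>
</html>
"""
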