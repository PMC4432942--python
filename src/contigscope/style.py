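"""Deterministic color assignment: ordinal palettes, statistical binning,
and gradient heat-map coloring for quantitative columns.

"Statistical binning" here means equal-frequency (quantile) bins by
default — robust to the heavy-tailed coverage distributions typical of
metagenome assemblies — with equal-width bins available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ContigScopeError

#: Fixed 20-color qualitative palette (hex RGB) used for group legends.
DEFAULT_PALETTE: tuple[str, ...] = (
    "#1F77B4", "#FF7F0E", "#2CA02C", "#D62728", "#9467BD",
    "#8C564B", "#E377C2", "#7F7F7F", "#BCBD22", "#17BECF",
    "#AEC7E8", "#FFBB78", "#98DF8A", "#FF9896", "#C5B0D5",
    "#C49C94", "#F7B6D2", "#C7C7C7", "#DBDB8D", "#9EDAE5",
)


@dataclass(frozen=True)
class ColorScheme:
    """A color mapping in one of three modes.

    * ``ordinal`` — labels → palette colors (wrapping when labels exceed
      the palette).
    * ``binned`` — strictly ascending ``bin_edges`` partition the value
      range; each bin has one color.
    * ``gradient`` — two ``endpoints`` linearly interpolated over the
      observed value range.
    """

    mode: str
    mapping: Mapping = field(default_factory=dict)
    bin_edges: tuple[float, ...] = ()
    endpoints: tuple[str, str] | None = None

    def __post_init__(self):
        if self.mode not in ("ordinal", "binned", "gradient"):
            raise ContigScopeError(f"unknown color mode {self.mode!r}")
        if any(a >= b for a, b in zip(self.bin_edges, self.bin_edges[1:])):
            raise ContigScopeError("bin_edges must be strictly ascending")

    def color_of(self, key) -> str | None:
        return self.mapping.get(key)

    def to_csv(self, dest) -> None:
        from .ingest import _open_text

        handle, close = _open_text(dest, "wt")
        try:
            handle.write("key,color\n")
            for key, color in self.mapping.items():
                handle.write(f"{key},{color}\n")
        finally:
            if close:
                handle.close()


def _parse_hex(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    if len(c) != 6:
        raise ContigScopeError(f"not a hex RGB color: {color!r}")
    return int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16)


def _to_hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def ordinal_colors(
    labels: Sequence[str], palette: Sequence[str] = DEFAULT_PALETTE
) -> ColorScheme:
    """Assign label *i* the palette color ``i mod len(palette)``.

    Deterministic for a fixed label order; labels beyond the palette reuse
    colors from the start.
    """
    if not palette:
        raise ContigScopeError("palette must be non-empty")
    mapping = {lab: palette[i % len(palette)] for i, lab in enumerate(labels)}
    return ColorScheme(mode="ordinal", mapping=mapping)


def quantile_bins(values: Sequence[float], k: int) -> tuple[float, ...]:
    """Equal-frequency bin edges by nearest-rank order statistics.

    The *j*-th edge (j = 1..k-1) is the ``ceil(j*n/k)``-th order statistic
    of the non-missing values; duplicate edges are removed. Bins are
    interpreted left-open right-closed, except the first bin which also
    contains its left boundary — see :func:`bin_index`.
    """
    if k < 1:
        raise ContigScopeError("k must be >= 1")
    vals = sorted(v for v in values if v is not None and not math.isnan(v))
    if not vals:
        raise ContigScopeError("no non-missing values to bin")
    n = len(vals)
    edges: list[float] = []
    for j in range(1, k):
        rank = math.ceil(j * n / k)  # 1-based nearest rank
        edge = vals[rank - 1]
        # dedup, and never emit an edge at the maximum (it would leave an
        # empty top bin; a constant column thus yields a single bin)
        if (not edges or edge > edges[-1]) and edge < vals[-1]:
            edges.append(edge)
    return tuple(edges)


def equal_width_bins(values: Sequence[float], k: int) -> tuple[float, ...]:
    """Equal-width alternative: k-1 evenly spaced interior edges."""
    if k < 1:
        raise ContigScopeError("k must be >= 1")
    vals = [v for v in values if v is not None and not math.isnan(v)]
    if not vals:
        raise ContigScopeError("no non-missing values to bin")
    lo, hi = min(vals), max(vals)
    if lo == hi:
        return ()
    return tuple(lo + (hi - lo) * j / k for j in range(1, k))


def bin_index(value: float, edges: Sequence[float]) -> int:
    """Index of the bin containing *value* (0-based).

    Bin *i* (i >= 1) is ``(edges[i-1], edges[i]]``; bin 0 is everything up
    to and including ``edges[0]``, so each value falls in exactly one bin.
    """
    return int(np.searchsorted(np.asarray(edges), value, side="left"))


def binned_colors(
    values: Sequence[float],
    k: int,
    palette: Sequence[str] = DEFAULT_PALETTE,
    method: str = "quantile",
) -> ColorScheme:
    """Bin a quantitative column and give each bin one palette color."""
    edge_fn = {"quantile": quantile_bins, "width": equal_width_bins}.get(method)
    if edge_fn is None:
        raise ContigScopeError(f"unknown binning method {method!r}")
    edges = edge_fn(values, k)
    n_bins = len(edges) + 1
    mapping = {i: palette[i % len(palette)] for i in range(n_bins)}
    return ColorScheme(mode="binned", mapping=mapping, bin_edges=edges)


def gradient_colors(
    values: Sequence[float], low: str = "#0000FF", high: str = "#FF0000"
) -> Callable[[float], str]:
    """Linear channel-wise gradient over the observed value range.

    The minimum maps exactly to *low*, the maximum exactly to *high*;
    a constant column maps everything to *low*.
    """
    vals = [v for v in values if v is not None and not math.isnan(v)]
    if not vals:
        raise ContigScopeError("no non-missing values for gradient")
    lo_v, hi_v = min(vals), max(vals)
    lo_rgb, hi_rgb = _parse_hex(low), _parse_hex(high)

    def color_of(value: float) -> str:
        if hi_v == lo_v:
            return _to_hex(lo_rgb)
        t = (value - lo_v) / (hi_v - lo_v)
        t = min(1.0, max(0.0, t))
        rgb = tuple(
            int(round(a + (b - a) * t)) for a, b in zip(lo_rgb, hi_rgb)
        )
        return _to_hex(rgb)

    return color_of
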