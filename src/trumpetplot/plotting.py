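"""The trumpet plot: effect size vs allele frequency on a log10 axis.

A trumpet plot scatters each variant's effect size (y) against its allele
frequency (x, log10 scale so rare variants are not crushed against the
axis), overlays analytic power curves (minimum detectable effect per target
power level), sizes points by |beta| and colors them by -log10(P). In the
recommended signed/minor-allele orientation the frequency axis runs to 0.5
and the power curves are mirrored to negative effects, giving the plot its
two-sided trumpet shape.

Rendering is split: :func:`build_plot_data` resolves every encoding into
render-ready geometry (so it can be tested without a graphics backend),
then :func:`render_static` draws it with matplotlib (PNG/SVG/PDF) and
:func:`render_interactive` writes a dependency-free standalone HTML file
with an embedded SVG whose points carry hover payloads.
"""

from __future__ import annotations

import html
import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .harmonize import OrientationMode
from .model import SumstatsTable
from .power import PowerCurve, PowerCurveSpec, build_power_curves

logger = logging.getLogger(__name__)

HOVER_CHOICES = ("variant_id", "beta", "gene", "pvalue", "trait")


@dataclass
class TrumpetPlotSpec:
    """Encoding choices for a trumpet plot.

    ``min_effect_display`` drops records with |beta| strictly below the
    threshold (|beta| equal to it is kept); the interactive default of 0.05
    keeps file sizes manageable. Point sizes (matplotlib "area" units,
    points^2) map |beta| linearly. The color scale is -log10(P), capped by
    default at 50 so genome-wide hits spanning hundreds of orders of
    magnitude stay distinguishable.
    """

    orientation: OrientationMode = OrientationMode.MINOR_ALLELE_SIGNED
    f_min: float = 1e-5
    f_max: Optional[float] = None  # default 0.5 signed / 1 - f_min positive
    size_min: float = 10.0
    size_max: float = 120.0
    color_cap: float = 50.0
    min_effect_display: float = 0.0
    show_power_curves: bool = True
    power: Optional[PowerCurveSpec] = None
    hover_fields: Sequence[str] = ("variant_id", "beta", "gene", "pvalue", "trait")

    def __post_init__(self) -> None:
        self.orientation = OrientationMode(self.orientation)
        if self.f_min <= 0.0:
            raise ValueError("f_min must be > 0")
        if self.f_max is None:
            self.f_max = (
                0.5
                if self.orientation is OrientationMode.MINOR_ALLELE_SIGNED
                else 1.0 - self.f_min
            )
        if not (self.size_min > 0 and self.size_max >= self.size_min):
            raise ValueError("point size bounds must be positive and ordered")
        if self.min_effect_display < 0:
            raise ValueError("min_effect_display must be >= 0")
        bad = [h for h in self.hover_fields if h not in HOVER_CHOICES]
        if bad:
            raise ValueError(f"unknown hover fields {bad}; choose from {HOVER_CHOICES}")


@dataclass
class PlotData:
    """Fully resolved geometry: points, curves and axis metadata."""

    points: pd.DataFrame  # x, y, size, color_value + hover columns
    curves: list[PowerCurve]
    ticks: list[float]
    spec: TrumpetPlotSpec
    n_input: int = 0
    n_dropped: int = 0
    n_clipped: int = 0

    @property
    def signed(self) -> bool:
        return self.spec.orientation is OrientationMode.MINOR_ALLELE_SIGNED


def _log_ticks(f_min: float, f_max: float) -> list[float]:
    lo = int(np.floor(np.log10(f_min)))
    hi = int(np.ceil(np.log10(f_max)))
    return [10.0**e for e in range(lo, hi + 1) if f_min <= 10.0**e <= f_max * 1.0001]


def build_plot_data(table: SumstatsTable, spec: TrumpetPlotSpec) -> PlotData:
    """Resolve encodings for a harmonized table.

    Fails if the table does not match the requested orientation (e.g. any
    eaf > 0.5 in signed mode). Points rarer than ``f_min`` are clipped to the
    axis edge with a warning rather than dropped: the rare tail is the whole
    point of the plot.
    """
    eaf = np.array([r.eaf for r in table.records])
    beta = np.array([r.beta for r in table.records])
    if spec.orientation is OrientationMode.MINOR_ALLELE_SIGNED:
        bad = int(np.sum(eaf > 0.5 + 1e-12))
        if bad:
            raise ValueError(
                f"{bad} records have eaf > 0.5: table is not harmonized to "
                "the minor-allele orientation"
            )
    else:
        bad = int(np.sum(beta < 0.0))
        if bad:
            raise ValueError(
                f"{bad} records have beta < 0: table is not harmonized to "
                "the positive-effect orientation"
            )

    n_input = len(table)
    keep = np.abs(beta) >= spec.min_effect_display
    n_dropped = int(np.sum(~keep))
    records = [r for r, k in zip(table.records, keep) if k]
    eaf, beta = eaf[keep], beta[keep]

    x = eaf.copy()
    n_clipped = int(np.sum(x < spec.f_min))
    if n_clipped:
        logger.warning(
            "%d points rarer than f_min=%g clipped to the axis edge",
            n_clipped, spec.f_min,
        )
    x = np.clip(x, spec.f_min, spec.f_max)

    ab = np.abs(beta)
    if len(ab) and ab.max() > ab.min():
        frac = (ab - ab.min()) / (ab.max() - ab.min())
        size = spec.size_min + frac * (spec.size_max - spec.size_min)
    else:  # degenerate range: midpoint size
        size = np.full(len(ab), 0.5 * (spec.size_min + spec.size_max))
    color = np.minimum(
        -np.log10(np.array([r.pvalue for r in records])), spec.color_cap
    ) if records else np.array([])

    points = pd.DataFrame(
        {
            "x": x,
            "y": beta,
            "size": size,
            "color_value": color,
            "variant_id": [r.variant_id for r in records],
            "beta": beta,
            "gene": [r.gene or "" for r in records],
            "pvalue": [r.pvalue for r in records],
            "trait": [r.trait or table.trait_name for r in records],
        }
    )

    curves: list[PowerCurve] = []
    if spec.show_power_curves and spec.power is not None:
        pw = spec.power
        if pw.f_min != spec.f_min or pw.f_max != spec.f_max:
            pw = PowerCurveSpec(
                n=pw.n, alpha=pw.alpha, trait_model=pw.trait_model,
                n_cases=pw.n_cases, n_controls=pw.n_controls,
                power_levels=pw.power_levels, f_min=spec.f_min,
                f_max=min(spec.f_max, 1.0 - 1e-9), n_grid=pw.n_grid,
            )
        curves = build_power_curves(
            pw, mirrored=spec.orientation is OrientationMode.MINOR_ALLELE_SIGNED
        )

    return PlotData(
        points=points,
        curves=curves,
        ticks=_log_ticks(spec.f_min, spec.f_max),
        spec=spec,
        n_input=n_input,
        n_dropped=n_dropped,
        n_clipped=n_clipped,
    )


_CURVE_COLORS = ["#2c7bb6", "#9b59b6", "#e85d9a", "#f46d43", "#66bd63"]


def render_static(
    data: PlotData, path: Union[str, os.PathLike], format: Optional[str] = None
) -> None:
    """Draw with matplotlib and write PNG/SVG/PDF.

    SVG output is made reproducible (fixed hash salt, no date metadata) so
    identical PlotData renders byte-identically.
    """
    if len(data.points) == 0:
        raise ValueError("no points to render")
    path = os.fspath(path)
    fmt = (format or os.path.splitext(path)[1].lstrip(".") or "svg").lower()
    if fmt not in ("png", "svg", "pdf"):
        raise ValueError(f"unsupported format {fmt!r}")

    with matplotlib.rc_context({"svg.hashsalt": "trumpetplot"}):
        fig, ax = plt.subplots(figsize=(9, 6))
        pts = data.points
        sc = ax.scatter(
            pts["x"], pts["y"], s=pts["size"], c=pts["color_value"],
            cmap="viridis", vmin=0.0, vmax=data.spec.color_cap,
            alpha=0.8, linewidths=0, zorder=2,
        )
        for ci, curve in enumerate(data.curves):
            color = _CURVE_COLORS[ci % len(_CURVE_COLORS)]
            ax.plot(curve.freqs, curve.beta_min, color=color, lw=1.8,
                    label=f"power {curve.level:g}", zorder=3)
            if curve.mirrored:
                ax.plot(curve.freqs, -curve.beta_min, color=color, lw=1.8,
                        zorder=3)
        if data.signed:
            ax.axhline(0.0, color="0.6", lw=0.8, zorder=1)
        ax.set_xscale("log")
        ax.set_xlim(data.spec.f_min * 0.9, data.spec.f_max * 1.1)
        ax.set_xticks(data.ticks)
        ax.set_xticklabels([f"$10^{{{int(np.log10(t))}}}$" if t < 1 else "1"
                            for t in data.ticks])
        ax.set_xlabel("Allele frequency" if not data.signed
                      else "Minor allele frequency")
        ax.set_ylabel("Effect size (beta)")
        fig.colorbar(sc, ax=ax, label=r"$-\log_{10}(P)$")
        if data.curves:
            ax.legend(loc="upper right", frameon=False)
        fig.tight_layout()
        metadata = None
        if fmt == "svg":
            metadata = {"Date": None}
        elif fmt == "pdf":
            metadata = {"CreationDate": None}
        fig.savefig(path, format=fmt, metadata=metadata)
        plt.close(fig)


def _hover_text(row: pd.Series, fields: Sequence[str]) -> str:
    parts = []
    for f in fields:
        v = row[f]
        if f in ("beta",):
            v = f"{v:.4g}"
        elif f == "pvalue":
            v = f"{v:.3g}"
        parts.append(f"{f}: {v}")
    return "\n".join(parts)


def render_interactive(data: PlotData, path: Union[str, os.PathLike]) -> None:
    """Write a self-contained interactive HTML trumpet plot.

    The file embeds a single SVG; every point is a circle carrying its hover
    payload both as a native ``<title>`` tooltip and as ``data-`` attributes.
    Points are serialized in sorted variant-id order so re-rendering
    identical PlotData is byte-identical.
    """
    if len(data.points) == 0:
        raise ValueError("no points to render")
    spec = data.spec
    W, H, ML, MR, MT, MB = 900, 600, 70, 30, 30, 60
    pw, ph = W - ML - MR, H - MT - MB

    lx0, lx1 = np.log10(spec.f_min), np.log10(spec.f_max)

    pts = data.points.sort_values("variant_id", kind="mergesort")
    ymax = float(np.abs(pts["y"]).max())
    for c in data.curves:
        ymax = max(ymax, float(c.beta_min[np.isfinite(c.beta_min)].max(initial=0.0)))
    ymax *= 1.05
    ylo = -ymax if data.signed else 0.0

    def X(f):
        return ML + (np.log10(np.asarray(f, dtype=float)) - lx0) / (lx1 - lx0) * pw

    def Y(b):
        return MT + (ymax - np.asarray(b, dtype=float)) / (ymax - ylo) * ph

    out = []
    out.append("<!DOCTYPE html>")
    out.append("<html><head><meta charset='utf-8'><title>Trumpet plot</title>")
    out.append(
        "<style>circle.pt{stroke:none;opacity:.8}"
        "circle.pt:hover{stroke:#000;stroke-width:1;opacity:1}"
        "text{font-family:sans-serif;font-size:12px}</style></head><body>"
    )
    out.append(f"<svg width='{W}' height='{H}' xmlns='http://www.w3.org/2000/svg'>")
    # axes
    out.append(
        f"<rect x='{ML}' y='{MT}' width='{pw}' height='{ph}' fill='none' stroke='#333'/>"
    )
    for t in data.ticks:
        xt = float(X(t))
        label = f"1e{int(np.log10(t))}" if t < 1 else "1"
        out.append(
            f"<line x1='{xt:.2f}' y1='{MT + ph}' x2='{xt:.2f}' y2='{MT + ph + 5}' stroke='#333'/>"
        )
        out.append(
            f"<text x='{xt:.2f}' y='{MT + ph + 20}' text-anchor='middle'>{label}</text>"
        )
    for b in np.linspace(ylo, ymax, 5):
        yt = float(Y(b))
        out.append(
            f"<line x1='{ML - 5}' y1='{yt:.2f}' x2='{ML}' y2='{yt:.2f}' stroke='#333'/>"
        )
        out.append(
            f"<text x='{ML - 8}' y='{yt + 4:.2f}' text-anchor='end'>{b:.2g}</text>"
        )
    out.append(
        f"<text x='{ML + pw / 2}' y='{H - 15}' text-anchor='middle'>"
        "Allele frequency (log scale)</text>"
    )
    out.append(
        f"<text x='18' y='{MT + ph / 2}' text-anchor='middle' "
        f"transform='rotate(-90 18 {MT + ph / 2})'>Effect size (beta)</text>"
    )
    if data.signed:
        y0 = float(Y(0.0))
        out.append(
            f"<line x1='{ML}' y1='{y0:.2f}' x2='{ML + pw}' y2='{y0:.2f}' "
            "stroke='#999' stroke-dasharray='4 3'/>"
        )
    # power curves under the points
    for ci, curve in enumerate(data.curves):
        color = _CURVE_COLORS[ci % len(_CURVE_COLORS)]
        branches = [curve.beta_min] + ([-curve.beta_min] if curve.mirrored else [])
        for branch in branches:
            mask = np.abs(branch) <= ymax
            if not mask.any():
                continue
            xs, ys = X(curve.freqs[mask]), Y(branch[mask])
            d = " ".join(f"{px:.2f},{py:.2f}" for px, py in zip(xs, ys))
            out.append(
                f"<polyline class='power-curve' data-level='{curve.level:g}' "
                f"points='{d}' fill='none' stroke='{color}' stroke-width='1.8'/>"
            )
        xl = float(X(curve.freqs[-1]))
        yl = float(Y(curve.beta_min[-1]))
        out.append(
            f"<text x='{xl - 4:.2f}' y='{yl - 6:.2f}' text-anchor='end' "
            f"fill='{color}'>power {curve.level:g}</text>"
        )
    # points
    cmap = plt.get_cmap("viridis")
    for _, row in pts.iterrows():
        rgba = cmap(min(row["color_value"] / spec.color_cap, 1.0))
        fill = matplotlib.colors.to_hex(rgba)
        radius = float(np.sqrt(row["size"] / np.pi))
        attrs = " ".join(
            f"data-{f}='{html.escape(str(row[f]), quote=True)}'"
            for f in spec.hover_fields
        )
        title = html.escape(_hover_text(row, spec.hover_fields))
        out.append(
            f"<circle class='pt' cx='{float(X(row['x'])):.2f}' "
            f"cy='{float(Y(row['y'])):.2f}' r='{radius:.2f}' fill='{fill}' "
            f"{attrs}><title>{title}</title></circle>"
        )
    out.append("</svg>")
    out.append(
        f"<p>{len(pts)} variants; color = -log10(P) capped at "
        f"{spec.color_cap:g}; point area proportional to |beta|.</p>"
    )
    out.append("</body></html>")
    with open(os.fspath(path), "w") as fh:
        fh.write("\n".join(out) + "\n")
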