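"""Shift-visualization suite and its data-preparation ("baker") transforms.

Each baker turns the long prediction table into a plain tabular spec that a
plotting front end can render directly: pie arcs (angle spans encode
frequencies), moon ratios (illuminated fraction = frequency) and 10x10
waffle grids (one cell per percent).  Baselines use the observed
frequencies; changed climates use the smooth-corrected predictions, with
trend colours fixed to red = decreasing / green = increasing.  The plotting
functions are thin matplotlib renderings of those specs; all bakers are
pure functions of the prediction table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Rectangle, Wedge
from scipy.interpolate import RBFInterpolator

from .freq import PredictionTable
from .io import EnvTable, GeoTable
from .ordination import RedundancyAnalysis

__all__ = [
    "pie_baker",
    "moon_waxer",
    "waffle_baker",
    "shift_plots",
    "population_shift_plot",
    "surface_fit",
]

_TWO_PI = 2.0 * math.pi


def _frequencies(table: PredictionTable) -> pd.DataFrame:
    """Long frame of (population, locus, climate, freq, trend).

    Baseline rows carry the observed frequency; changed rows the corrected
    prediction and its trend.  Corrected frequencies outside [0, 1] are a
    contract violation (the caller passed the unbounded RDA frequency).
    """
    d = table.data
    bad = d[(d["Freq.e2"] < 0) | (d["Freq.e2"] > 1)]
    if len(bad):
        r = bad.iloc[0]
        raise ValueError(
            f"corrected frequency outside [0, 1] for population {r['population']!r}, "
            f"locus {r['locus']!r}: {r['Freq.e2']}; bakers require Freq.e2, never Freq.e1"
        )
    rows = []
    for _, r in d.iterrows():
        trend = "increasing" if r["increasing"] else "decreasing"
        rows.append((r["population"], r["locus"], "baseline", float(r["Allele.freq"]), "baseline"))
        rows.append((r["population"], r["locus"], "changed", float(r["Freq.e2"]), trend))
    return pd.DataFrame(rows, columns=["population", "locus", "climate", "freq", "trend"])


def pie_baker(table: PredictionTable, r0: float = 0.25, r1: float = 1.0) -> pd.DataFrame:
    """Arc specs for pie/donut rendering.

    Two arcs per population x locus x climate: the minor-allele arc spans
    ``freq * 2*pi`` starting at angle 0 (clockwise from 12 o'clock), the
    major-allele arc covers the remainder; ``r0``/``r1`` are the ring radii.
    """
    freqs = _frequencies(table)
    rows = []
    for _, r in freqs.iterrows():
        split = r["freq"] * _TWO_PI
        for allele, a0, a1 in (("minor", 0.0, split), ("major", split, _TWO_PI)):
            rows.append(
                {
                    "population": r["population"],
                    "locus": r["locus"],
                    "climate": r["climate"],
                    "allele": allele,
                    "start_angle": a0,
                    "end_angle": a1,
                    "r0": r0,
                    "r1": r1,
                    "trend": r["trend"],
                }
            )
    return pd.DataFrame(rows)


def moon_waxer(table: PredictionTable) -> pd.DataFrame:
    """Moon-ratio specs: illuminated fraction equals the minor-allele
    frequency; the complementary row carries 1 - freq."""
    freqs = _frequencies(table)
    rows = []
    for _, r in freqs.iterrows():
        for allele, ratio in (("minor", r["freq"]), ("major", 1.0 - r["freq"])):
            rows.append(
                {
                    "population": r["population"],
                    "locus": r["locus"],
                    "climate": r["climate"],
                    "allele": allele,
                    "ratio": ratio,
                    "trend": r["trend"],
                }
            )
    return pd.DataFrame(rows)


def waffle_baker(table: PredictionTable) -> pd.DataFrame:
    """10x10 waffle grids, one cell per percent.

    Minor cells = round-half-up(freq * 100), filled row-major from the
    top-left; every grid has exactly 100 cells.
    """
    freqs = _frequencies(table)
    rows = []
    for _, r in freqs.iterrows():
        minor_cells = int(math.floor(r["freq"] * 100 + 0.5))
        for cell in range(100):
            rows.append(
                {
                    "population": r["population"],
                    "locus": r["locus"],
                    "climate": r["climate"],
                    "cell": cell,
                    "row": cell // 10,
                    "col": cell % 10,
                    "fill": "minor" if cell < minor_cells else "major",
                    "trend": r["trend"],
                }
            )
    return pd.DataFrame(rows)


_TREND_COLOR = {"increasing": "tab:green", "decreasing": "tab:red", "baseline": "black"}


def _save(fig, out):
    if out is None:
        return
    out = str(out)
    stem = out.rsplit(".", 1)[0] if out.endswith((".png", ".svg")) else out
    fig.savefig(stem + ".png", dpi=150, bbox_inches="tight")
    fig.savefig(stem + ".svg", bbox_inches="tight")


def shift_plots(table: PredictionTable, style: str = "dot", mean_change: bool = False, out=None):
    """Render the frequency-shift figure in the requested style.

    One panel per locus (a single aggregated panel when ``mean_change``).
    The dot style shows the baseline frequency (black), the corrected
    changed-climate frequency (blue) and a vertical confidence segment.
    Returns the matplotlib figure; with ``out`` set, writes PNG and SVG.
    """
    if len(table.data) == 0:
        raise ValueError("empty prediction table")
    if style not in {"dot", "pie", "moon", "waffle"}:
        raise ValueError(f"unknown style {style!r}")
    data = table.data
    if mean_change:
        agg = data.groupby("population", sort=False).agg(
            {"Allele.freq": "mean", "Freq.e2": "mean", "LCL": "mean", "UCL": "mean"}
        )
        agg["increasing"] = agg["Freq.e2"] > agg["Allele.freq"]
        agg = agg.reset_index()
        agg["locus"] = "mean"
        for col in ("N", "A", "B", "Ap", "Bp", "N.e1", "Freq.e1"):
            agg[col] = data.groupby("population", sort=False)[col].mean().to_numpy()
        data = agg
        table = PredictionTable(data, climate_tag=table.climate_tag)
    loci = list(dict.fromkeys(data["locus"]))
    fig, axes = plt.subplots(1, len(loci), figsize=(4 * len(loci), 4), squeeze=False)
    if style == "dot":
        for ax, locus in zip(axes[0], loci):
            sub = data[data["locus"] == locus]
            ys = np.arange(len(sub))
            ax.vlines(sub["Freq.e2"], ys - 0.0, ys - 0.0, color="none")
            for y, (_, r) in zip(ys, sub.iterrows()):
                ax.plot([r["LCL"], r["UCL"]], [y, y], color="grey", lw=1.5, zorder=1)
                ax.plot(r["Allele.freq"], y, "o", color="black", zorder=2)
                ax.plot(r["Freq.e2"], y, "o", color="tab:blue", zorder=3)
            ax.set_yticks(ys, sub["population"])
            ax.set_xlabel("minor-allele frequency")
            ax.set_title(str(locus))
    elif style == "pie":
        arcs = pie_baker(table)
        for ax, locus in zip(axes[0], loci):
            sub = arcs[arcs["locus"] == locus]
            pops = list(dict.fromkeys(sub["population"]))
            for i, pop in enumerate(pops):
                for j, climate in enumerate(("baseline", "changed")):
                    rows = sub[(sub["population"] == pop) & (sub["climate"] == climate)]
                    cx, cy = 2.5 * j, -2.5 * i
                    for _, a in rows.iterrows():
                        color = (
                            _TREND_COLOR[a["trend"]] if a["allele"] == "minor" else "lightgrey"
                        )
                        # matplotlib wedges run counterclockwise from 3 o'clock;
                        # 90 - angle converts from clockwise-from-12
                        ax.add_patch(
                            Wedge(
                                (cx, cy),
                                a["r1"],
                                90 - math.degrees(a["end_angle"]),
                                90 - math.degrees(a["start_angle"]),
                                width=a["r1"] - a["r0"],
                                facecolor=color,
                                edgecolor="white",
                            )
                        )
                ax.text(-1.6, -2.5 * i, str(pop), ha="right", va="center", fontsize=8)
            ax.set_xlim(-4, 5)
            ax.set_ylim(-2.5 * len(pops), 2.5)
            ax.set_aspect("equal")
            ax.axis("off")
            ax.set_title(str(locus))
    elif style == "moon":
        moons = moon_waxer(table)
        for ax, locus in zip(axes[0], loci):
            sub = moons[(moons["locus"] == locus) & (moons["allele"] == "minor")]
            for i, (_, m) in enumerate(sub[sub["climate"] == "baseline"].iterrows()):
                ax.add_patch(Wedge((0, -2.5 * i), 1, 90, 90 + 360 * m["ratio"], facecolor="white", edgecolor="black"))
            for i, (_, m) in enumerate(sub[sub["climate"] == "changed"].iterrows()):
                ax.add_patch(
                    Wedge((2.5, -2.5 * i), 1, 90, 90 + 360 * m["ratio"], facecolor=_TREND_COLOR[m["trend"]], edgecolor="black")
                )
            npop = sub["population"].nunique()
            ax.set_xlim(-2, 4.5)
            ax.set_ylim(-2.5 * npop, 2.5)
            ax.set_aspect("equal")
            ax.axis("off")
            ax.set_title(str(locus))
    else:  # waffle
        waffles = waffle_baker(table)
        for ax, locus in zip(axes[0], loci):
            sub = waffles[waffles["locus"] == locus]
            pops = list(dict.fromkeys(sub["population"]))
            for i, pop in enumerate(pops):
                for j, climate in enumerate(("baseline", "changed")):
                    cells = sub[(sub["population"] == pop) & (sub["climate"] == climate)]
                    x0, y0 = 12 * j, -12 * i
                    for _, c in cells.iterrows():
                        if c["fill"] == "minor":
                            color = "black" if climate == "baseline" else _TREND_COLOR[c["trend"]]
                        else:
                            color = "lightgrey"
                        ax.add_patch(Rectangle((x0 + c["col"], y0 - c["row"]), 0.9, 0.9, facecolor=color))
            ax.set_xlim(-2, 24)
            ax.set_ylim(-12 * len(pops), 2)
            ax.set_aspect("equal")
            ax.axis("off")
            ax.set_title(str(locus))
    _save(fig, out)
    return fig


@dataclass
class ShiftOrdination:
    """Scores of populations under both climates plus the arrows between."""

    scores: pd.DataFrame  # columns: population, climate, axis1, axis2
    arrows: pd.DataFrame  # columns: population, x0, y0, dx, dy


def population_shift_plot(baseline: EnvTable, changed: EnvTable, method: str = "pca", out=None):
    """Ordination of populations under both climates with shift arrows.

    Baseline and changed rows are stacked and the variables standardized;
    ``pca`` ordinates the stack unconstrained, ``rda`` constrains it by the
    two-level climate factor (axis 1 = constrained axis, axis 2 = first
    residual axis).  Returns (figure, :class:`ShiftOrdination`).
    """
    if list(baseline.population_ids) != list(changed.population_ids):
        raise ValueError("baseline and changed tables list different populations")
    if list(baseline.variable_names) != list(changed.variable_names):
        raise ValueError("baseline and changed tables list different variables")
    g = len(baseline.population_ids)
    stacked = np.vstack([baseline.values.to_numpy(float), changed.values.to_numpy(float)])
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (stacked - mu) / sd
    if method == "pca":
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        pts = u[:, :2] * s[:2]
    elif method == "rda":
        climate = np.r_[np.zeros(g), np.ones(g)][:, None]
        model = RedundancyAnalysis().fit(climate, z)
        ax1 = model.site_scores_[:, 0]
        ur, sr, _ = np.linalg.svd(model.residual_, full_matrices=False)
        ax2 = ur[:, 0] * sr[0]
        pts = np.column_stack([ax1, ax2])
    else:
        raise ValueError(f"unknown method {method!r}")
    pops = list(baseline.population_ids)
    scores = pd.DataFrame(
        {
            "population": pops * 2,
            "climate": ["baseline"] * g + ["changed"] * g,
            "axis1": pts[:, 0],
            "axis2": pts[:, 1],
        }
    )
    arrows = pd.DataFrame(
        {
            "population": pops,
            "x0": pts[:g, 0],
            "y0": pts[:g, 1],
            "dx": pts[g:, 0] - pts[:g, 0],
            "dy": pts[g:, 1] - pts[:g, 1],
        }
    )
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(pts[:g, 0], pts[:g, 1], color="black", label="baseline")
    ax.scatter(pts[g:, 0], pts[g:, 1], color="tab:blue", label="changed")
    for _, a in arrows.iterrows():
        ax.annotate(
            "",
            xy=(a["x0"] + a["dx"], a["y0"] + a["dy"]),
            xytext=(a["x0"], a["y0"]),
            arrowprops={"arrowstyle": "->", "color": "grey"},
        )
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    ax.legend()
    ax.set_title(f"population shift ({method.upper()})")
    _save(fig, out)
    return fig, ShiftOrdination(scores=scores, arrows=arrows)


@dataclass
class SurfaceResult:
    grid: pd.DataFrame  # long format: longitude, latitude, fitted
    figure: object


def surface_fit(
    geo: GeoTable,
    freqs: pd.Series,
    grid_resolution: int = 41,
    smoothing: float = 0.0,
    trend: pd.Series | None = None,
    out=None,
) -> SurfaceResult:
    """Smoothed geographic surface of per-population frequencies.

    Fits a thin-plate spline (with optional smoothing penalty) of frequency
    on (longitude, latitude) and evaluates it on a ``grid_resolution`` x
    ``grid_resolution`` grid over the bounding box.  Circle sizes encode the
    population frequencies; ``trend`` (a boolean increasing flag per
    population) colours them red/green.
    """
    coords = geo.coords.to_numpy(float)
    freqs = pd.Series(freqs).reindex(geo.population_ids)
    if freqs.isna().any():
        raise ValueError("frequencies missing for some populations")
    if len(coords) < 3:
        raise ValueError("surface fitting needs at least 3 populations")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(coords)), coords])) < 3:
        raise ValueError("population locations are collinear; surface undefined")
    rbf = RBFInterpolator(coords, freqs.to_numpy(float), kernel="thin_plate_spline", smoothing=smoothing)
    lon = np.linspace(coords[:, 0].min(), coords[:, 0].max(), grid_resolution)
    lat = np.linspace(coords[:, 1].min(), coords[:, 1].max(), grid_resolution)
    gx, gy = np.meshgrid(lon, lat)
    fitted = rbf(np.column_stack([gx.ravel(), gy.ravel()]))
    grid = pd.DataFrame({"longitude": gx.ravel(), "latitude": gy.ravel(), "fitted": fitted})
    fig, ax = plt.subplots(figsize=(6, 5))
    cs = ax.contourf(gx, gy, fitted.reshape(gx.shape), levels=12, cmap="viridis", alpha=0.8)
    fig.colorbar(cs, ax=ax, label="frequency")
    if trend is not None:
        colors = [
            "tab:green" if bool(trend.get(p, False)) else "tab:red" for p in geo.population_ids
        ]
    else:
        colors = "black"
    ax.scatter(coords[:, 0], coords[:, 1], s=20 + 300 * freqs.to_numpy(float), c=colors, edgecolor="white")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    _save(fig, out)
    return SurfaceResult(grid=grid, figure=fig)
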