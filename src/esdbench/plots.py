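"""Visualizations of effect-size distributions.

Four plots: the plain ESD histogram; the histogram annotated with the
small/medium/large benchmark lines and bootstrap CI ribbons; the SESOI
split (share of the absolute ESD at or above a smallest effect of
interest); and the "iceberg" plot contrasting the raw ESD (above the
axis) with the publication-bias-adjusted ESD mirrored below it, each with
its summary-effect diamond.

Every function returns a machine-readable manifest (bin edges, counts,
line positions, diamond coordinates) alongside the figure, so content can
be asserted without pixel comparison.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless backend; figures go to files
import matplotlib.pyplot as plt
import numpy as np

from .benchmarks import BenchmarkMethod, benchmark_table, sesoi_split
from .core import ESDataset, ValidationError
from .meta import LimitMeta

__all__ = [
    "PlotFormat",
    "PlotSpec",
    "HistogramSummary",
    "plot_esd",
    "plot_esd_benchmarks",
    "plot_sesoi",
    "plot_iceberg",
]

RAW_COLOR = "#9ecae1"  # light blue
ADJ_COLOR = "#2171b5"  # dark blue
BELOW_COLOR = "#bdbdbd"  # grey
CI_COLOR = "red"


class PlotFormat(str, enum.Enum):
    PNG = "png"
    SVG = "svg"
    PDF = "pdf"


@dataclass(frozen=True)
class PlotSpec:
    """Rendering options shared by all ESD plots."""

    bin_width: float = 0.1
    es_label: str = "Hedges' g"
    absolute: bool = False
    output_path: str | Path | None = None
    format: PlotFormat = PlotFormat.PNG

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        object.__setattr__(self, "format", PlotFormat(self.format))


@dataclass(frozen=True)
class HistogramSummary:
    """Zero-anchored histogram: edges (len = bins+1) and counts."""

    edges: tuple[float, ...]
    counts: tuple[int, ...]

    @property
    def n(self) -> int:
        return int(sum(self.counts))


def _bin_indices(values: np.ndarray, width: float) -> np.ndarray:
    """Half-open [a, a + width) bin index of each value, bins anchored at 0.

    Boundary values are snapped so that a value exactly on an edge falls
    in the bin it opens (e.g. 0.1 with width 0.1 lands in [0.1, 0.2)),
    despite floating-point division noise.
    """
    r = values / width
    idx = np.floor(r)
    near = np.isclose(r, np.round(r), rtol=0.0, atol=1e-9)
    idx[near] = np.round(r[near])
    return idx.astype(int)


def histogram(values: np.ndarray, width: float) -> HistogramSummary:
    idx = _bin_indices(np.asarray(values, dtype=float), width)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    edges = (np.arange(lo, hi + 2) * width).tolist()
    return HistogramSummary(tuple(edges), tuple(int(c) for c in counts))


def _save(fig, spec: PlotSpec, manifest: dict) -> Path | None:
    path = None
    if spec.output_path is not None:
        path = Path(spec.output_path)
        if path.suffix.lstrip(".") != spec.format.value:
            path = path.with_suffix("." + spec.format.value)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path)
        sidecar = path.with_suffix(path.suffix + ".manifest.json")
        sidecar.write_text(json.dumps(manifest, indent=2))
    plt.close(fig)
    return path


def _bars(ax, hist: HistogramSummary, color: str, sign: int = 1) -> None:
    lefts = np.array(hist.edges[:-1])
    ax.bar(
        lefts,
        sign * np.array(hist.counts),
        width=hist.edges[1] - hist.edges[0],
        align="edge",
        color=color,
        edgecolor="white",
        linewidth=0.5,
    )


def plot_esd(ds: ESDataset, spec: PlotSpec = PlotSpec()) -> tuple[Path | None, dict]:
    """Histogram of the ESD; returns (file path, manifest)."""
    values = np.abs(ds.yi) if spec.absolute else ds.yi
    hist = histogram(values, spec.bin_width)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    _bars(ax, hist, RAW_COLOR)
    ax.set_xlabel(spec.es_label)
    ax.set_ylabel("Number of effects")
    manifest = {
        "kind": "esd",
        "n": hist.n,
        "bin_edges": list(hist.edges),
        "counts": list(hist.counts),
        "absolute": spec.absolute,
    }
    return _save(fig, spec, manifest), manifest


def plot_esd_benchmarks(
    ds: ESDataset,
    spec: PlotSpec = PlotSpec(absolute=True),
    method: BenchmarkMethod | str = BenchmarkMethod.QUADS,
    ci: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
    weighted: bool = False,
) -> tuple[Path | None, dict]:
    """Absolute-ESD histogram with benchmark lines and optional CI ribbons.

    The vertical lines sit at exactly the values ``benchmark_table`` would
    report for the same options and seed; annotation states them to 2 dp.
    """
    table = benchmark_table(
        ds,
        method=method,
        absolute=spec.absolute,
        weighted=weighted,
        ci=ci,
        n_boot=n_boot,
        seed=seed,
    )
    ests = table.overall_row.estimates
    values = np.abs(ds.yi) if spec.absolute else ds.yi
    hist = histogram(values, spec.bin_width)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    _bars(ax, hist, RAW_COLOR)
    ribbons = []
    for est in ests:
        if ci and est.ci_low is not None:
            ax.axvspan(est.ci_low, est.ci_high, color=CI_COLOR, alpha=0.2)
            ribbons.append([est.ci_low, est.ci_high])
        ax.axvline(est.value, color="black", linestyle="--", linewidth=1)
    labels = ("small", "medium", "large")
    text = ", ".join(
        f"{lab} = {est.value:.2f}" for lab, est in zip(labels, ests)
    )
    ax.set_title(text, fontsize=10)
    ax.set_xlabel(spec.es_label)
    ax.set_ylabel("Number of effects")
    manifest = {
        "kind": "benchmarks",
        "n": hist.n,
        "bin_edges": list(hist.edges),
        "counts": list(hist.counts),
        "lines": [est.value for est in ests],
        "ribbons": ribbons,
        "annotation": text,
        "method": BenchmarkMethod(method).value,
    }
    return _save(fig, spec, manifest), manifest


def plot_sesoi(
    ds: ESDataset, spec: PlotSpec, sesoi: float
) -> tuple[Path | None, dict, tuple[float, float]]:
    """Two-color absolute-ESD histogram split at the SESOI.

    Returns (path, manifest, (prop_below, prop_at_or_above)); the
    proportions equal :func:`esdbench.benchmarks.sesoi_split` exactly.
    """
    values = np.abs(ds.yi)
    props = sesoi_split(values, sesoi, absolute=False)
    hist = histogram(values, spec.bin_width)
    edges = np.array(hist.edges)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    # split each bar at the sesoi by counting below/at-or-above per bin
    idx = _bin_indices(values, spec.bin_width)
    lo = int(round(edges[0] / spec.bin_width))
    below = np.zeros(len(hist.counts))
    above = np.zeros(len(hist.counts))
    for v, i in zip(values, idx):
        (above if v >= sesoi else below)[i - lo] += 1
    w = spec.bin_width
    ax.bar(edges[:-1], below, width=w, align="edge", color=BELOW_COLOR)
    ax.bar(edges[:-1], above, width=w, align="edge", bottom=below, color=ADJ_COLOR)
    ax.axvline(sesoi, color="black", linestyle="--", linewidth=1)
    annotation = (
        f"{100 * props[0]:.0f}% below {sesoi:g}, "
        f"{100 * props[1]:.0f}% at or above"
    )
    ax.set_title(annotation, fontsize=10)
    ax.set_xlabel(spec.es_label)
    ax.set_ylabel("Number of effects")
    manifest = {
        "kind": "sesoi",
        "n": hist.n,
        "bin_edges": list(hist.edges),
        "counts": list(hist.counts),
        "sesoi": sesoi,
        "prop_below": props[0],
        "prop_at_or_above": props[1],
        "annotation": annotation,
    }
    return _save(fig, spec, manifest), manifest, props


def plot_iceberg(ds: ESDataset, spec: PlotSpec = PlotSpec()) -> tuple[Path | None, dict]:
    """Raw ESD above the axis, bias-adjusted ESD mirrored below.

    Each half carries a diamond at its summary effect whose width spans
    the 95% CI: random-effects summary on top, limit-meta adjusted
    summary below. Both halves share the bin width and conserve n.
    """
    fit = LimitMeta.from_dataset(ds).fit()
    raw_hist = histogram(ds.yi, spec.bin_width)
    adj_hist = histogram(np.asarray(fit.shrunken), spec.bin_width)
    mu_raw, ci_raw = fit.unadjusted_summary
    mu_adj, ci_adj = fit.adjusted_summary

    fig, ax = plt.subplots(figsize=(7, 5.5))
    _bars(ax, raw_hist, RAW_COLOR, sign=1)
    _bars(ax, adj_hist, ADJ_COLOR, sign=-1)
    ax.axhline(0, color="black", linewidth=0.8)
    ymax = max(raw_hist.counts)
    for mu, (lo, hi), y in ((mu_raw, ci_raw, 0.6 * ymax), (mu_adj, ci_adj, -0.6 * ymax)):
        h = 0.08 * ymax
        ax.fill(
            [lo, mu, hi, mu], [y, y + h, y, y - h], color="black", zorder=5
        )
    ax.set_xlabel(spec.es_label)
    ax.set_ylabel("Number of effects (adjusted below axis)")
    manifest = {
        "kind": "iceberg",
        "n": raw_hist.n,
        "raw": {"bin_edges": list(raw_hist.edges), "counts": list(raw_hist.counts)},
        "adjusted": {
            "bin_edges": list(adj_hist.edges),
            "counts": list(adj_hist.counts),
        },
        "diamonds": {
            "raw": {"center": mu_raw, "ci": list(ci_raw)},
            "adjusted": {"center": mu_adj, "ci": list(ci_adj)},
        },
        "alpha": fit.alpha,
        "beta": fit.beta,
        "tau2": fit.tau2,
    }
    return _save(fig, spec, manifest), manifest
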