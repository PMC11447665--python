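"""Explanation views: waterfall, relevance coefficients, saliency map, beeswarm.

Each view is computed first as a plain data structure (exportable as
delimited text for headless inspection) and rendered separately with
matplotlib.  Positive contributions are drawn red, negative blue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .shap_zones import Attribution
from .spectra import SpectraSet, Spectrum
from .zones import ZoneSet

__all__ = [
    "WaterfallData",
    "SummaryData",
    "waterfall_data",
    "saliency_data",
    "summary_data",
    "render",
    "plot_waterfall",
    "plot_relevance",
    "plot_saliency",
    "plot_summary",
    "plot_zone_overlay",
]

_POS, _NEG = "#d62728", "#1f77b4"  # red positive, blue negative
_FORMATS = ("png", "svg")


@dataclass
class WaterfallData:
    """Ordered top-k zone contributions plus a grouped remainder row.

    rows + remainder telescope from base_value to prediction:
    sum(contribution) + remainder = prediction - base_value.
    """

    rows: list[tuple[str, float]]
    remainder: float
    n_remainder_zones: int
    base_value: float
    prediction: float

    def to_frame(self) -> pd.DataFrame:
        rows = self.rows + [
            (f"{self.n_remainder_zones} other zones", self.remainder)
        ]
        return pd.DataFrame(rows, columns=["zone", "contribution"])


@dataclass
class SummaryData:
    """Beeswarm summary columns: per-zone values and intensity colors.

    ``values[i, j]`` is the attribution of ordered zone j for spectrum i;
    ``colors`` holds the min-max normalized zone mean intensities in [0, 1]
    (degenerate all-equal columns map to 0).  ``order`` gives the original
    zone index of each column, sorted by descending mean |value|.
    """

    zone_labels: list[str]
    values: np.ndarray
    colors: np.ndarray
    order: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for j, lab in enumerate(self.zone_labels):
            for i in range(self.values.shape[0]):
                recs.append((lab, self.values[i, j], self.colors[i, j]))
        return pd.DataFrame(recs, columns=["zone", "value", "color"])


def _rank_order(att: Attribution) -> np.ndarray:
    """Zone order by descending |phi|, ties broken by ascending zone lo."""
    los = np.array([z.lo for z in att.zone_set])
    return np.lexsort((los, -np.abs(att.values)))


def waterfall_data(a: Attribution, top_k: int = 9) -> WaterfallData:
    """Top-k zones by |phi| plus the summed remainder.

    Only additive (SHAP) attributions are accepted: LIME coefficients do not
    decompose the base-to-prediction path, so rendering them as a waterfall
    would be misleading and is refused.
    """
    if a.method == "lime":
        raise ValueError(
            "waterfall plots require additive attributions; LIME coefficients "
            "are not additive and cannot explain the path from base_value to "
            "the prediction"
        )
    order = _rank_order(a)
    shown = order[:top_k]
    hidden = order[top_k:]
    rows = [(a.zone_set[int(k)].label, float(a.values[k])) for k in shown]
    return WaterfallData(
        rows=rows,
        remainder=float(a.values[hidden].sum()),
        n_remainder_zones=int(hidden.size),
        base_value=a.base_value,
        prediction=a.prediction,
    )


def saliency_data(a: Attribution) -> np.ndarray:
    """Per-wavenumber signed relevance in [-1, 1], piecewise constant per zone.

    Each grid point carries its zone's phi divided by max|phi|; an all-zero
    attribution yields the all-zero map (no division by zero).
    """
    scale = float(np.max(np.abs(a.values)))
    levels = a.values / scale if scale > 0 else np.zeros_like(a.values)
    return levels[a.zone_set.point_to_zone()]


def summary_data(atts: list[Attribution], ds: SpectraSet) -> SummaryData:
    """Dataset-level beeswarm columns, zones ordered by mean |phi| descending.

    The color scalar of spectrum i in zone j is the zone mean intensity,
    min-max normalized across the dataset within the zone.
    """
    if not atts:
        raise ValueError("no attributions")
    zs = atts[0].zone_set
    for a in atts[1:]:
        if a.zone_set is not zs and [
            (z.start, z.end) for z in a.zone_set
        ] != [(z.start, z.end) for z in zs]:
            raise ValueError("attributions use mixed zone sets")
    if ds.n_spectra != len(atts):
        raise ValueError("dataset rows do not align with attributions")
    values = np.stack([a.values for a in atts])
    zmeans = zs.zone_means(ds.matrix)
    lo, hi = zmeans.min(axis=0), zmeans.max(axis=0)
    span = hi - lo
    colors = np.zeros_like(zmeans)
    ok = span > 0
    colors[:, ok] = (zmeans[:, ok] - lo[ok]) / span[ok]
    mean_abs = np.abs(values).mean(axis=0)
    los = np.array([z.lo for z in zs])
    order = np.lexsort((los, -mean_abs))
    return SummaryData(
        zone_labels=[zs[int(k)].label for k in order],
        values=values[:, order],
        colors=colors[:, order],
        order=order,
    )


# ---------------------------------------------------------------------------
# rendering


def _check_format(path: Path, fmt: str | None) -> str:
    fmt = (fmt or path.suffix.lstrip(".") or "png").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown image format {fmt!r}; supported: {_FORMATS}")
    return fmt


def plot_waterfall(wd: WaterfallData, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _check_format(path, fmt)
    rows = wd.rows + [(f"{wd.n_remainder_zones} other zones", wd.remainder)]
    labels = [r[0] for r in rows]
    contribs = np.array([r[1] for r in rows])
    # telescoping left edges from the prediction downward
    fig, ax = plt.subplots(figsize=(7, 0.5 * len(rows) + 2))
    cum = wd.prediction
    for i, c in enumerate(contribs):
        ax.barh(i, c, left=cum - c, color=_POS if c >= 0 else _NEG, height=0.7)
        cum -= c
    ax.axvline(wd.base_value, color="gray", lw=0.8, ls="--")
    ax.axvline(wd.prediction, color="black", lw=0.8, ls="--")
    ax.set_yticks(range(len(rows)), labels)
    ax.invert_yaxis()
    ax.set_xlabel(
        f"model output (E[f(x)]≈{wd.base_value:.3f} → f(x)={wd.prediction:.3f})"
    )
    fig.tight_layout()
    fig.savefig(path, format=fmt)
    plt.close(fig)


def plot_relevance(a: Attribution, path: str | Path, fmt: str | None = None) -> None:
    """Relevance-coefficient plot: one bar per zone at its wavenumber span."""
    path = Path(path)
    fmt = _check_format(path, fmt)
    fig, ax = plt.subplots(figsize=(8, 3))
    for z, v in zip(a.zone_set, a.values):
        ax.bar((z.lo + z.hi) / 2, v, width=(z.hi - z.lo) * 0.9,
               color=_POS if v >= 0 else _NEG)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("zone coefficient")
    fig.tight_layout()
    fig.savefig(path, format=fmt)
    plt.close(fig)


def plot_saliency(
    a: Attribution, path: str | Path, fmt: str | None = None,
    spectrum: Spectrum | None = None,
) -> None:
    """Normalized saliency map, optionally overlaid on the spectrum."""
    path = Path(path)
    fmt = _check_format(path, fmt)
    sal = saliency_data(a)
    grid = a.zone_set.grid
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.fill_between(grid, sal, 0, where=sal >= 0, color=_POS, alpha=0.6,
                    step="mid")
    ax.fill_between(grid, sal, 0, where=sal < 0, color=_NEG, alpha=0.6,
                    step="mid")
    if spectrum is not None:
        ax2 = ax.twinx()
        ax2.plot(spectrum.grid, spectrum.intensities, color="gray", lw=0.7)
        ax2.set_yticks([])
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("normalized relevance")
    fig.tight_layout()
    fig.savefig(path, format=fmt)
    plt.close(fig)


def plot_summary(sd: SummaryData, path: str | Path, fmt: str | None = None,
                 max_zones: int = 20, seed: int = 0) -> None:
    """Beeswarm summary: one jittered row per zone, colored by intensity."""
    path = Path(path)
    fmt = _check_format(path, fmt)
    k = min(max_zones, len(sd.zone_labels))
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(7, 0.35 * k + 2))
    cmap = plt.get_cmap("cool")  # blue (low) → pink/magenta (high)
    for j in range(k):
        yjit = k - 1 - j + rng.uniform(-0.25, 0.25, size=sd.values.shape[0])
        ax.scatter(sd.values[:, j], yjit, c=cmap(sd.colors[:, j]), s=12,
                   edgecolors="none")
    ax.axvline(0, color="black", lw=0.8)
    ax.set_yticks(range(k - 1, -1, -1), sd.zone_labels[:k])
    ax.set_xlabel("SHAP value (impact on model output)")
    sm = plt.cm.ScalarMappable(cmap=cmap)
    cb = fig.colorbar(sm, ax=ax, ticks=[0, 1])
    cb.ax.set_yticklabels(["low", "high"])
    cb.set_label("zone intensity")
    fig.tight_layout()
    fig.savefig(path, format=fmt)
    plt.close(fig)


def plot_zone_overlay(
    s: Spectrum, zs: ZoneSet, path: str | Path,
    peaks: np.ndarray | None = None, valleys: np.ndarray | None = None,
    fmt: str | None = None,
) -> None:
    """Spectrum with zone boundaries: red lines at peaks, green at valleys."""
    path = Path(path)
    fmt = _check_format(path, fmt)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(s.grid, s.intensities, color="black", lw=0.8)
    if peaks is not None:
        for p in peaks:
            ax.axvline(p, color="red", lw=0.7)
    if valleys is not None:
        for v in valleys:
            ax.axvline(v, color="green", lw=0.7)
    for z in zs.zones[1:]:
        ax.axvline(z.lo, color="green", lw=0.4, ls=":")
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("intensity (a.u.)")
    fig.tight_layout()
    fig.savefig(path, format=fmt)
    plt.close(fig)


def render(data, path: str | Path, fmt: str | None = None, **kw) -> None:
    """Dispatch a plot-data object to its renderer and write an image file."""
    if isinstance(data, WaterfallData):
        plot_waterfall(data, path, fmt)
    elif isinstance(data, SummaryData):
        plot_summary(data, path, fmt, **kw)
    elif isinstance(data, Attribution):
        plot_relevance(data, path, fmt)
    else:
        raise TypeError(f"don't know how to render {type(data).__name__}")
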