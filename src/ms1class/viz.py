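"""Diagnostic graphics: Van Krevelen scatter, DBE distributions, range bars.

Coordinate mapping (pure, unit-testable) is separated from rendering
(matplotlib, smoke-tested).  Axis convention throughout: x = O/C,
y = H/C — the conventional Van Krevelen orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .knowledge_base import KnowledgeBase

__all__ = [
    "PlotDataset",
    "vk_points",
    "dbe_distribution",
    "class_palette",
    "render",
    "PLOT_KINDS",
]

PLOT_KINDS = ("vk", "dbe_hist", "range_bars", "box", "vk3d")


@dataclass
class PlotDataset:
    """Plot-ready point set: one row per formula with finite coordinates."""

    points: pd.DataFrame  # columns: oc, hc, dbe, label, c
    excluded_count: int = 0
    styling: dict = field(default_factory=dict)


def vk_points(table: pd.DataFrame) -> PlotDataset:
    """Extract Van Krevelen coordinates from an annotated table.

    Requires ``hc`` and ``oc`` columns; ``dbe``, ``c`` and class labels
    (``top1_class``) are carried along when present.  Rows with undefined
    or non-finite ratios are excluded and counted.
    """
    for col in ("hc", "oc"):
        if col not in table.columns:
            raise ValueError(f"annotated table lacks required column {col!r}")
    df = table.copy()
    df["hc"] = pd.to_numeric(df["hc"], errors="coerce")
    df["oc"] = pd.to_numeric(df["oc"], errors="coerce")
    keep = np.isfinite(df["hc"]) & np.isfinite(df["oc"])
    excluded = int((~keep).sum())
    df = df[keep]
    points = pd.DataFrame({
        "oc": df["oc"].to_numpy(dtype=float),
        "hc": df["hc"].to_numpy(dtype=float),
        "dbe": pd.to_numeric(df["dbe"], errors="coerce").to_numpy()
        if "dbe" in df.columns else np.full(len(df), np.nan),
        "label": df["top1_class"].astype(str).to_numpy()
        if "top1_class" in df.columns else np.array(["unclassified"] * len(df)),
        "c": pd.to_numeric(df["c"], errors="coerce").to_numpy()
        if "c" in df.columns else np.full(len(df), np.nan),
    })
    return PlotDataset(points=points, excluded_count=excluded)


def dbe_distribution(
    table: pd.DataFrame, bin_width: float = 0.5
) -> dict[str, dict[float, int]]:
    """Per-class DBE histogram counts.

    ``bin_width`` of 0.5 (default) resolves half-integer alkaloid DBE
    values into their own bins; values are assigned to bins by the floor
    rule ``bin = floor(dbe / width) * width``.  Total counts over all
    classes equal the number of rows with a finite DBE.
    """
    if bin_width not in (0.5, 1.0):
        raise ValueError("bin_width must be 0.5 or 1.0")
    if "dbe" not in table.columns:
        raise ValueError("annotated table lacks required column 'dbe'")
    labels = (
        table["top1_class"].astype(str)
        if "top1_class" in table.columns
        else pd.Series(["all"] * len(table), index=table.index)
    )
    out: dict[str, dict[float, int]] = {}
    for dbe_val, label in zip(pd.to_numeric(table["dbe"], errors="coerce"), labels):
        if not np.isfinite(dbe_val):
            continue
        b = math.floor(dbe_val / bin_width) * bin_width
        out.setdefault(label, {})
        out[label][b] = out[label].get(b, 0) + 1
    return out


def class_palette(kb: KnowledgeBase) -> dict[str, tuple]:
    """Fixed, reproducible color per class (tab20 cycled), plus grey for unclassified."""
    cmap = plt.get_cmap("tab20")
    palette = {name: cmap(i % 20) for i, name in enumerate(kb.names())}
    palette["unclassified"] = (0.6, 0.6, 0.6, 1.0)
    return palette


def _render_vk(ds: PlotDataset, ax, palette):
    for label, sub in ds.points.groupby("label", sort=True):
        ax.scatter(sub["oc"], sub["hc"], s=18, alpha=0.8,
                   color=palette.get(label, None), label=label)
    ax.set_xlabel("O/C")
    ax.set_ylabel("H/C")
    ax.set_title("Van Krevelen diagram")
    if ds.points["label"].nunique() > 1:
        ax.legend(fontsize=7, loc="best")


def _render_dbe_hist(ds: PlotDataset, ax, palette, bin_width=0.5):
    hist = dbe_distribution(ds.points.rename(columns={"label": "top1_class"}),
                            bin_width=bin_width)
    for label in sorted(hist):
        bins = sorted(hist[label])
        ax.bar(bins, [hist[label][b] for b in bins], width=bin_width * 0.9,
               alpha=0.6, color=palette.get(label, None), label=label)
    ax.set_xlabel("DBE")
    ax.set_ylabel("number of compounds")
    ax.set_title("DBE distribution")
    if len(hist) > 1:
        ax.legend(fontsize=7)


def _render_range_bars(kb: KnowledgeBase, ax):
    rows = [c for c in kb.classes if c.hc_min is not None or c.oc_min is not None]
    ys = np.arange(len(rows))
    for y, c in zip(ys, rows):
        if c.hc_min is not None:
            ax.plot([c.hc_min, c.hc_max], [y + 0.15] * 2, lw=5,
                    color="tab:blue", solid_capstyle="butt")
        if c.oc_min is not None:
            ax.plot([c.oc_min, c.oc_max], [y - 0.15] * 2, lw=5,
                    color="tab:orange", solid_capstyle="butt")
    ax.set_yticks(ys, [c.name for c in rows], fontsize=7)
    ax.set_xlabel("atomic ratio")
    ax.set_title("H/C (blue) and O/C (orange) ranges per class")


def _render_box(ds: PlotDataset, ax):
    groups = [(label, sub["dbe"].dropna().to_numpy())
              for label, sub in ds.points.groupby("label", sort=True)]
    groups = [(l, v) for l, v in groups if len(v)]
    ax.boxplot([v for _, v in groups], tick_labels=[l for l, _ in groups])
    ax.set_ylabel("DBE")
    ax.tick_params(axis="x", labelrotation=75, labelsize=7)
    ax.set_title("DBE by class")


def _render_vk3d(ds: PlotDataset, fig, palette):
    ax = fig.add_subplot(projection="3d")
    for label, sub in ds.points.groupby("label", sort=True):
        ax.scatter(sub["oc"], sub["hc"], sub["dbe"], s=14,
                   color=palette.get(label, None), label=label)
    ax.set_xlabel("O/C")
    ax.set_ylabel("H/C")
    ax.set_zlabel("DBE")
    if ds.points["label"].nunique() > 1:
        ax.legend(fontsize=7)


def render(
    dataset: PlotDataset | KnowledgeBase,
    kind: str,
    path: str | Path,
    kb: KnowledgeBase | None = None,
    bin_width: float = 0.5,
) -> Path:
    """Render a dataset to PNG or SVG (chosen by file extension).

    ``kind`` is one of ``vk``, ``dbe_hist``, ``box``, ``vk3d`` (all take a
    :class:`PlotDataset`) or ``range_bars`` (takes a
    :class:`KnowledgeBase`).  Layout is deterministic for fixed inputs.
    """
    if kind not in PLOT_KINDS:
        raise ValueError(f"unknown plot kind {kind!r}; choose from {PLOT_KINDS}")
    path = Path(path)
    from .knowledge_base import default_kb

    palette = class_palette(kb if kb is not None else default_kb())
    fig = plt.figure(figsize=(7, 5), dpi=120)
    try:
        if kind == "range_bars":
            if not isinstance(dataset, KnowledgeBase):
                raise ValueError("range_bars renders a KnowledgeBase")
            _render_range_bars(dataset, fig.add_subplot())
        elif kind == "vk3d":
            _render_vk3d(dataset, fig, palette)
        elif kind == "vk":
            _render_vk(dataset, fig.add_subplot(), palette)
        elif kind == "dbe_hist":
            _render_dbe_hist(dataset, fig.add_subplot(), palette, bin_width)
        elif kind == "box":
            _render_box(dataset, fig.add_subplot())
        fig.tight_layout()
        fig.savefig(path, metadata={"Software": None} if path.suffix == ".png" else None)
    finally:
        plt.close(fig)
    return path
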