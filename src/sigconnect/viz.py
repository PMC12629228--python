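"""Result visualizations: radar, GSEA and Venn plots.

Each plotting function first builds a :class:`PlotData` — named tables
sufficient to redraw the figure without the original report — and the image
renderers consume only that.  Tables are the contract; images are side
effects.

* **radar** — one reference signature's directional percentile rank
  (0–100) on each of the six method axes, in fixed order, so the six
  heterogeneous score scales are comparable on one polygon.  An ungated
  WTCS axis is drawn at 0 and flagged.
* **GSEA** — the weighted running sums of the query up and down extreme
  sets along one reference ranking, with hit positions; the enrichment
  scores equal the extrema of the emitted curves.
* **Venn** — overlap of the per-method vote sets across 2–6 chosen
  methods (all ``2^m - 1`` region counts; circle diagrams for 2–3 sets,
  a region bar chart beyond that).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ExtremeGeneSet, Signature
from .scoring import METHODS, _running_sum, _signed_extremum
from .screening import ScreenReport

__all__ = [
    "PlotData",
    "radar_data",
    "gsea_data",
    "venn_data",
    "plot_radar",
    "plot_gsea",
    "plot_venn",
    "render",
]


@dataclass
class PlotData:
    """Plot-ready tables for one figure."""

    kind: str  # radar | gsea | venn
    tables: dict[str, pd.DataFrame]
    title: str = ""
    notes: dict[str, str] = field(default_factory=dict)


def radar_data(report: ScreenReport, sig_id: str) -> PlotData:
    """Six-axis percentile profile of one reference in the screen."""
    result = report.get(sig_id)  # raises KeyError on unknown sig_id
    rows = []
    for m in METHODS:
        rows.append(
            {
                "method": m,
                "percentile": result.percentiles.get(m, 0.0),
                "vote": result.votes.get(m, 0),
                "gated": int(m != "wtcs" or result.gated),
            }
        )
    axes = pd.DataFrame(rows, columns=["method", "percentile", "vote", "gated"])
    notes = {"meta_score": str(result.meta_score), "direction": report.direction}
    if not result.gated:
        notes["wtcs"] = "ungated (shown as 0)"
    return PlotData("radar", {"axes": axes}, title=f"{sig_id} vs {report.query_id}", notes=notes)


def gsea_data(extremes: ExtremeGeneSet, ref: Signature, weight_exponent: float = 1.0) -> PlotData:
    """Running-sum curves of the query extreme sets along one reference
    ranking; the reported enrichment scores are the curves' signed
    extrema (identical to the standalone enrichment-score computation)."""
    tables: dict[str, pd.DataFrame] = {}
    notes: dict[str, str] = {}
    for label, gene_set in (("up", extremes.up), ("down", extremes.down)):
        order, hits, running = _running_sum(gene_set, ref.gene_ids, ref.z, weight_exponent)
        tables[f"{label}_running"] = pd.DataFrame(
            {
                "position": np.arange(1, len(order) + 1),
                "gene_id": [ref.gene_ids[i] for i in order],
                "ref_z": ref.z[order],
                "hit": hits.astype(int),
                "running_sum": running,
            }
        )
        notes[f"es_{label}"] = repr(_signed_extremum(running))
    return PlotData("gsea", tables, title=f"extreme sets vs {ref.sig_id}", notes=notes)


def venn_data(report: ScreenReport, methods: Sequence[str] = METHODS) -> PlotData:
    """Vote-set overlaps for 2–6 methods: member lists and every
    non-empty-combination region count (inclusion–exclusion complete)."""
    methods = list(methods)
    if not 2 <= len(methods) <= 6:
        raise ValueError("choose between 2 and 6 methods for a Venn plot")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    vote_sets = {
        m: {r.sig_id for r in report.results if r.votes.get(m, 0) == 1} for m in methods
    }
    members = pd.DataFrame(
        [
            {"method": m, "sig_id": s}
            for m in methods
            for s in sorted(vote_sets[m])
        ],
        columns=["method", "sig_id"],
    )
    rows = []
    for mask in range(1, 2 ** len(methods)):
        inside = [m for k, m in enumerate(methods) if mask >> k & 1]
        outside = [m for m in methods if m not in inside]
        region = set.intersection(*(vote_sets[m] for m in inside))
        for m in outside:
            region -= vote_sets[m]
        rows.append(
            {
                "region": "&".join(inside),
                "n_methods": len(inside),
                "count": len(region),
            }
        )
    regions = pd.DataFrame(rows, columns=["region", "n_methods", "count"])
    return PlotData("venn", {"members": members, "regions": regions},
                    title="method vote overlap")


def _require_matplotlib():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_radar(data: PlotData, path: str | Path) -> None:
    plt = _require_matplotlib()
    axes = data.tables["axes"]
    theta = np.linspace(0, 2 * np.pi, len(axes) + 1)
    vals = np.append(axes["percentile"].to_numpy(), axes["percentile"].iloc[0])
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.plot(theta, vals, "o-", lw=2)
    ax.fill(theta, vals, alpha=0.25)
    ax.set_xticks(theta[:-1])
    ax.set_xticklabels(axes["method"])
    ax.set_ylim(0, 100)
    ax.set_title(data.title, pad=20)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_gsea(data: PlotData, path: str | Path) -> None:
    plt = _require_matplotlib()
    fig, axs = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for ax, label, color in zip(axs, ("up", "down"), ("tab:red", "tab:blue")):
        tab = data.tables[f"{label}_running"]
        ax.plot(tab["position"], tab["running_sum"], color=color, lw=1.5)
        hitpos = tab.loc[tab["hit"] == 1, "position"]
        ax.vlines(hitpos, -0.05, 0.05, color="k", lw=0.6)
        ax.axhline(0.0, color="grey", lw=0.5)
        es = data.notes.get(f"es_{label}", "")
        ax.set_ylabel(f"{label} running sum")
        ax.set_title(f"{label} set ES = {float(es):.4f}" if es else label, fontsize=10)
    axs[1].set_xlabel("reference rank (z descending)")
    fig.suptitle(data.title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_venn(data: PlotData, path: str | Path) -> None:
    plt = _require_matplotlib()
    regions = data.tables["regions"]
    methods = sorted(
        {m for reg in regions["region"] for m in reg.split("&")},
        key=lambda m: METHODS.index(m) if m in METHODS else 99,
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    if len(methods) <= 3:
        centers = {2: [(-0.5, 0), (0.5, 0)], 3: [(-0.5, -0.3), (0.5, -0.3), (0, 0.55)]}[len(methods)]
        for (x, y), m in zip(centers, methods):
            ax.add_patch(plt.Circle((x, y), 0.9, alpha=0.3, label=m))
            ax.annotate(m, (x, y + 0.95), ha="center")
        # annotate each region count at a crude centroid of its circles
        for _, row in regions.iterrows():
            inside = row["region"].split("&")
            pts = [centers[methods.index(m)] for m in inside]
            cx = float(np.mean([p[0] for p in pts]))
            cy = float(np.mean([p[1] for p in pts]))
            shift = 0.45 if len(inside) == 1 else 0.0
            direction = np.array([cx, cy])
            if len(inside) == 1 and np.linalg.norm(direction) > 0:
                cx, cy = direction * (1 + shift)
            ax.annotate(str(row["count"]), (cx, cy), ha="center", fontsize=11)
        ax.set_xlim(-2, 2)
        ax.set_ylim(-2, 2)
        ax.set_aspect("equal")
        ax.axis("off")
    else:
        order = regions.sort_values(["n_methods", "region"]).reset_index(drop=True)
        ax.bar(np.arange(len(order)), order["count"])
        ax.set_xticks(np.arange(len(order)))
        ax.set_xticklabels(order["region"], rotation=90, fontsize=6)
        ax.set_ylabel("references in region")
    ax.set_title(data.title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def render(data: PlotData, path: str | Path) -> None:
    """Dispatch a PlotData to its image renderer."""
    {"radar": plot_radar, "gsea": plot_gsea, "venn": plot_venn}[data.kind](data, path)


def write_tables(data: PlotData, directory: str | Path, stem: str) -> list[Path]:
    """Write each table as TSV; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name, tab in data.tables.items():
        p = directory / f"{stem}_{name}.tsv"
        tab.to_csv(p, sep="\t", index=False)
        out.append(p)
    return out
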