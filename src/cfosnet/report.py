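"""Analysis orchestration and output artifacts: tables, GraphML, figures.

This module turns cohorts into the full two-condition analysis bundle and
serializes it: correlation / p-value / z-weight matrices as CSV, signed
edge lists as CSV and GraphML, the metric-and-contrast report as JSON, a
chord diagram of the signed significant edges (significance tiers p < 0.05
/ 0.01 / 0.001 in distinct colors), and a force-directed (Kamada-Kawai)
layout of the positive-strength network.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

if not os.environ.get("DISPLAY"):  # headless: file-only rendering
    matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .atlas import CohortTable
from .compare import (
    ConditionContrast,
    hemispheric_counts,
    node_connectivity_contrast,
    positive_fraction,
    regional_density_contrast,
    total_connectivity_contrast,
)
from .metrics import MetricReport, WeightedGraph, summarize_network
from .network import (
    CorrelationResult,
    FunctionalNetwork,
    all_pairs_z,
    correlation_matrix,
    threshold_network,
)

__all__ = [
    "AnalysisBundle",
    "analyze_pair",
    "matrix_frame",
    "edges_frame",
    "network_to_graphml",
    "graphml_to_network_weights",
    "chord_plot",
    "kamada_kawai_plot",
    "save_report_json",
]

#: presentation colors for the five anatomical systems
GROUP_COLORS = {
    "cortical": "tab:orange",
    "hippocampal": "tab:purple",
    "amygdalar": "tab:red",
    "thalamic": "tab:green",
    "brainstem": "tab:blue",
}


@dataclass
class AnalysisBundle:
    """Everything the two-condition pipeline computes, in one place."""

    corr_a: CorrelationResult = field(repr=False)
    corr_b: CorrelationResult = field(repr=False)
    net_a: FunctionalNetwork = field(repr=False)
    net_b: FunctionalNetwork = field(repr=False)
    metrics_a: MetricReport = field(repr=False)
    metrics_b: MetricReport = field(repr=False)
    contrast: ConditionContrast = field(repr=False)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "conditions": {
                self.corr_a.condition: {"metrics": self.metrics_a.to_dict()},
                self.corr_b.condition: {"metrics": self.metrics_b.to_dict()},
            },
            "contrast": self.contrast.to_dict(),
        }


def analyze_pair(
    cohort_a: CohortTable,
    cohort_b: CohortTable,
    alpha: float = 0.05,
    method: str = "auto",
    lc_nodes: tuple[str, ...] = ("LC-L", "LC-R"),
) -> AnalysisBundle:
    """Run the full two-condition pipeline.

    Correlation matrices, thresholded networks, weighted graph metrics and
    all between-condition contrasts (total connectivity, per-LC-node
    connectivity, hemispheric edge counts, positive-correlation fraction,
    per-region density tests).
    """
    if cohort_a.atlas.codes != cohort_b.atlas.codes:
        raise ValueError("cohorts must share the same atlas")
    corr_a = correlation_matrix(cohort_a, method=method)
    corr_b = correlation_matrix(cohort_b, method=method)
    net_a = threshold_network(corr_a, alpha=alpha)
    net_b = threshold_network(corr_b, alpha=alpha)
    metrics_a = summarize_network(WeightedGraph.from_network(net_a))
    metrics_b = summarize_network(WeightedGraph.from_network(net_b))
    lc = {}
    for node in lc_nodes:
        if node in cohort_a.atlas.codes:
            lc[node] = node_connectivity_contrast(corr_a, corr_b, node)
    contrast = ConditionContrast(
        label_a=cohort_a.condition,
        label_b=cohort_b.condition,
        total_connectivity=total_connectivity_contrast(
            all_pairs_z(corr_a), all_pairs_z(corr_b)
        ),
        lc_contrast=lc,
        hemispheric_counts={
            cohort_a.condition: hemispheric_counts(net_a),
            cohort_b.condition: hemispheric_counts(net_b),
        },
        positive_fraction={
            cohort_a.condition: positive_fraction(corr_a),
            cohort_b.condition: positive_fraction(corr_b),
        },
        density_tests=regional_density_contrast(cohort_a, cohort_b),
    )
    return AnalysisBundle(
        corr_a=corr_a, corr_b=corr_b, net_a=net_a, net_b=net_b,
        metrics_a=metrics_a, metrics_b=metrics_b, contrast=contrast, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Tabular / GraphML serialization
# ---------------------------------------------------------------------------


def matrix_frame(matrix: np.ndarray, codes: list[str]) -> pd.DataFrame:
    """Square matrix as a labelled DataFrame (for CSV output)."""
    return pd.DataFrame(matrix, index=codes, columns=codes)


def edges_frame(net: FunctionalNetwork) -> pd.DataFrame:
    """Signed edge list with rho, p, sign and positive-edge z weight."""
    rows = []
    for e in net.edges:
        i, j = net.atlas.index(e.region_i), net.atlas.index(e.region_j)
        rows.append(
            dict(region_i=e.region_i, region_j=e.region_j, rho=e.rho, p=e.p,
                 sign=e.sign, z=net.z_weights[i, j])
        )
    return pd.DataFrame(rows, columns=["region_i", "region_j", "rho", "p", "sign", "z"])


def network_to_graphml(net: FunctionalNetwork, path: str | Path) -> Path:
    """Write the signed network as GraphML (all atlas nodes, edge
    attributes rho / p / sign / z).  Round-trips through networkx."""
    G = nx.Graph()
    for region in net.atlas:
        G.add_node(
            region.code,
            hemisphere=region.hemisphere,
            display_group=region.display_group,
            area_group=region.area_group,
        )
    for e in net.edges:
        i, j = net.atlas.index(e.region_i), net.atlas.index(e.region_j)
        G.add_edge(
            e.region_i, e.region_j,
            rho=float(e.rho), p=float(e.p), sign=int(e.sign),
            weight=float(net.z_weights[i, j]),
        )
    path = Path(path)
    nx.write_graphml(G, path)
    return path


def graphml_to_network_weights(path: str | Path) -> pd.DataFrame:
    """Reload a GraphML edge list (round-trip check / interchange)."""
    G = nx.read_graphml(path)
    rows = [
        dict(region_i=u, region_j=v, rho=d["rho"], p=d["p"], sign=d["sign"],
             z=d["weight"])
        for u, v, d in G.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["region_i", "region_j", "rho", "p", "sign", "z"])


def save_report_json(bundle: AnalysisBundle, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(bundle.to_dict(), fh, indent=2)  # repr floats: full precision
    return path


def summary_text(bundle: AnalysisBundle) -> str:
    """Human-readable summary table of the two-condition analysis."""
    c = bundle.contrast
    t = c.total_connectivity
    lines = [
        f"Conditions: {c.label_a} vs {c.label_b} (alpha = {bundle.alpha})",
        f"Edges: {bundle.net_a.n_edges} vs {bundle.net_b.n_edges}",
        f"Total connectivity (z): {t.mean_a:.3f} +/- {t.sem_a:.3f} vs "
        f"{t.mean_b:.3f} +/- {t.sem_b:.3f}  [t({t.df}) = {t.t:.2f}, p = {t.p_t:.2g}; "
        f"Kruskal-Wallis H = {t.kw_h:.2f}, p = {t.p_kw:.2g}]",
        f"Positive-correlation fraction: "
        f"{c.positive_fraction[c.label_a]:.3f} vs {c.positive_fraction[c.label_b]:.3f}",
        "Global metrics (a vs b):",
    ]
    for name in ("global_efficiency", "average_clustering", "average_strength", "average_degree"):
        va = getattr(bundle.metrics_a, name)
        vb = getattr(bundle.metrics_b, name)
        lines.append(f"  {name}: {va:.3f} vs {vb:.3f}")
    lines.append("Hemispheric significant-correlation counts:")
    for label in (c.label_a, c.label_b):
        for group, cnt in c.hemispheric_counts[label].items():
            lines.append(
                f"  {label:>16} {group:>12}: intra L {cnt['intra_left']}, "
                f"intra R {cnt['intra_right']}, inter {cnt['inter']}"
            )
    lines.append("Top 5 hubs by normalized nodal strength:")
    lines.append(f"  {c.label_a}: {', '.join(bundle.metrics_a.hub_order[:5])}")
    lines.append(f"  {c.label_b}: {', '.join(bundle.metrics_b.hub_order[:5])}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def _edge_style(e) -> tuple[str, float]:
    """Color and width encoding sign and significance tier."""
    if e.p < 0.001:
        return "gold", 2.4
    if e.p < 0.01:
        return "darkorange", 2.0
    return ("tab:blue", 1.2) if e.sign > 0 else ("tab:red", 1.2)


def chord_plot(net: FunctionalNetwork, path: str | Path | None = None, title: str = ""):
    """Chord diagram of the signed significant edges.

    Nodes are placed on a circle frontal-to-caudal with the two hemispheres
    on separate halves (left hemisphere on the left).  Positive edges are
    blue, negative red; edges at p < 0.01 are highlighted in orange and at
    p < 0.001 in yellow.
    """
    atlas = net.atlas
    left = atlas.hemisphere_codes("left")
    right = atlas.hemisphere_codes("right")
    angles: dict[str, float] = {}
    # left hemisphere: 90 deg -> 270 deg (left half), right hemisphere mirrored
    for k, code in enumerate(left):
        angles[code] = np.pi / 2 + np.pi * (k + 0.5) / len(left)
    for k, code in enumerate(right):
        angles[code] = np.pi / 2 - np.pi * (k + 0.5) / len(right)
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.set_aspect("equal")
    ax.axis("off")
    for e in net.edges:
        a1, a2 = angles[e.region_i], angles[e.region_j]
        p1 = np.array([np.cos(a1), np.sin(a1)])
        p2 = np.array([np.cos(a2), np.sin(a2)])
        color, lw = _edge_style(e)
        # quadratic Bezier toward the center
        ts = np.linspace(0, 1, 40)[:, None]
        curve = (1 - ts) ** 2 * p1 + 2 * ts * (1 - ts) * np.zeros(2) + ts**2 * p2
        ax.plot(curve[:, 0], curve[:, 1], color=color, lw=lw, alpha=0.85, zorder=1)
    for code, ang in angles.items():
        region = atlas[code]
        x, y = np.cos(ang), np.sin(ang)
        ax.scatter([x], [y], s=60, color=GROUP_COLORS[region.display_group], zorder=2)
        ha = "right" if x < 0 else "left"
        ax.annotate(code, (1.06 * x, 1.06 * y), ha=ha, va="center", fontsize=7)
    if title:
        ax.set_title(title)
    if path is not None:
        _save_figure(fig, path)
    return fig


def kamada_kawai_plot(
    net: FunctionalNetwork, path: str | Path | None = None, title: str = ""
):
    """Force-directed (Kamada-Kawai) layout of the positive z-strength
    network; the layout is deterministic and presentation-only."""
    G = nx.Graph()
    for region in net.atlas:
        G.add_node(region.code)
    d = len(net.atlas)
    codes = net.atlas.codes
    for i in range(d):
        for j in range(i + 1, d):
            if net.z_weights[i, j] > 0:
                G.add_edge(codes[i], codes[j], weight=float(net.z_weights[i, j]),
                           distance=float(1.0 / net.z_weights[i, j]))
    if G.number_of_edges():
        pos = nx.kamada_kawai_layout(G, weight="distance")
    else:
        pos = nx.circular_layout(G)
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.axis("off")
    colors = [GROUP_COLORS[net.atlas[c].display_group] for c in G.nodes]
    widths = [1.5 * G[u][v]["weight"] for u, v in G.edges]
    nx.draw_networkx_edges(G, pos, ax=ax, width=widths, alpha=0.6, edge_color="gray")
    nx.draw_networkx_nodes(G, pos, ax=ax, node_color=colors, node_size=220)
    nx.draw_networkx_labels(G, pos, ax=ax, font_size=7)
    if title:
        ax.set_title(title)
    if path is not None:
        _save_figure(fig, path)
    return fig


def _save_figure(fig, path: str | Path) -> None:
    """Save as both SVG and PNG next to each other."""
    path = Path(path)
    base = path.with_suffix("")
    fig.savefig(base.with_suffix(".svg"))
    fig.savefig(base.with_suffix(".png"), dpi=150)
    plt.close(fig)
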