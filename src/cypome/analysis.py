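"""GCM analyses: pan/core-CYPome curves, power-law fit, co-occurrence network,
genome clustering with heatmap, and CYP-cloud frequencies.

The pan-CYPome of a genome subset is the number of GCM rows present in at
least one subset genome; the core-CYPome is the number present in every
subset genome.  For each subset size n the curve draws up to ``samples``
distinct genome subsets (exhaustive when C(N, n) fits the budget) and records
all sampled sizes plus their mean and median.  Pan-CYPome growth is modelled
by the power law n_pan = σ·N^γ fitted by ordinary least squares on log-log
scale; γ near 0 means a closed (saturated) pan-CYPome, larger γ an open one.

Co-occurrence follows M_CYP = diagonal(reps(M·Mᵀ)) on the presence/absence
indicator of the GCM: reps() binarises the product and diagonal() zeroes the
diagonal, leaving an unweighted adjacency; the weighted matrix (genomes
shared per CYP pair) is kept for edge weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from itertools import combinations

from scipy.cluster.hierarchy import dendrogram, leaves_list, linkage

from .gcm import GCM

logger = logging.getLogger(__name__)

DEFAULT_PAN_SAMPLES = 300
FitTarget = Literal["mean", "median"]


# ---------------------------------------------------------------------------
# Pan/core-CYPome rarefaction
# ---------------------------------------------------------------------------

@dataclass
class PanCoreCurve:
    """Sampled pan- and core-CYPome sizes for each genome subset size n."""

    n: list[int]
    samples_per_n: list[int]
    pan_sizes: list[list[int]]
    core_sizes: list[list[int]]

    @property
    def pan_mean(self) -> np.ndarray:
        return np.array([np.mean(s) for s in self.pan_sizes])

    @property
    def core_mean(self) -> np.ndarray:
        return np.array([np.mean(s) for s in self.core_sizes])

    @property
    def pan_median(self) -> np.ndarray:
        return np.array([np.median(s) for s in self.pan_sizes])

    @property
    def core_median(self) -> np.ndarray:
        return np.array([np.median(s) for s in self.core_sizes])

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-sample table (n, sample, pan, core)."""
        rows = []
        for n, pans, cores in zip(self.n, self.pan_sizes, self.core_sizes):
            for i, (p, c) in enumerate(zip(pans, cores)):
                rows.append({"n": n, "sample": i, "pan": p, "core": c})
        return pd.DataFrame(rows, columns=["n", "sample", "pan", "core"])


def _distinct_subsets(
    n_genomes: int, size: int, budget: int, rng: np.random.Generator
) -> list[tuple[int, ...]]:
    total = comb(n_genomes, size)
    if total <= budget:
        return list(combinations(range(n_genomes), size))
    chosen: set[tuple[int, ...]] = set()
    # Distinct-subset rejection sampling; collisions are rare when total >> budget.
    while len(chosen) < budget:
        pick = tuple(sorted(rng.choice(n_genomes, size=size, replace=False).tolist()))
        chosen.add(pick)
    return sorted(chosen)


def pan_core_curve(
    gcm: GCM, samples: int = DEFAULT_PAN_SAMPLES, seed: int = 0
) -> PanCoreCurve:
    """Sample pan/core-CYPome sizes over distinct genome subsets of each size.

    For every n in 1..N, min(samples, C(N, n)) distinct subsets are drawn
    (all of them when they fit the budget); each subset contributes one
    C_pan (rows occupied in ≥1 subset genome) and one C_core (rows occupied
    in all subset genomes).
    """
    if samples < 1:
        raise ValueError("samples must be ≥ 1")
    N = gcm.g_t
    if N < 1:
        raise ValueError("GCM has no genomes")
    rng = np.random.default_rng(seed)
    presence = gcm.counts > 0  # rows × genomes
    ns, counts_per_n, pan_all, core_all = [], [], [], []
    for size in range(1, N + 1):
        subsets = _distinct_subsets(N, size, samples, rng)
        pans, cores = [], []
        for idx in subsets:
            sub = presence[:, list(idx)]
            pans.append(int(sub.any(axis=1).sum()))
            cores.append(int(sub.all(axis=1).sum()))
        ns.append(size)
        counts_per_n.append(len(subsets))
        pan_all.append(pans)
        core_all.append(cores)
    return PanCoreCurve(n=ns, samples_per_n=counts_per_n, pan_sizes=pan_all, core_sizes=core_all)


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted parameters of the pan-CYPome growth law n_pan = σ·N^γ."""

    sigma: float
    gamma: float
    n_points: int
    fit_target: str


def fit_power_law_xy(n: Sequence[float], sizes: Sequence[float]) -> PowerLawFit:
    """OLS fit of size = σ·n^γ on log-log scale (γ = slope, σ = exp(intercept))."""
    n = np.asarray(n, dtype=float)
    y = np.asarray(sizes, dtype=float)
    if len(n) < 2 or len(np.unique(n)) < 2:
        raise ValueError("need ≥ 2 distinct n values")
    if np.any(y <= 0):
        raise ValueError("all sizes must be positive for a log-log fit")
    slope, intercept = np.polyfit(np.log(n), np.log(y), 1)
    return PowerLawFit(
        sigma=float(np.exp(intercept)), gamma=float(slope), n_points=len(n), fit_target="xy"
    )


def fit_power_law(curve: PanCoreCurve, fit_target: FitTarget = "mean") -> PowerLawFit:
    """Fit the power law to the pan-CYPome summary curve (mean by default)."""
    y = curve.pan_mean if fit_target == "mean" else curve.pan_median
    fit = fit_power_law_xy(curve.n, y)
    return PowerLawFit(
        sigma=fit.sigma, gamma=fit.gamma, n_points=fit.n_points, fit_target=fit_target
    )


# ---------------------------------------------------------------------------
# Co-occurrence network
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceNetwork:
    """CYP co-occurrence: genome-sharing counts and the binarised adjacency."""

    occurrence: pd.Series  # genomes carrying each CYP
    weighted: pd.DataFrame  # genomes shared per CYP pair, zero diagonal
    adjacency: pd.DataFrame  # 0/1, zero diagonal
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)  # cyp_a < cyp_b, weight > 0

    def to_networkx(self):
        """Weighted undirected graph with per-node occurrence counts."""
        import networkx as nx

        g = nx.Graph()
        for name, occ in self.occurrence.items():
            g.add_node(name, occurrence=int(occ))
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.cyp_a, row.cyp_b, weight=int(row.weight))
        return g


def cooccurrence(gcm: GCM) -> CooccurrenceNetwork:
    """Build the co-occurrence network of a GCM.

    Two CYPs co-occur when at least one genome carries both; edge weights are
    the number of genomes sharing the pair, node sizes the number of genomes
    carrying the CYP.
    """
    names = gcm.cyp_names
    b = (gcm.counts > 0).astype(int)
    weighted = b @ b.T
    np.fill_diagonal(weighted, 0)
    adjacency = (weighted >= 1).astype(int)
    occurrence = pd.Series(b.sum(axis=1), index=names, name="occurrence")
    wdf = pd.DataFrame(weighted, index=names, columns=names)
    adf = pd.DataFrame(adjacency, index=names, columns=names)
    rows = [
        {"cyp_a": names[i], "cyp_b": names[j], "weight": int(weighted[i, j])}
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if weighted[i, j] > 0
    ]
    edges = pd.DataFrame(rows, columns=["cyp_a", "cyp_b", "weight"])
    return CooccurrenceNetwork(occurrence=occurrence, weighted=wdf, adjacency=adf, edges=edges)


# ---------------------------------------------------------------------------
# Genome clustering / heatmap
# ---------------------------------------------------------------------------

@dataclass
class GenomeClustering:
    """Hierarchical clustering of genomes (and CYP rows) on the count matrix."""

    genome_linkage: np.ndarray
    cyp_linkage: np.ndarray | None
    genome_leaf_order: list[str]
    cyp_leaf_order: list[str]
    metric: str
    method: str


def cluster_genomes(
    gcm: GCM, metric: str = "euclidean", method: str = "average"
) -> GenomeClustering | None:
    """Hierarchically cluster genome columns (and CYP rows) of the GCM.

    Returns None with a warning when fewer than 2 genomes are present.
    """
    if gcm.g_t < 2:
        logger.warning("WARN clustering skipped: need ≥ 2 genomes, have %d", gcm.g_t)
        return None
    counts = gcm.counts.astype(float)
    genome_link = linkage(counts.T, method=method, metric=metric)
    genome_order = [gcm.genome_ids[i] for i in leaves_list(genome_link)]
    if gcm.n_cyps >= 2:
        cyp_link = linkage(counts, method=method, metric=metric)
        cyp_order = [gcm.cyp_names[i] for i in leaves_list(cyp_link)]
    else:
        cyp_link, cyp_order = None, list(gcm.cyp_names)
    return GenomeClustering(
        genome_linkage=genome_link,
        cyp_linkage=cyp_link,
        genome_leaf_order=genome_order,
        cyp_leaf_order=cyp_order,
        metric=metric,
        method=method,
    )


def cluster_heatmap(
    gcm: GCM,
    metric: str = "euclidean",
    method: str = "average",
    out_image: str | Path | None = None,
    out_text: str | Path | None = None,
) -> GenomeClustering | None:
    """Cluster the GCM and optionally render a dendrogram heatmap image.

    The text output records both leaf orders and the genome merge tree; the
    image is a clustered heatmap with the genome dendrogram on top.
    """
    clustering = cluster_genomes(gcm, metric=metric, method=method)
    if clustering is None:
        return None
    if out_text is not None:
        lines = ["#GENOME_LEAF_ORDER\t" + "\t".join(clustering.genome_leaf_order)]
        lines.append("#CYP_LEAF_ORDER\t" + "\t".join(clustering.cyp_leaf_order))
        lines.append("#GENOME_MERGE_TREE\tleft\tright\tdistance\tsize")
        for row in clustering.genome_linkage:
            lines.append(
                "\t".join(["M", str(int(row[0])), str(int(row[1])), f"{row[2]:.6g}", str(int(row[3]))])
            )
        Path(out_text).write_text("\n".join(lines) + "\n")
    if out_image is not None:
        _render_heatmap(gcm, clustering, out_image)
    return clustering


def _render_heatmap(gcm: GCM, clustering: GenomeClustering, out_image: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ordered = gcm.table.loc[clustering.cyp_leaf_order, clustering.genome_leaf_order]
    fig = plt.figure(figsize=(8, 8))
    ax_dendro = fig.add_axes([0.25, 0.76, 0.65, 0.18])
    dendrogram(clustering.genome_linkage, ax=ax_dendro, no_labels=True, color_threshold=0)
    ax_dendro.set_axis_off()
    ax_heat = fig.add_axes([0.25, 0.08, 0.65, 0.65])
    ax_heat.imshow(ordered.to_numpy(), aspect="auto", cmap="viridis", interpolation="nearest")
    ax_heat.set_xticks(range(len(ordered.columns)))
    ax_heat.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax_heat.set_yticks(range(len(ordered.index)))
    ax_heat.set_yticklabels(ordered.index, fontsize=5)
    fig.savefig(out_image, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# CYP cloud
# ---------------------------------------------------------------------------

def cloud_frequencies(gcm: GCM) -> pd.DataFrame:
    """Per-CYP total sequence counts, rank-ordered descending (ties by name)."""
    totals = gcm.table.sum(axis=1)
    df = pd.DataFrame({"cyp": totals.index, "frequency": totals.to_numpy()})
    df = df.sort_values(["frequency", "cyp"], ascending=[False, True], kind="stable")
    df["rank"] = range(1, len(df) + 1)
    return df.reset_index(drop=True)


def render_cloud(frequencies: pd.DataFrame, out_image: str | Path, seed: int = 0) -> None:
    """Render a CYP cloud: names scattered with font size scaled by frequency."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(8, 6))
    if len(frequencies):
        fmax = frequencies["frequency"].max() or 1
        for _, row in frequencies.iterrows():
            size = 6 + 30 * row["frequency"] / fmax
            ax.text(
                rng.uniform(0.05, 0.85),
                rng.uniform(0.05, 0.9),
                row["cyp"],
                fontsize=size,
                alpha=0.8,
            )
    ax.set_axis_off()
    fig.savefig(out_image, dpi=120)
    plt.close(fig)


def plot_pan_core(curve: PanCoreCurve, fit: PowerLawFit | None, out_image: str | Path) -> None:
    """Scatter sampled pan/core sizes per n with means and the fitted power law."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for n, pans, cores in zip(curve.n, curve.pan_sizes, curve.core_sizes):
        ax.plot([n] * len(pans), pans, "o", mfc="none", color="tab:blue", ms=3, alpha=0.3)
        ax.plot([n] * len(cores), cores, "o", color="tab:orange", ms=3, alpha=0.3)
    ax.plot(curve.n, curve.pan_mean, "-", color="tab:blue", label="pan mean")
    ax.plot(curve.n, curve.core_mean, "-", color="tab:orange", label="core mean")
    if fit is not None:
        xs = np.linspace(min(curve.n), max(curve.n), 100)
        ax.plot(xs, fit.sigma * xs**fit.gamma, "r--", label=f"σ·N^γ (γ={fit.gamma:.2f})")
    ax.set_xlabel("genomes (n)")
    ax.set_ylabel("CYP families/subfamilies")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_image, dpi=120)
    plt.close(fig)
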