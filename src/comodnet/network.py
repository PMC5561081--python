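"""Materialize the thresholded co-expression network with per-edge metadata.

The network is a multigraph: a transcript pair contributes one edge per
qualifying Gaussian cluster, each edge carrying its own signed correlation
and sample string. Perfect correlations (|rho| = 1.0) are excluded as
artifacts of near-zero expression range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .pairwise import PairResult

__all__ = [
    "Edge",
    "Network",
    "extract_network",
    "binarize_sample_strings",
    "order_edges",
    "degree_distribution",
    "clustering_coefficient_profile",
    "write_network",
    "read_network",
    "plot_sample_heatmap",
]


@dataclass
class Edge:
    gene_a: str  # gene_a < gene_b lexicographically
    gene_b: str
    cluster_index: int
    rho: float
    sample_string: str
    method: str = "spearman"

    @property
    def num_samples(self) -> int:
        return self.sample_string.count("1")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class Network:
    edges: list[Edge] = field(default_factory=list)
    threshold: float = 0.0
    sample_ids: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in (e.gene_a, e.gene_b)}

    def simple_graph(self) -> nx.Graph:
        """Simple-graph projection (multi-edges collapsed)."""
        g = nx.Graph()
        g.add_edges_from(e.pair for e in self.edges)
        return g


def extract_network(
    results: Iterable[PairResult],
    tau: float,
    sample_ids: Optional[list[str]] = None,
    method: str = "spearman",
) -> Network:
    """All (pair, cluster) records with |rho| >= tau and |rho| < 1.0."""
    edges: list[Edge] = []
    for res in results:
        a, b = sorted((res.gene_a, res.gene_b))
        for cl in res.clusters:
            if cl.skipped or cl.rho is None:
                continue
            if abs(cl.rho) >= tau and abs(cl.rho) < 1.0:
                edges.append(
                    Edge(
                        gene_a=a,
                        gene_b=b,
                        cluster_index=cl.index,
                        rho=cl.rho,
                        sample_string=cl.sample_string,
                        method=method,
                    )
                )
    return Network(edges=edges, threshold=tau, sample_ids=sample_ids or [])


def binarize_sample_strings(network: Network) -> np.ndarray:
    """Edges x samples 0/1 matrix: 1 iff the digit is '1'."""
    if not network.edges:
        raise ValueError("network is empty")
    return np.array(
        [[1 if d == "1" else 0 for d in e.sample_string] for e in network.edges],
        dtype=int,
    )


def order_edges(matrix: np.ndarray) -> np.ndarray:
    """Leaf order of average-linkage (Euclidean) hierarchical clustering of
    the 0/1 edge rows; identity for a single edge."""
    matrix = np.asarray(matrix)
    if matrix.shape[0] < 2:
        return np.arange(matrix.shape[0])
    Z = linkage(matrix.astype(float), method="average", metric="euclidean")
    return np.asarray(leaves_list(Z))


def degree_distribution(network: Network) -> dict[int, int]:
    """Histogram of node degrees on the simple-graph projection."""
    g = network.simple_graph()
    hist: dict[int, int] = {}
    for _, d in g.degree():
        hist[d] = hist.get(d, 0) + 1
    return dict(sorted(hist.items()))


def clustering_coefficient_profile(network: Network) -> list[tuple[int, float]]:
    """(degree, mean local clustering coefficient) pairs on the simple
    projection; the hierarchical signature is a decreasing profile."""
    g = network.simple_graph()
    if g.number_of_nodes() == 0:
        return []
    cc = nx.clustering(g)
    by_degree: dict[int, list[float]] = {}
    for node, d in g.degree():
        by_degree.setdefault(d, []).append(cc[node])
    return [(d, float(np.mean(v))) for d, v in sorted(by_degree.items())]


def write_network(network: Network, path, sidecar: Optional[dict] = None) -> None:
    """Network TSV plus a JSON sidecar with the threshold and configuration."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(
            "gene_a\tgene_b\tcluster_index\trho\tmethod\tnum_samples\t"
            "sample_string\n"
        )
        for e in network.edges:
            fh.write(
                f"{e.gene_a}\t{e.gene_b}\t{e.cluster_index}\t{e.rho:.10g}\t"
                f"{e.method}\t{e.num_samples}\t{e.sample_string}\n"
            )
    meta = {"threshold": network.threshold, "sample_ids": network.sample_ids}
    if sidecar:
        meta.update(sidecar)
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def read_network(path) -> Network:
    df = pd.read_csv(path, sep="\t", dtype={"sample_string": str})
    edges = [
        Edge(
            gene_a=row.gene_a,
            gene_b=row.gene_b,
            cluster_index=int(row.cluster_index),
            rho=float(row.rho),
            sample_string=str(row.sample_string),
            method=row.method,
        )
        for row in df.itertuples(index=False)
    ]
    threshold = 0.0
    sample_ids: list[str] = []
    try:
        with open(str(path) + ".json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        threshold = meta.get("threshold", 0.0)
        sample_ids = meta.get("sample_ids", [])
    except FileNotFoundError:
        pass
    return Network(edges=edges, threshold=threshold, sample_ids=sample_ids)


def plot_sample_heatmap(
    network: Network,
    path,
    sample_groups: Optional[dict[str, str]] = None,
) -> None:
    """Sample-composition heatmap: rows = samples (grouped), columns = edges
    ordered by sample-string similarity. The 0/1 matrix is stored edges x
    samples and transposed at plot time."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = binarize_sample_strings(network)
    order = order_edges(mat)
    mat = mat[order]
    row_order = np.arange(mat.shape[1])
    boundaries: list[int] = []
    if sample_groups and network.sample_ids:
        groups = [sample_groups.get(s, "") for s in network.sample_ids]
        row_order = np.argsort(groups, kind="stable")
        sorted_groups = [groups[i] for i in row_order]
        boundaries = [
            k for k in range(1, len(sorted_groups))
            if sorted_groups[k] != sorted_groups[k - 1]
        ]
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.imshow(
        mat.T[row_order],
        aspect="auto",
        interpolation="nearest",
        cmap="RdYlGn",
        vmin=0,
        vmax=1,
    )
    for b in boundaries:
        ax.axhline(b - 0.5, color="black", linewidth=0.8)
    ax.set_xlabel("edges (clustered by sample composition)")
    ax.set_ylabel("samples")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
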