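"""Protein–protein interaction (PPI) network analysis.

Consumes STRING-style edge lists (two identifier columns plus a combined
confidence score, either an integer on the 0–999 scale or a float in
[0, 1]), filters by a minimum confidence, restricts to a protein subset
(e.g. the DEPs) and ranks hub proteins by node degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionEdge:
    """Undirected protein pair with confidence score in [0, 1]."""

    protein_a: str
    protein_b: str
    score: float

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError(f"self-loop on {self.protein_a}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
        # canonical orientation so (a, b) == (b, a)
        if self.protein_b < self.protein_a:
            a, b = self.protein_a, self.protein_b
            object.__setattr__(self, "protein_a", b)
            object.__setattr__(self, "protein_b", a)

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    degrees: dict[str, int]
    component_sizes: list[int]
    top_degree_nodes: list[tuple[str, int]]
    n_isolated_subset_members: int = 0


def load_edges(
    source: str | Path | pd.DataFrame, min_score: float = 0.4
) -> list[InteractionEdge]:
    """Read and filter a STRING-dialect edge list.

    Scores on the 0–999 integer scale are detected (any value > 1) and
    divided by 1000. Edges with score ≥ ``min_score`` are retained (closed
    boundary); duplicate undirected pairs and self-loops are dropped with a
    logged count. Malformed rows raise with their line numbers.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t")
    if df.shape[1] < 3:
        raise ValueError("edge list needs columns: protein_a, protein_b, combined_score")
    cols = list(df.columns[:3])
    df = df[cols]
    df.columns = ["protein_a", "protein_b", "combined_score"]

    bad_lines = []
    scores = []
    for i, v in enumerate(df["combined_score"]):
        try:
            scores.append(float(v))
        except (TypeError, ValueError):
            bad_lines.append(i + 2)  # 1-based + header line
    if bad_lines:
        raise ValueError(f"malformed score values at lines {bad_lines}")
    df["combined_score"] = scores
    if (df["combined_score"] > 1).any():
        df["combined_score"] = df["combined_score"] / 1000.0
    if (df["combined_score"] < 0).any() or (df["combined_score"] > 1).any():
        raise ValueError("scores outside [0, 1] after dialect normalisation")

    best: dict[tuple[str, str], float] = {}
    n_self = n_dup = 0
    for row in df.itertuples(index=False):
        a, b = str(row.protein_a), str(row.protein_b)
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in best:
            n_dup += 1
            # max score keeps the result independent of input row order
            best[key] = max(best[key], float(row.combined_score))
        else:
            best[key] = float(row.combined_score)
    if n_self or n_dup:
        logger.info("dropped %d self-loop(s) and %d duplicate pair(s)", n_self, n_dup)
    return [
        InteractionEdge(a, b, s)
        for (a, b), s in sorted(best.items())
        if s >= min_score
    ]


def to_graph(edges: Iterable[InteractionEdge]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.protein_a, e.protein_b, score=e.score)
    return g


def summarize(graph: nx.Graph, top_k: int = 10) -> NetworkSummary:
    degrees = dict(graph.degree())
    comp_sizes = sorted((len(c) for c in nx.connected_components(graph)), reverse=True)
    top = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    return NetworkSummary(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        degrees=degrees,
        component_sizes=comp_sizes,
        top_degree_nodes=top,
    )


def induced_subnetwork(
    edges: Sequence[InteractionEdge], node_subset: Iterable[str], top_k: int = 10
) -> tuple[NetworkSummary, list[InteractionEdge]]:
    """Edges with both endpoints in ``node_subset`` and their summary.

    Subset members that end up with no edge are counted separately
    (``n_isolated_subset_members``) rather than inflating the node count.
    """
    subset = set(node_subset)
    if not subset:
        raise ValueError("empty node subset")
    kept = [e for e in edges if e.protein_a in subset and e.protein_b in subset]
    graph = to_graph(kept)
    summary = summarize(graph, top_k=top_k)
    summary.n_isolated_subset_members = len(subset - set(graph.nodes))
    return summary, kept


def hub_ranking(
    edges: Sequence[InteractionEdge], top_k: int = 10
) -> list[tuple[str, int]]:
    """Nodes ranked by degree (descending; ties broken lexicographically)."""
    if top_k < 1:
        raise ConfigurationError("top_k must be >= 1")
    if not edges:
        raise ValueError("hub ranking needs at least one edge")
    graph = to_graph(edges)
    ranked = sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]


def edges_to_frame(edges: Sequence[InteractionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein_a": e.protein_a, "protein_b": e.protein_b, "combined_score": e.score}
            for e in edges
        ],
        columns=["protein_a", "protein_b", "combined_score"],
    )


def write_network_outputs(
    edges: Sequence[InteractionEdge], summary: NetworkSummary, outdir: str | Path
) -> None:
    """Filtered edges, degree table and component summary as TSV."""
    outdir = Path(outdir)
    edges_to_frame(edges).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(summary.degrees.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["node", "degree"],
    ).to_csv(outdir / "network_degrees.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"component": range(1, len(summary.component_sizes) + 1), "size": summary.component_sizes}
    ).to_csv(outdir / "network_components.tsv", sep="\t", index=False)
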