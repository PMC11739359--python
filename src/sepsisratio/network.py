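"""Hub-gene selection among candidate markers on interaction networks.

Candidates (the stable up-regulated genes) are scored by weighted degree
within the subgraph each network induces on the candidate set; ranks are
averaged across networks (genes absent from a network score 0 there) and
the best consensus rank wins, ties broken lexicographically. Selecting one
hub limits collinearity among the co-expressed up genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd


class NetworkParseError(ValueError):
    pass


@dataclass
class GeneNetwork:
    """Undirected weighted interaction network."""

    graph: nx.Graph
    name: str = ""

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def network_from_edges(edges: pd.DataFrame, name: str = "") -> GeneNetwork:
    """Build a network from an edge-list frame (gene_a, gene_b[, weight]).

    Self-loops are dropped; duplicate edges collapse to the maximum weight;
    unweighted edges get weight 1.
    """
    g = nx.Graph(name=name)
    for row in edges.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        w = float(row[2]) if len(row) > 2 and pd.notna(row[2]) else 1.0
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w)
    return GeneNetwork(graph=g, name=name)


def load_network(edge_list_path: str | Path, name: str | None = None) -> GeneNetwork:
    """Read a 2-3 column TSV edge list (header optional) into a GeneNetwork."""
    path = Path(edge_list_path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"gene_a", "source", "from"}:
                continue
            if len(parts) not in (2, 3):
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 2-3 tab-separated columns, got {len(parts)}"
                )
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise NetworkParseError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from exc
                if w < 0:
                    raise NetworkParseError(f"{path}:{lineno}: negative weight {w}")
                rows.append((parts[0], parts[1], w))
            else:
                rows.append((parts[0], parts[1], 1.0))
    if not rows:
        import warnings

        warnings.warn(f"empty network file {path}", stacklevel=2)
        return GeneNetwork(graph=nx.Graph(), name=name or path.stem)
    return network_from_edges(
        pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]),
        name=name or path.stem,
    )


def rank_hubs(
    candidates: list[str],
    networks: list[GeneNetwork],
    induced: bool = True,
) -> pd.DataFrame:
    """Rank candidate genes by consensus hub-ness across networks.

    Per network each candidate gets its weighted degree in the subgraph
    induced on the candidate set (or its global weighted degree with
    ``induced=False``); candidates absent from a network score 0. Scores are
    converted to ranks (1 = highest score, average ranks on ties) and the
    consensus is the mean rank across networks; output is sorted by
    consensus rank then gene id.
    """
    if not networks:
        raise ValueError("at least one network is required")
    if not candidates:
        raise ValueError("candidate set is empty")
    cand = sorted(set(candidates))
    scores = pd.DataFrame(index=cand)
    for i, net in enumerate(networks):
        label = net.name or f"network{i + 1}"
        graph = net.graph.subgraph(cand) if induced else net.graph
        deg = dict(graph.degree(weight="weight"))
        scores[label] = [float(deg.get(g, 0.0)) for g in cand]
    ranks = scores.rank(ascending=False, method="average")
    out = pd.DataFrame(
        {"consensus_rank": ranks.mean(axis=1)}, index=scores.index
    ).join(scores)
    # stable sort on an index-sorted frame breaks consensus ties lexicographically
    return out.sort_index(kind="mergesort").sort_values(
        "consensus_rank", kind="mergesort"
    )


def select_hub(ranked: pd.DataFrame) -> str:
    """Top-ranked gene of a ``rank_hubs`` table."""
    if ranked.empty:
        raise ValueError("empty hub ranking")
    return str(ranked.index[0])
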