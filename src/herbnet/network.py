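"""Herb networks built from ranked pair scores.

The herb network takes the top-N ranked pairs as weighted undirected edges;
the hub module extends a set of hub herbs to every statistically significant
pair touching them (one-hop closure: significant edges among the resulting
neighbour set are included too).  Recovery against a curated reference pair
list is reported as precision over the ranked edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from statsmodels.stats.multitest import multipletests

_EDGE_COLS = ["herb_x", "herb_y", "score", "p_value", "rank"]


def _set_degrees(G: nx.Graph) -> nx.Graph:
    # node size contract: proportional to the number of herbs connecting to it
    for node, deg in G.degree():
        G.nodes[node]["degree"] = int(deg)
    return G


def _add_pair_edges(G: nx.Graph, rows: pd.DataFrame) -> None:
    for row in rows.itertuples(index=False):
        G.add_edge(
            row.herb_x, row.herb_y,
            weight=float(row.score), score=float(row.score),
            p_value=float(row.p_value), rank=int(row.rank),
            n_xy=int(row.n_xy) if hasattr(row, "n_xy") else 0,
        )


def build_network(
    pairs: pd.DataFrame,
    top_n: int,
    properties: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Undirected herb network from the ``top_n`` highest-ranked pairs.

    Edges carry the DMIM score (as ``weight``/``score``), chi-square
    ``p_value`` and ``rank``; nodes carry the herb's natural property when
    a property map is supplied.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if top_n > len(pairs):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(pairs)} available pairs; using all",
            stacklevel=2,
        )
        top_n = len(pairs)
    sel = pairs.sort_values("rank", kind="mergesort").head(top_n)
    G = nx.Graph()
    _add_pair_edges(G, sel)
    for node in G.nodes:
        G.nodes[node]["natural_property"] = (properties or {}).get(node, "Unknown")
    return _set_degrees(G)


def extract_hub_module(
    pairs: pd.DataFrame,
    hubs: Iterable[str],
    alpha: float = 0.05,
    herb_names: Sequence[str] | None = None,
    fdr: bool = False,
    properties: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Module around hub herbs: all pairs significant at ``alpha`` that touch
    a hub, plus significant pairs among the included neighbours.

    ``fdr=True`` applies Benjamini-Hochberg to the pair p-values before
    thresholding; the choice is recorded in ``G.graph``.  Significance is
    strict (p < alpha), so no returned edge ever has p >= alpha.
    """
    hubs = set(hubs)
    if not hubs:
        raise ValueError("hubs must be non-empty")
    universe = set(herb_names) if herb_names is not None else (
        set(pairs["herb_x"]) | set(pairs["herb_y"])
    )
    missing = sorted(hubs - universe)
    if missing:
        raise ValueError(f"hub herb(s) not in corpus: {', '.join(missing)}")
    p = pairs["p_value"].to_numpy()
    if fdr and len(p):
        p = multipletests(p, method="fdr_bh")[1]
    sig = pairs[p < alpha]
    touching = sig[sig["herb_x"].isin(hubs) | sig["herb_y"].isin(hubs)]
    members = hubs | set(touching["herb_x"]) | set(touching["herb_y"])
    inner = sig[sig["herb_x"].isin(members) & sig["herb_y"].isin(members)]
    G = nx.Graph(alpha=float(alpha), fdr=bool(fdr), hubs=",".join(sorted(hubs)))
    G.add_nodes_from(hubs)
    _add_pair_edges(G, inner)
    for node in G.nodes:
        G.nodes[node]["natural_property"] = (properties or {}).get(node, "Unknown")
        G.nodes[node]["is_hub"] = node in hubs
    return _set_degrees(G)


@dataclass
class RecoveryReport:
    """How many network edges match a curated reference pair list."""

    n_edges: int
    n_matched: int
    matched: list[tuple[str, str]]
    novel: list[tuple[str, str]]
    precision: float
    precision_at_k: dict[int, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Reference-pair recovery",
            f"  edges:     {self.n_edges}",
            f"  matched:   {self.n_matched}",
            f"  novel:     {self.n_edges - self.n_matched}",
            f"  precision: {self.precision:.3f}",
        ]
        return "\n".join(lines)


def evaluate_recovery(
    network: nx.Graph, reference_pairs: Iterable[tuple[str, str]]
) -> RecoveryReport:
    """Precision of the network's ranked edges against reference pairs.

    Reference pairs are unordered; herbs in the reference that never appear
    in the network are simply ignored (the comparison is over edges).
    """
    ref = {frozenset(p) for p in reference_pairs}
    edges = sorted(
        network.edges(data=True),
        key=lambda e: e[2].get("rank", float("inf")),
    )
    matched: list[tuple[str, str]] = []
    novel: list[tuple[str, str]] = []
    hits = 0
    precision_at_k: dict[int, float] = {}
    for k, (u, v, _) in enumerate(edges, start=1):
        if frozenset((u, v)) in ref:
            hits += 1
            matched.append((u, v))
        else:
            novel.append((u, v))
        precision_at_k[k] = hits / k
    n_edges = len(edges)
    return RecoveryReport(
        n_edges=n_edges,
        n_matched=len(matched),
        matched=matched,
        novel=novel,
        precision=len(matched) / n_edges if n_edges else 0.0,
        precision_at_k=precision_at_k,
    )


def load_reference_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of reference herb pairs."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: reference pairs need two columns")
            out.append((parts[0].strip(), parts[1].strip()))
    return out


def export_network(G: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a herb network as GraphML or a ranked edge-list TSV."""
    path = Path(path)
    _set_degrees(G)
    if format == "graphml":
        nx.write_graphml(G, path)
    elif format == "edgelist_tsv":
        rows = [
            {
                "herb_x": u, "herb_y": v,
                "score": d.get("score", d.get("weight", 0.0)),
                "p_value": d.get("p_value", float("nan")),
                "rank": d.get("rank", 0),
            }
            for u, v, d in G.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=_EDGE_COLS)
        if len(df):
            df = df.sort_values("rank", kind="mergesort")
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a network written by :func:`export_network`."""
    if format == "graphml":
        return nx.read_graphml(Path(path))
    if format == "edgelist_tsv":
        df = pd.read_csv(path, sep="\t")
        G = nx.Graph()
        _add_pair_edges(G, df)
        return _set_degrees(G)
    raise ValueError(f"unknown network format {format!r}")
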