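"""Synthetic formula corpora and omics fixtures with planted structure.

The corpus generator emulates the statistical shape of a real ordered
formula collection: a handful of genuine herb pairs that co-occur far more
often than chance and sit adjacently in the listing order; one or more
high-frequency "Guide" herbs that appear in a large fraction of formulae at
an arbitrary position (and therefore carry little pairing information); and
random filler herbs.  The defaults plant 5 pairs at 30% co-occurrence with
90% adjacency and one Guide herb at 40% marginal frequency in 500 formulae
over 60 herbs — a regime in which distance-aware pair scoring should rank
every planted pair above every Guide pairing.

The omics generator produces a random interaction network, herb and disease
gene sets with tunable overlap, random pathways (one deliberately biased
toward the herb genes so enrichment has signal), and a phenotype-by-feature
matrix with one planted similar block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from herbnet.corpus import FormulaCorpus
from herbnet.comodule import OmicsContext, write_edgelist, write_gmt


# -- corpus ----------------------------------------------------------------


@dataclass
class CorpusSpec:
    """Parameters of the synthetic formula corpus.

    ``planted_pairs`` rows are (herb_x, herb_y, co_prob, adjacency_prob);
    ``guide_herbs`` rows are (herb, marginal_freq).  All planted and guide
    herb names must be distinct; remaining herbs are fillers.
    """

    n_herbs: int = 60
    m_formulae: int = 500
    size_range: tuple[int, int] = (4, 10)
    planted_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)
    guide_herbs: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        k_min, k_max = self.size_range
        if k_min < 2:
            raise ValueError("k_min must be >= 2")
        if k_max < k_min:
            raise ValueError("size_range must be (k_min, k_max) with k_max >= k_min")
        if k_max > self.n_herbs:
            raise ValueError("k_max cannot exceed the number of herbs")
        special = [h for x, y, *_ in self.planted_pairs for h in (x, y)]
        special += [g for g, _ in self.guide_herbs]
        if len(set(special)) != len(special):
            raise ValueError("planted and guide herbs must be distinct")
        for x, y, co, adj in self.planted_pairs:
            if not (0 <= co <= 1 and 0 <= adj <= 1):
                raise ValueError(f"probabilities for pair ({x}, {y}) must be in [0, 1]")
        for g, f in self.guide_herbs:
            if not 0 <= f <= 1:
                raise ValueError(f"marginal frequency for guide {g!r} must be in [0, 1]")
        if self.n_herbs < len(special):
            raise ValueError("n_herbs smaller than the number of planted/guide herbs")

    @property
    def special_herbs(self) -> list[str]:
        return [h for x, y, *_ in self.planted_pairs for h in (x, y)] + [
            g for g, _ in self.guide_herbs
        ]


def default_corpus_spec(seed: int = 0) -> CorpusSpec:
    """The reference study conditions: 60 herbs, 500 formulae of 4-10 herbs,
    5 planted pairs (co-occurrence 0.3, adjacency 0.9), one Guide herb at
    40% marginal frequency."""
    return CorpusSpec(
        n_herbs=60,
        m_formulae=500,
        size_range=(4, 10),
        planted_pairs=[
            (f"pair{i}_a", f"pair{i}_b", 0.3, 0.9) for i in range(1, 6)
        ],
        guide_herbs=[("guide", 0.4)],
        seed=seed,
    )


def generate_corpus(spec: CorpusSpec) -> FormulaCorpus:
    """Draw a corpus from the spec; fully determined by ``spec.seed``.

    Per formula: size k is uniform on ``size_range``; each planted pair is
    included with its co-probability and, when included, placed in adjacent
    positions with its adjacency probability; guide herbs enter as Bernoulli
    draws at a uniform random position; the remaining slots are distinct
    random fillers.  If the included planted/guide herbs outnumber k, k is
    expanded to fit so inclusion probabilities stay exact.
    """
    rng = np.random.default_rng(spec.seed)
    k_min, k_max = spec.size_range
    fillers = [
        f"filler_{i:03d}" for i in range(1, spec.n_herbs - len(spec.special_herbs) + 1)
    ]
    records = []
    for i in range(spec.m_formulae):
        k = int(rng.integers(k_min, k_max + 1))
        units: list[list[str]] = []
        for x, y, co, adj in spec.planted_pairs:
            if rng.random() < co:
                if rng.random() < adj:
                    block = [x, y] if rng.random() < 0.5 else [y, x]
                    units.append(block)
                else:
                    units.append([x])
                    units.append([y])
        for g, f in spec.guide_herbs:
            if rng.random() < f:
                units.append([g])
        used = sum(len(u) for u in units)
        k = max(k, used)
        n_fill = k - used
        if n_fill > len(fillers):
            raise ValueError("not enough filler herbs to reach the formula size")
        if n_fill:
            idx = rng.choice(len(fillers), size=n_fill, replace=False)
            units.extend([[fillers[j]] for j in idx])
        order = rng.permutation(len(units))
        herbs = [h for j in order for h in units[j]]
        records.append((f"F{i + 1:04d}", herbs))
    return FormulaCorpus.from_records(records)


# -- omics -----------------------------------------------------------------


@dataclass
class NetSpec:
    """Parameters of the synthetic interaction network, gene sets and
    phenotype matrix."""

    n_genes: int = 150
    edge_model: str = "erdos_renyi"      # or "scale_free"
    density: float = 0.04                # ER edge probability
    attachment: int = 2                  # preferential-attachment edges
    n_herbs: int = 6
    herb_set_size: int = 15
    herb_pool_size: int = 40             # herb sets drawn from a shared pool
    n_diseases: int = 8
    disease_set_size: int = 15
    herb_disease_overlap: float = 0.3    # fraction of disease genes from herb genes
    n_pathways: int = 12
    pathway_size: int = 20
    n_phenotypes: int = 50
    n_features: int = 30
    block_size: int = 10                 # planted similar phenotype block
    block_similarity: float = 0.8        # 1.0 = identical rows
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_model not in ("erdos_renyi", "scale_free"):
            raise ValueError("edge_model must be 'erdos_renyi' or 'scale_free'")
        if not 0 <= self.herb_disease_overlap <= 1:
            raise ValueError("herb_disease_overlap must be in [0, 1]")
        if not 0 <= self.block_similarity <= 1:
            raise ValueError("block_similarity must be in [0, 1]")
        if self.herb_pool_size > self.n_genes:
            raise ValueError("herb_pool_size cannot exceed n_genes")
        if self.herb_set_size > self.herb_pool_size:
            raise ValueError("herb_set_size cannot exceed herb_pool_size")
        if self.block_size > self.n_phenotypes:
            raise ValueError("block_size cannot exceed n_phenotypes")


def generate_omics(spec: NetSpec) -> OmicsContext:
    """Draw an :class:`OmicsContext` from the spec; reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:04d}" for i in range(1, spec.n_genes + 1)]
    graph_seed = int(rng.integers(2**31))
    if spec.edge_model == "erdos_renyi":
        G0 = nx.gnp_random_graph(spec.n_genes, spec.density, seed=graph_seed)
    else:
        G0 = nx.barabasi_albert_graph(spec.n_genes, spec.attachment, seed=graph_seed)
    ppi = nx.relabel_nodes(G0, dict(enumerate(genes)))

    pool = [genes[i] for i in rng.choice(spec.n_genes, spec.herb_pool_size, replace=False)]
    herb_genes = {
        f"herb_{h}": {
            pool[i]
            for i in rng.choice(len(pool), spec.herb_set_size, replace=False)
        }
        for h in range(1, spec.n_herbs + 1)
    }
    herb_union = sorted(set().union(*herb_genes.values()))
    outside = sorted(set(genes) - set(herb_union))
    n_in = int(round(spec.herb_disease_overlap * spec.disease_set_size))
    n_in = min(n_in, len(herb_union))
    disease_genes = {}
    for d in range(1, spec.n_diseases + 1):
        inside = [herb_union[i] for i in rng.choice(len(herb_union), n_in, replace=False)] if n_in else []
        n_out = spec.disease_set_size - len(inside)
        if n_out > len(outside):
            raise ValueError("not enough genes outside the herb sets for disease sets")
        rest = [outside[i] for i in rng.choice(len(outside), n_out, replace=False)]
        disease_genes[f"disease_{d}"] = set(inside) | set(rest)

    pathways = {}
    for p in range(1, spec.n_pathways + 1):
        if p == 1:
            # one pathway deliberately enriched in the herb genes
            n_bias = min(spec.pathway_size // 2, len(herb_union))
            bias = [herb_union[i] for i in rng.choice(len(herb_union), n_bias, replace=False)]
            pad = [genes[i] for i in rng.choice(spec.n_genes, spec.pathway_size - n_bias, replace=False)]
            pathways["pw_001"] = set(bias) | set(pad)
        else:
            pathways[f"pw_{p:03d}"] = {
                genes[i] for i in rng.choice(spec.n_genes, spec.pathway_size, replace=False)
            }

    ids = [f"ph{i:04d}" for i in range(1, spec.n_phenotypes + 1)]
    base = rng.random(spec.n_features) + 0.1
    M = np.empty((spec.n_phenotypes, spec.n_features))
    s = spec.block_similarity
    for i in range(spec.n_phenotypes):
        noise = rng.random(spec.n_features) + 0.1
        M[i] = s * base + (1 - s) * noise if i < spec.block_size else noise
    phenotypes = pd.DataFrame(M, index=ids)
    members = set(ids[: spec.block_size])

    return OmicsContext(
        ppi=ppi,
        pathways=pathways,
        herb_genes=herb_genes,
        disease_genes=disease_genes,
        phenotypes=phenotypes,
        phenotype_members=members,
    )


def write_omics(context: OmicsContext, out_dir: str | Path) -> dict[str, Path]:
    """Write an omics context as plain-text files under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": out_dir / "ppi.tsv",
        "herb_genes": out_dir / "herb_genes.gmt",
        "disease_genes": out_dir / "disease_genes.gmt",
        "pathways": out_dir / "pathways.gmt",
        "phenotypes": out_dir / "phenotypes.tsv",
        "members": out_dir / "phenotype_members.txt",
    }
    write_edgelist(context.ppi, paths["ppi"])
    write_gmt(context.herb_genes, paths["herb_genes"])
    write_gmt(context.disease_genes, paths["disease_genes"])
    write_gmt(context.pathways, paths["pathways"])
    context.phenotypes.to_csv(paths["phenotypes"], sep="\t")
    paths["members"].write_text(
        "\n".join(sorted(context.phenotype_members or [])) + "\n"
    )
    return paths
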