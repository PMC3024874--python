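"""Herb-biomolecule-disease co-module analysis.

A multi-herb formula that treats several apparently unrelated diseases may
act through a shared biomolecular module.  Given herb -> responsive-gene
sets, disease -> disease-gene sets, a protein-protein interaction (PPI)
network and a phenotype-by-feature matrix, this module quantifies three
lines of evidence:

1. **Pathway enrichment** of the pooled herb genes (and disease genes):
   one-sided Fisher exact / hypergeometric upper-tail test per pathway,
   Benjamini-Hochberg FDR across pathways.
2. **Network closeness**: the mean shortest-path length between the herb
   gene set and the disease gene set on the PPI network, with a permutation
   null that redraws the disease set (same size, without replacement) from
   a pool of networked disease genes while the herb set stays fixed.
   p = (r + 1) / (n_perm + 1) where r counts permuted means <= observed, so
   p is never zero.
3. **Phenotype similarity**: the mean pairwise cosine similarity of the
   member phenotypes' feature vectors, against a null of equally many
   randomly drawn phenotypes; p = (r + 1)/(n_perm + 1), r counting permuted
   means >= observed.

The tripartite projection links two herbs when they share responsive genes
and two diseases when they share disease genes (edge weight = shared-gene
count); the core genes belong to at least one herb set and one disease set.

Model-object entry point::

    res = CoModule(context, n_perm=2000).fit(seed=7)
    print(res.summary())
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ENRICHMENT_COLUMNS = [
    "pathway_id", "overlap", "set_size", "pathway_size",
    "background_size", "fisher_p", "fdr",
]


@dataclass
class OmicsContext:
    """All inputs of the co-module analysis, with consistent gene ids.

    ``background`` defaults to the PPI nodes unioned with every gene set;
    ``disease_pool`` (permutation pool) defaults to the PPI node set.
    ``phenotype_members`` names the phenotype rows attributed to the
    studied diseases.
    """

    ppi: nx.Graph
    pathways: dict[str, set] = field(default_factory=dict)
    herb_genes: dict[str, set] = field(default_factory=dict)
    disease_genes: dict[str, set] = field(default_factory=dict)
    phenotypes: pd.DataFrame | None = None
    background: set | None = None
    disease_pool: set | None = None
    phenotype_members: set | None = None

    def __post_init__(self) -> None:
        nodes = set(self.ppi.nodes)
        if self.background is None:
            self.background = nodes | set().union(
                *self.pathways.values(),
                *self.herb_genes.values(),
                *self.disease_genes.values(),
                set(),
            )
        if self.disease_pool is None:
            self.disease_pool = set(nodes)
        elif not set(self.disease_pool) <= nodes:
            raise ValueError("disease_pool must be a subset of the PPI nodes")

    @property
    def herb_gene_union(self) -> set:
        return set().union(*self.herb_genes.values(), set())

    @property
    def disease_gene_union(self) -> set:
        return set().union(*self.disease_genes.values(), set())


# -- file formats ----------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set]:
    """GMT gene sets: ``name<TAB>description<TAB>gene1<TAB>gene2...``."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need name, description, genes")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    """Undirected interaction network from a two-column edge-list TSV."""
    G = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: edge rows need two columns")
            if parts[0] != parts[1]:   # drop self-loops
                G.add_edge(parts[0], parts[1])
    return G


def write_edgelist(G: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(map(sorted, G.edges())):
            fh.write(f"{u}\t{v}\n")


def read_phenotype_matrix(path: str | Path) -> pd.DataFrame:
    """Phenotype-by-feature TSV; first column holds phenotype ids."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


# -- (1) pathway enrichment ------------------------------------------------


def pathway_enrichment(
    gene_set: Iterable[str],
    pathways: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of ``gene_set`` in each pathway.

    The p-value is the hypergeometric upper tail P(X >= overlap) drawing
    |gene_set| genes from the background; FDR is Benjamini-Hochberg across
    the tested pathways.  Rows sorted by FDR, then raw p.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background gene universe is empty")
    gs = set(gene_set) & bg
    if not gs:
        raise ValueError("gene set is empty after intersecting with the background")
    N, n = len(bg), len(gs)
    rows = []
    for pid, genes in pathways.items():
        pw = set(genes) & bg
        k = len(gs & pw)
        p = float(stats.hypergeom.sf(k - 1, N, len(pw), n))
        rows.append({
            "pathway_id": pid, "overlap": k, "set_size": n,
            "pathway_size": len(pw), "background_size": N, "fisher_p": p,
        })
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if len(df):
        df["fdr"] = multipletests(df["fisher_p"], method="fdr_bh")[1]
        df = df.sort_values(["fdr", "fisher_p", "pathway_id"]).reset_index(drop=True)
    else:
        df["fdr"] = []
    return df


# -- (2) network closeness -------------------------------------------------


class _ClosenessEngine:
    """Distances from a fixed source gene set, pre-computed once so that
    thousands of permuted target sets can be scored by array indexing."""

    def __init__(self, ppi: nx.Graph, set_a: Iterable[str]):
        self.nodes = list(ppi.nodes)
        self.index = {g: i for i, g in enumerate(self.nodes)}
        self.sources = sorted(set(set_a) & set(self.nodes))
        if not self.sources:
            raise ValueError("source gene set has no genes on the network")
        D = np.full((len(self.sources), len(self.nodes)), np.inf)
        for r, a in enumerate(self.sources):
            for node, d in nx.single_source_shortest_path_length(ppi, a).items():
                D[r, self.index[node]] = d
        self.D = D
        self._source_row = {a: r for r, a in enumerate(self.sources)}

    def mean_path(self, set_b: Iterable[str]) -> tuple[float, float]:
        """(mean shortest path over connected cross pairs, covered fraction).

        Cross pairs with identical endpoints are excluded; an unreachable
        target contributes to the denominator of the coverage only.
        Returns (inf, 0.0) when no cross pair is connected.
        """
        cols = [self.index[b] for b in set_b if b in self.index]
        if not cols:
            raise ValueError("target gene set has no genes on the network")
        sub = self.D[:, cols]
        keep = np.ones_like(sub, dtype=bool)
        for j, b in enumerate(g for g in set_b if g in self.index):
            r = self._source_row.get(b)
            if r is not None:
                keep[r, j] = False      # self-pair: same gene on both sides
        finite = keep & np.isfinite(sub)
        total = int(keep.sum())
        connected = int(finite.sum())
        if total == 0 or connected == 0:
            return float("inf"), 0.0
        return float(sub[finite].sum() / connected), connected / total


def average_shortest_path(
    ppi: nx.Graph, set_a: Iterable[str], set_b: Iterable[str]
) -> tuple[float, float]:
    """Mean shortest-path length between two gene sets on the PPI network.

    Averages over all cross pairs (a, b), a != b, that are connected;
    also returns the fraction of cross pairs that were connected.
    Disconnected pairs are excluded from the mean rather than given an
    arbitrary length.
    """
    engine = _ClosenessEngine(ppi, set_a)
    mean, coverage = engine.mean_path(sorted(set(set_b)))
    if not np.isfinite(mean):
        raise ValueError("no connected cross pair between the two gene sets")
    return mean, coverage


def closeness_permutation(
    ppi: nx.Graph,
    set_a: Iterable[str],
    set_b: Iterable[str],
    pool: Iterable[str],
    n_perm: int = 2000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for the closeness of ``set_a`` and ``set_b``.

    ``set_a`` stays fixed; each of ``n_perm`` draws replaces ``set_b`` by an
    equally sized set sampled without replacement from ``pool`` (networked
    genes).  p = (r + 1)/(n_perm + 1) with r the number of permuted means
    <= the observed mean, so a set closer than every draw yields
    1/(n_perm + 1), never 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    engine = _ClosenessEngine(ppi, set_a)
    nodes = set(engine.index)
    b_on_net = sorted(set(set_b) & nodes)
    if not b_on_net:
        raise ValueError("set_b has no genes on the network")
    pool = sorted(set(pool))
    if not set(pool) <= nodes:
        raise ValueError("permutation pool must lie on the PPI network")
    size = len(b_on_net)
    if len(pool) < size:
        raise ValueError(f"pool of {len(pool)} genes cannot supply draws of size {size}")
    observed, _ = engine.mean_path(b_on_net)
    if not np.isfinite(observed):
        raise ValueError("no connected cross pair between the two gene sets")
    rng = np.random.default_rng(seed)
    pool_arr = np.asarray(pool, dtype=object)
    r = 0
    for _ in range(n_perm):
        draw = pool_arr[rng.choice(len(pool_arr), size=size, replace=False)]
        mean, _ = engine.mean_path(list(draw))
        if mean <= observed:
            r += 1
    return (r + 1) / (n_perm + 1)


# -- (3) phenotype similarity ----------------------------------------------


def _unit_rows(phenotypes: pd.DataFrame, members: list) -> np.ndarray:
    missing = [p for p in members if p not in phenotypes.index]
    if missing:
        raise ValueError(f"unknown phenotype id(s): {missing}")
    M = phenotypes.loc[members].to_numpy(dtype=float)
    norms = np.linalg.norm(M, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(
            f"phenotype {members[bad[0]]!r} has a zero-norm feature vector"
        )
    return M / norms[:, None]


def phenotype_similarity(phenotypes: pd.DataFrame, members: Iterable) -> float:
    """Mean pairwise cosine similarity of the member phenotypes' rows."""
    members = sorted(set(members))
    if len(members) < 2:
        raise ValueError("need at least two phenotypes to compare")
    U = _unit_rows(phenotypes, members)
    S = U @ U.T
    iu = np.triu_indices(len(members), k=1)
    return float(S[iu].mean())


def phenotype_permutation(
    phenotypes: pd.DataFrame,
    members: Iterable,
    n_perm: int = 2000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for the members' mean cosine similarity against
    equally many phenotypes drawn at random from the whole matrix.

    p = (r + 1)/(n_perm + 1), r counting permuted means >= observed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = sorted(set(members))
    observed = phenotype_similarity(phenotypes, members)
    ids = list(phenotypes.index)
    size = len(members)
    if size > len(ids):
        raise ValueError("more members than phenotype rows")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(size, k=1)
    r = 0
    for _ in range(n_perm):
        # sorted so that a draw equal to the member set reproduces the
        # observed mean bit-for-bit (summation order)
        draw = sorted(ids[i] for i in rng.choice(len(ids), size=size, replace=False))
        U = _unit_rows(phenotypes, draw)
        mean = float((U @ U.T)[iu].mean())
        if mean >= observed:
            r += 1
    return (r + 1) / (n_perm + 1)


# -- tripartite projection -------------------------------------------------


@dataclass
class ComoduleResult:
    """Tripartite co-module: herb and disease modules joined by core genes."""

    herb_module: nx.Graph
    disease_module: nx.Graph
    core_genes: set
    networked_core: set
    empty_core: bool
    closeness: float | None = None
    closeness_coverage: float | None = None
    closeness_p: float | None = None
    phenotype_similarity: float | None = None
    phenotype_p: float | None = None


def _shared_gene_graph(sets: Mapping[str, set], min_shared: int) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(sets)
    for a, b in itertools.combinations(sorted(sets), 2):
        shared = len(set(sets[a]) & set(sets[b]))
        if shared >= min_shared:
            G.add_edge(a, b, weight=shared, shared_genes=shared)
    return G


def build_comodule(
    herb_genes: Mapping[str, set],
    disease_genes: Mapping[str, set],
    ppi: nx.Graph | None = None,
    min_shared: int = 1,
    neighborhood: int = 0,
) -> ComoduleResult:
    """Project the herb and disease layers onto shared-gene modules.

    Two herbs are linked when they share at least ``min_shared`` responsive
    genes (edge weight = shared count); diseases likewise.  Core genes
    belong to >= 1 herb set and >= 1 disease set; ``networked_core`` maps
    them onto the PPI network, optionally expanded by their direct PPI
    neighbours (``neighborhood=1``).
    """
    if len(herb_genes) < 2 or len(disease_genes) < 2:
        raise ValueError("need at least two herbs and two diseases")
    if neighborhood not in (0, 1):
        raise ValueError("neighborhood must be 0 or 1")
    herb_module = _shared_gene_graph(dict(herb_genes), min_shared)
    disease_module = _shared_gene_graph(dict(disease_genes), min_shared)
    herb_union = set().union(*herb_genes.values())
    disease_union = set().union(*disease_genes.values())
    core = herb_union & disease_union
    networked = core & set(ppi.nodes) if ppi is not None else set(core)
    if ppi is not None and neighborhood == 1:
        networked = networked | {
            nb for g in networked for nb in ppi.neighbors(g)
        }
    return ComoduleResult(
        herb_module=herb_module,
        disease_module=disease_module,
        core_genes=core,
        networked_core=networked,
        empty_core=not core,
    )


# -- model / results -------------------------------------------------------


class CoModule:
    """Joint herb-gene-disease analysis over an :class:`OmicsContext`.

    ``fit(seed)`` runs pathway enrichment for the pooled herb and disease
    gene sets, the closeness permutation test, the phenotype-similarity
    permutation test, and the tripartite co-module projection.
    """

    def __init__(
        self,
        context: OmicsContext,
        n_perm: int = 2000,
        min_shared: int = 1,
        neighborhood: int = 0,
        fdr_threshold: float = 0.05,
    ):
        if not context.herb_genes or not context.disease_genes:
            raise ValueError("context needs herb_genes and disease_genes mappings")
        self.context = context
        self.n_perm = n_perm
        self.min_shared = min_shared
        self.neighborhood = neighborhood
        self.fdr_threshold = fdr_threshold

    @property
    def config(self) -> dict:
        return {
            "n_perm": self.n_perm,
            "min_shared": self.min_shared,
            "neighborhood": self.neighborhood,
            "fdr_threshold": self.fdr_threshold,
        }

    def fit(self, seed: int | None = None) -> "CoModuleResults":
        ctx = self.context
        rng = np.random.default_rng(seed)
        close_seed = int(rng.integers(2**31))
        pheno_seed = int(rng.integers(2**31))

        herb_union = ctx.herb_gene_union
        disease_union = ctx.disease_gene_union
        herb_enrichment = disease_enrichment = None
        if ctx.pathways:
            herb_enrichment = pathway_enrichment(herb_union, ctx.pathways, ctx.background)
            disease_enrichment = pathway_enrichment(
                disease_union, ctx.pathways, ctx.background
            )

        comod = build_comodule(
            ctx.herb_genes, ctx.disease_genes, ctx.ppi,
            min_shared=self.min_shared, neighborhood=self.neighborhood,
        )
        comod.closeness, comod.closeness_coverage = average_shortest_path(
            ctx.ppi, herb_union, disease_union
        )
        comod.closeness_p = closeness_permutation(
            ctx.ppi, herb_union, disease_union, ctx.disease_pool,
            n_perm=self.n_perm, seed=close_seed,
        )
        if ctx.phenotypes is not None and ctx.phenotype_members:
            comod.phenotype_similarity = phenotype_similarity(
                ctx.phenotypes, ctx.phenotype_members
            )
            comod.phenotype_p = phenotype_permutation(
                ctx.phenotypes, ctx.phenotype_members,
                n_perm=self.n_perm, seed=pheno_seed,
            )
        return CoModuleResults(
            self, comod, herb_enrichment, disease_enrichment, seed
        )


class CoModuleResults:
    """Fitted co-module statistics with a text summary and JSON export."""

    def __init__(
        self,
        model: CoModule,
        comodule: ComoduleResult,
        herb_enrichment: pd.DataFrame | None,
        disease_enrichment: pd.DataFrame | None,
        seed: int | None,
    ):
        self.model = model
        self.comodule = comodule
        self.herb_enrichment = herb_enrichment
        self.disease_enrichment = disease_enrichment
        self.seed = seed

    # convenience passthroughs
    @property
    def closeness(self) -> float:
        return self.comodule.closeness

    @property
    def closeness_p(self) -> float:
        return self.comodule.closeness_p

    @property
    def phenotype_similarity(self) -> float | None:
        return self.comodule.phenotype_similarity

    @property
    def phenotype_p(self) -> float | None:
        return self.comodule.phenotype_p

    def _enriched_count(self, df: pd.DataFrame | None) -> int | None:
        if df is None:
            return None
        return int((df["fdr"] < self.model.fdr_threshold).sum())

    def as_dict(self) -> dict:
        c = self.comodule
        return {
            "seed": self.seed,
            "config": self.model.config,
            "n_herbs": len(self.model.context.herb_genes),
            "n_diseases": len(self.model.context.disease_genes),
            "core_genes": sorted(c.core_genes),
            "networked_core": sorted(c.networked_core),
            "empty_core": c.empty_core,
            "herb_module_edges": c.herb_module.number_of_edges(),
            "disease_module_edges": c.disease_module.number_of_edges(),
            "closeness": c.closeness,
            "closeness_coverage": c.closeness_coverage,
            "closeness_p": c.closeness_p,
            "phenotype_similarity": c.phenotype_similarity,
            "phenotype_p": c.phenotype_p,
            "herb_pathways_enriched": self._enriched_count(self.herb_enrichment),
            "disease_pathways_enriched": self._enriched_count(self.disease_enrichment),
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)
            fh.write("\n")

    def summary(self) -> str:
        c = self.comodule
        lines = [
            "Herb-biomolecule-disease co-module analysis",
            "=" * 54,
            f"Herbs / diseases:        {len(self.model.context.herb_genes)}"
            f" / {len(self.model.context.disease_genes)}",
            f"Herb-module edges:       {c.herb_module.number_of_edges()}",
            f"Disease-module edges:    {c.disease_module.number_of_edges()}",
            f"Core genes:              {len(c.core_genes)}"
            f" ({len(c.networked_core)} on the PPI network)"
            + ("  [EMPTY CORE]" if c.empty_core else ""),
            f"Closeness (mean path):   {c.closeness:.4f}"
            f" (coverage {c.closeness_coverage:.3f})",
            f"Closeness permutation p: {c.closeness_p:.4g}"
            f"  ({self.model.n_perm} permutations)",
        ]
        if c.phenotype_similarity is not None:
            lines += [
                f"Phenotype similarity:    {c.phenotype_similarity:.4f}",
                f"Phenotype permutation p: {c.phenotype_p:.4g}",
            ]
        if self.herb_enrichment is not None:
            lines.append(
                f"Pathways enriched (FDR<{self.model.fdr_threshold}): "
                f"herb genes {self._enriched_count(self.herb_enrichment)}, "
                f"disease genes {self._enriched_count(self.disease_enrichment)}"
            )
        return "\n".join(lines)
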