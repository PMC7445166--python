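"""Seed-anchored module detection on a PPI network (MCODE-style).

The pipeline is: weight every vertex by the density of the highest k-core of
its closed neighborhood, grow vertex-disjoint complexes greedily from
high-weight seeds, keep complexes whose member genes are over-represented
for seed genes, and finally intersect the three per-phenotype modules into
the toxicity module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def _highest_k_core(graph: nx.Graph) -> tuple[int, nx.Graph]:
    """Max k with a non-empty k-core, and that core subgraph."""
    if graph.number_of_edges() == 0:
        return 0, graph
    core_num = nx.core_number(graph)
    k = max(core_num.values())
    nodes = [v for v, c in core_num.items() if c >= k]
    return k, graph.subgraph(nodes)


def mcode_vertex_weights(network: nx.Graph) -> dict[str, float]:
    """MCODE vertex weight: k * density of the highest k-core of N[v].

    The closed neighborhood includes v itself.  Isolated vertices weigh 0.
    """
    weights: dict[str, float] = {}
    for v in network.nodes:
        nbrs = list(network.neighbors(v))
        if not nbrs:
            weights[v] = 0.0
            continue
        sub = network.subgraph([v, *nbrs])
        k, core = _highest_k_core(sub)
        weights[v] = k * _density(core)
    return weights


@dataclass
class MCODEComplex:
    members: frozenset[str]
    seed: str
    score: float
    survives_2core: bool = True

    @property
    def size(self) -> int:
        return len(self.members)


def _two_core(graph: nx.Graph) -> nx.Graph:
    """2-core by iterative removal of degree<2 vertices (== k_core(2))."""
    g = graph.copy()
    changed = True
    while changed:
        drop = [v for v, d in g.degree() if d < 2]
        changed = bool(drop)
        g.remove_nodes_from(drop)
    return g


def mcode_find_complexes(
    network: nx.Graph,
    weights: Mapping[str, float],
    vwp: float = 0.5,
    haircut: bool = True,
    fluff: bool = False,
) -> list[MCODEComplex]:
    """Greedy complex growth from high-weight seeds.

    Starting from the highest-weight unvisited vertex, neighbors with weight
    >= (1 - vwp) * seed weight are added recursively; every added vertex is
    marked visited, so complexes are vertex-disjoint.  Complexes with no
    2-core are discarded; haircut then iteratively strips degree-1 members.
    Output is sorted by score (= density * size) descending.
    """
    if not 0 <= vwp < 1:
        raise ValueError(f"vwp must be in [0, 1), got {vwp}")
    if fluff:
        raise NotImplementedError("fluff post-processing is not supported")
    # deterministic order: weight desc, then gene id
    order = sorted(network.nodes, key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    complexes: list[MCODEComplex] = []
    for seed in order:
        if seed in visited:
            continue
        threshold = (1.0 - vwp) * weights[seed]
        members = {seed}
        visited.add(seed)
        stack = [seed]
        while stack:
            v = stack.pop()
            for u in network.neighbors(v):
                if u in visited:
                    continue
                if weights[u] >= threshold:
                    visited.add(u)
                    members.add(u)
                    stack.append(u)
        sub = network.subgraph(members)
        core2 = _two_core(sub)
        if core2.number_of_nodes() == 0:
            continue  # no 2-core: not a complex
        if haircut:
            members = set(core2.nodes)  # iterated degree-1 removal == 2-core
            sub = network.subgraph(members)
        score = _density(sub) * len(members)
        complexes.append(MCODEComplex(frozenset(members), seed, score))
    complexes.sort(key=lambda c: (-c.score, -c.size, c.seed))
    return complexes


@dataclass
class SeededModule:
    genes: set[str]
    seeds_contained: set[str]
    complex_pvalues: list[tuple[frozenset, float, bool]] = field(default_factory=list)


def seed_module(
    network: nx.Graph,
    complexes: Sequence[MCODEComplex],
    seed_genes: Iterable[str],
    enrich_alpha: float = 0.05,
) -> SeededModule:
    """Union of complexes over-represented for seed genes.

    Each complex is tested one-sided (greater) by the hypergeometric law
    against the network node universe; complexes with p < ``enrich_alpha``
    are merged into the module.
    """
    universe = set(network.nodes)
    seeds = set(seed_genes)
    unknown = seeds - universe
    if unknown:
        logger.info("dropping %d seed gene(s) absent from the network", len(unknown))
        seeds -= unknown
    N, K = len(universe), len(seeds)
    module: set[str] = set()
    tested = []
    for cx in complexes:
        n = cx.size
        k = len(cx.members & seeds)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        include = p < enrich_alpha
        tested.append((cx.members, p, include))
        if include:
            module |= set(cx.members)
    if not module:
        logger.warning("no complex enriched for seeds; module is empty")
    return SeededModule(genes=module, seeds_contained=module & seeds, complex_pvalues=tested)


@dataclass
class ToxicityModule:
    """Genes shared by >= min_overlap of the per-phenotype modules."""

    genes: set[str]
    membership: dict[str, tuple[bool, bool, bool]]
    phenotypes: tuple[str, str, str]
    min_overlap: int
    member_variants: dict[str, list[str]] = field(default_factory=dict)


def toxicity_overlap(
    modules: Mapping[str, set[str]],
    min_overlap: int = 2,
    variant_gene_map: Mapping[str, str] | None = None,
) -> ToxicityModule:
    """Cross-phenotype overlap of exactly three per-phenotype gene modules.

    ``variant_gene_map`` (variant_id -> gene_id, typically restricted to the
    nominal variants) attaches member variants to module genes.
    """
    if len(modules) != 3:
        raise ValueError(f"expected exactly 3 phenotype modules, got {len(modules)}")
    if min_overlap not in (2, 3):
        raise ValueError("min_overlap must be 2 or 3")
    phenos = tuple(modules)
    for p, genes in modules.items():
        if not genes:
            logger.warning("phenotype module %r is empty", p)
    counts: dict[str, int] = {}
    for genes in modules.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, c in counts.items() if c >= min_overlap}
    membership = {g: tuple(g in modules[p] for p in phenos) for g in shared}
    member_variants: dict[str, list[str]] = {}
    if variant_gene_map:
        for vid, gene in variant_gene_map.items():
            if gene in shared:
                member_variants.setdefault(gene, []).append(vid)
        member_variants = {g: sorted(vs) for g, vs in member_variants.items()}
    return ToxicityModule(shared, membership, phenos, min_overlap, member_variants)
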