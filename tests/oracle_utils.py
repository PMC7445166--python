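"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the implementation's code paths: k-cores by naive
iterative stripping (no networkx core machinery), complex growth by
recursion, AUC by all-pairs comparison, Fisher p-values by margin-grouped
exact integer enumeration.
"""

import itertools
from math import comb

import networkx as nx


def oracle_highest_k_core(edges, nodes):
    """Max k with non-empty k-core, plus that core's nodes, by stripping."""
    best_k, best_nodes = 0, set(nodes)
    k = 1
    while True:
        keep = set(nodes)
        changed = True
        while changed:
            deg = {v: 0 for v in keep}
            for u, v in edges:
                if u in keep and v in keep:
                    deg[u] += 1
                    deg[v] += 1
            drop = {v for v in keep if deg[v] < k}
            keep -= drop
            changed = bool(drop)
        if not keep:
            return best_k, best_nodes
        best_k, best_nodes = k, keep
        k += 1


def oracle_vertex_weight(graph, v):
    nbrs = set(graph.neighbors(v)) | {v}
    edges = [(a, b) for a, b in graph.edges if a in nbrs and b in nbrs]
    k, core = oracle_highest_k_core(edges, nbrs)
    n = len(core)
    if n < 2:
        return 0.0
    m = sum(1 for a, b in edges if a in core and b in core)
    return k * 2 * m / (n * (n - 1))


def oracle_two_core_members(graph, members):
    edges = [(a, b) for a, b in graph.edges if a in members and b in members]
    keep = set(members)
    changed = True
    while changed:
        deg = {v: 0 for v in keep}
        for u, v in edges:
            if u in keep and v in keep:
                deg[u] += 1
                deg[v] += 1
        drop = {v for v in keep if deg[v] < 2}
        keep -= drop
        changed = bool(drop)
    return keep


def oracle_complexes(graph, weights, vwp):
    """Recursive re-derivation of the greedy seed-growth complexes."""
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    visited = set()
    out = []
    for seed in order:
        if seed in visited:
            continue
        threshold = (1 - vwp) * weights[seed]
        members = {seed}
        visited.add(seed)

        def grow(v):
            for u in graph.neighbors(v):
                if u not in visited and weights[u] >= threshold:
                    visited.add(u)
                    members.add(u)
                    grow(u)

        grow(seed)
        core = oracle_two_core_members(graph, members)
        if not core:
            continue
        n = len(core)
        m = sum(1 for a, b in graph.edges if a in core and b in core)
        density = 2 * m / (n * (n - 1)) if n > 1 else 0.0
        out.append((frozenset(core), density * n))
    out.sort(key=lambda t: -t[1])
    return out


def all_graphs(n):
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(2 ** len(pairs)):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(p for i, p in enumerate(pairs) if bits >> i & 1)
        yield g


def oracle_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def oracle_fisher_margin_family(r1, r2, c1):
    """Exact two-sided Fisher p for every table with the given margins.

    Returns {a: p}.  Works in integers: a table is counted iff its
    hypergeometric weight is <= the observed one, compared exactly.
    """
    n = r1 + r2
    total = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = list(range(lo, hi + 1))
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in ks}
    ordered = sorted(ks, key=lambda k: weights[k])
    prefix = []
    acc = 0
    for k in ordered:
        acc += weights[k]
        prefix.append(acc)
    out = {}
    for k in ks:
        w = weights[k]
        # largest index in `ordered` whose weight <= w
        idx = max(i for i, kk in enumerate(ordered) if weights[kk] <= w)
        out[k] = prefix[idx] / total
    return out
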