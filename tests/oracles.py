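"""Independent oracles used by the test suite.

Each oracle is a naive, definitional implementation kept deliberately
separate from the package code paths it checks: exact integer enumeration
for the hypergeometric tail, the literal step-up recursion for the
Benjamini-Hochberg adjustment, a scan-everything union builder for the
typed network, and exhaustive threshold search for hub detection.
"""

from __future__ import annotations

import math
import random


def hypergeom_sf_vector(N: int, K: int, n: int) -> list[float]:
    """Exact upper-tail P(X >= k) for k = 0..min(K, n) by integer enumeration."""
    m = min(K, n)
    denom = math.comb(N, n)
    terms = [math.comb(K, j) * math.comb(N - K, n - j) for j in range(m + 1)]
    out = [0.0] * (m + 1)
    acc = 0
    for j in range(m, -1, -1):
        acc += terms[j]
        out[j] = acc / denom
    return out


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    return hypergeom_sf_vector(N, K, n)[k]


def bh_stepup(pvals) -> list[float]:
    """Literal Benjamini-Hochberg step-up: adj_(i) = min_{j>=i} p_(j)*m/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: (pvals[i], i))
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = running
    return adjusted


def union_network(candidates, ddi_edges, dt_edges, dg_edges, ppi_edges):
    """Naive union + role assignment by scanning every edge list.

    Returns (node -> role, set of (a, b, relation) with a < b).
    """
    cand = set(candidates)
    roles: dict[str, str] = {c: "candidate_drug" for c in cand}
    edges: set[tuple[str, str, str]] = set()

    drug_ids = set(cand)
    for e in ddi_edges:
        drug_ids.add(e.drug_id)
        drug_ids.add(e.partner_id)
        a, b = sorted((e.drug_id, e.partner_id))
        edges.add((a, b, "DDI"))
    for e in dt_edges:
        drug_ids.add(e.drug_id)
    for e in dg_edges:
        drug_ids.add(e.drug_id)
    for d in drug_ids:
        if d not in cand:
            roles[d] = "interacting_drug"

    dt_syms = {e.symbol for e in dt_edges}
    dg_syms = {e.symbol for e in dg_edges}
    for e in dt_edges:
        a, b = sorted((e.drug_id, e.symbol))
        edges.add((a, b, "DT"))
    for e in dg_edges:
        a, b = sorted((e.drug_id, e.symbol))
        edges.add((a, b, "DG"))
    for e in ppi_edges:
        edges.add((e.symbol_a, e.symbol_b, "PPI"))

    gene_ids = dt_syms | dg_syms | {s for e in ppi_edges for s in (e.symbol_a, e.symbol_b)}
    for g in gene_ids:
        if g in dt_syms and g in dg_syms:
            roles[g] = "target_and_gene"
        elif g in dt_syms:
            roles[g] = "target"
        elif g in dg_syms:
            roles[g] = "associated_gene"
        else:
            roles[g] = "interactor_protein"
    return roles, edges


def hub_threshold_search(degrees: dict[str, int], fraction: float):
    """Exhaustive search over every candidate threshold 0..max_degree+1."""
    n = len(degrees)
    max_deg = max(degrees.values())
    chosen = None
    for d in range(0, max_deg + 2):
        if sum(1 for v in degrees.values() if v >= d) <= fraction * n:
            chosen = d
            break
    hubs = {x for x, v in degrees.items() if v >= chosen}
    if not hubs:
        chosen = max_deg
        hubs = {x for x, v in degrees.items() if v == max_deg}
    return chosen, hubs


def random_edge_sets(seed: int, max_edges: int = 1000):
    """A random typed-edge instance with disjoint drug/gene namespaces."""
    from dtome import DDIEdge, DGEdge, DTEdge
    from dtome.kb_io import make_ppi_edge

    rng = random.Random(seed)
    n_cand = rng.randint(1, 3)
    candidates = [f"D{i:03d}" for i in range(n_cand)]
    drug_pool = [f"D{i:03d}" for i in range(n_cand, n_cand + rng.randint(2, 30))]
    gene_pool = [f"S{i:03d}" for i in range(rng.randint(5, 60))]

    ddi = [
        DDIEdge(rng.choice(candidates), rng.choice(drug_pool), "adverse interaction")
        for _ in range(rng.randint(0, max_edges // 4))
    ]
    dt = [
        DTEdge(rng.choice(candidates), rng.choice(gene_pool))
        for _ in range(rng.randint(0, max_edges // 4))
    ]
    dg = [
        DGEdge(rng.choice(candidates), rng.choice(gene_pool), frozenset({"PK"}))
        for _ in range(rng.randint(0, max_edges // 4))
    ]
    ppi = []
    for _ in range(rng.randint(0, max_edges // 4)):
        a, b = rng.sample(gene_pool, 2)
        ppi.append(make_ppi_edge(a, b, sources=("src",)))
    return candidates, ddi, dt, dg, ppi
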