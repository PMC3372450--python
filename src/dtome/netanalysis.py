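"""Network characteristics: degree, distribution, hubs, simplification, modules.

The degree of a node counts every incident edge regardless of relation, so
a gene linked to a drug by both a target and an association edge gains two.
Hub detection replaces an eyeballed degree-distribution plateau with a
deterministic tie-inclusive top-fraction rule (a mean + 2·SD rule is
available for comparison). Network simplification mirrors the descriptive
reduction used for single-drug interactomes: drop every drug node except
the candidates, then drop nodes left with at most one link.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .netbuild import DRUG_ROLES, DTomeNetwork


def node_degrees(net: DTomeNetwork) -> pd.DataFrame:
    """Per-node degree table (columns: id, role, degree), sorted by id."""
    rows = [
        {"id": n, "role": net.graph.nodes[n].get("role"), "degree": d}
        for n, d in net.graph.degree()
    ]
    table = pd.DataFrame(rows, columns=["id", "role", "degree"])
    return table.sort_values("id", ignore_index=True)


def degree_distribution(table: pd.DataFrame) -> dict[int, int]:
    """Exact histogram: degree value -> number of nodes with that degree."""
    if table.empty:
        return {}
    counts = table["degree"].value_counts().sort_index()
    return {int(d): int(c) for d, c in counts.items()}


@dataclass
class HubSet:
    threshold_degree: int
    hubs: frozenset[str]
    method: str = "top_fraction"


def find_hubs(table: pd.DataFrame, fraction: float = 0.05, method: str = "top_fraction") -> HubSet:
    """Tie-inclusive high-degree node set.

    ``top_fraction``: the threshold is the smallest degree d such that at
    most ``fraction * n`` nodes have degree >= d; every node at or above the
    threshold is a hub (ties included, so the set may exceed the fraction).
    If that leaves the set empty (e.g. all degrees equal), the nodes of
    maximum degree are the hubs. ``mean_sd`` thresholds at mean + 2·SD.
    """
    if table.empty:
        raise ValidationError("cannot find hubs in an empty degree table")
    degrees = table.set_index("id")["degree"]
    if method == "mean_sd":
        threshold = int(np.ceil(degrees.mean() + 2 * degrees.std(ddof=0)))
        hubs = frozenset(degrees.index[degrees >= threshold])
        if not hubs:
            threshold = int(degrees.max())
            hubs = frozenset(degrees.index[degrees == degrees.max()])
        return HubSet(threshold_degree=threshold, hubs=hubs, method=method)
    if method != "top_fraction":
        raise ValidationError(f"unknown hub method {method!r}")
    if not 0 < fraction < 1:
        raise ValidationError(f"hub fraction must be in (0, 1), got {fraction}")
    n = len(degrees)
    budget = fraction * n
    max_deg = int(degrees.max())
    threshold = None
    for d in range(0, max_deg + 2):
        if int((degrees >= d).sum()) <= budget:
            threshold = d
            break
    if threshold is None:
        threshold = max_deg
    hubs = frozenset(degrees.index[degrees >= threshold])
    if not hubs:
        threshold = max_deg
        hubs = frozenset(degrees.index[degrees == max_deg])
    return HubSet(threshold_degree=int(threshold), hubs=hubs, method="top_fraction")


@dataclass
class SimplifyReport:
    n_drugs_removed: int
    n_low_degree_removed: int
    passes: int


def simplify_network(
    net: DTomeNetwork,
    candidate_ids,
    iterate: bool = False,
    drug_removal_first: bool = True,
) -> tuple[DTomeNetwork, SimplifyReport]:
    """Reduce a network to the candidate drugs and their connected core.

    Step 1 removes every drug node not in ``candidate_ids`` (with incident
    edges); step 2 removes non-candidate nodes whose degree in the step-1
    graph is <= 1, in a single pass with degrees measured before any
    removal. ``iterate`` repeats step 2 to a fixpoint; ``drug_removal_first``
    can flip the step order. Candidates are never removed.
    """
    cand = set(candidate_ids)
    missing = sorted(n for n in cand if n not in net.graph)
    if missing:
        raise ValidationError(f"candidate ids not in network: {missing}")

    g = net.graph.copy()

    def drop_drugs() -> int:
        doomed = [
            n
            for n in list(g.nodes)
            if g.nodes[n].get("role") in DRUG_ROLES and n not in cand
        ]
        g.remove_nodes_from(doomed)
        return len(doomed)

    def drop_low_degree() -> tuple[int, int]:
        removed = 0
        passes = 0
        while True:
            passes += 1
            doomed = [n for n in list(g.nodes) if n not in cand and g.degree(n) <= 1]
            g.remove_nodes_from(doomed)
            removed += len(doomed)
            if not doomed or not iterate:
                break
        return removed, passes

    if drug_removal_first:
        n_drugs = drop_drugs()
        n_low, passes = drop_low_degree()
    else:
        n_low, passes = drop_low_degree()
        n_drugs = drop_drugs()

    return DTomeNetwork(g), SimplifyReport(
        n_drugs_removed=n_drugs, n_low_degree_removed=n_low, passes=passes
    )


def assign_modules(net: DTomeNetwork, method: str = "components") -> dict[str, int]:
    """Partition nodes into modules.

    ``components`` labels connected components; ``greedy`` uses greedy
    modularity communities on the simple-graph view. Labels are assigned
    in order of each module's smallest node id, so they are deterministic.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return {}
    if method == "components":
        parts = list(nx.connected_components(g))
    elif method == "greedy":
        simple = nx.Graph(g)
        parts = [set(c) for c in nx.community.greedy_modularity_communities(simple)]
        # greedy modularity only covers nodes with edges; isolated nodes
        # become singleton modules
        covered = set().union(*parts) if parts else set()
        parts.extend({n} for n in g.nodes if n not in covered)
    else:
        raise ValidationError(f"unknown module method {method!r}")
    labels: dict[str, int] = {}
    for idx, part in enumerate(sorted(parts, key=min)):
        for n in part:
            labels[n] = idx
    return labels
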