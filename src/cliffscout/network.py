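"""Activity-cliff networks.

Compounds are nodes, pairwise cliffs are edges.  Connected components
("AC clusters") with a single edge are *isolated* cliffs; components with
two or more edges are *coordinated* — overlapping cliffs formed by groups
of analogs, which carry far more SAR information than isolated pairs.
Densely connected nodes are *hubs* (also called AC generators): typically
a highly potent compound with many weakly potent analogs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .cliffs import ActivityCliff


@dataclass
class ClusterReport:
    component_id: int
    n_nodes: int
    n_edges: int
    kind: str  # "isolated" (1 edge) or "coordinated" (>= 2 edges)
    hubs: list[tuple[str, int]]


def build(acs: Sequence[ActivityCliff], multi_target: bool = False) -> nx.Graph:
    """Build the cliff network: one node per cliff-forming compound, one
    edge per cliff.  Networks are per-target unless ``multi_target``;
    in the union mode edges keep their target label.
    """
    targets = {ac.target_id for ac in acs}
    if len(targets) > 1 and not multi_target:
        raise ValueError(
            f"cliffs from several targets {sorted(targets)}; pass multi_target=True "
            "for a labelled union network"
        )
    g = nx.Graph()
    for ac in sorted(acs, key=lambda a: a.key):
        for cid, pki, role in (
            (ac.id_high, ac.pki_high, "high"),
            (ac.id_low, ac.pki_low, "low"),
        ):
            if cid not in g:
                g.add_node(cid, pki=pki, role=role)
            else:
                if g.nodes[cid]["role"] != role:
                    g.nodes[cid]["role"] = "both"
        g.add_edge(
            ac.id_high,
            ac.id_low,
            delta_pki=ac.delta_pki,
            generation=ac.generation,
            criterion=ac.criterion,
            target_id=ac.target_id,
        )
    return g


def components(net: nx.Graph) -> list[set[str]]:
    """Deterministically ordered connected components."""
    return sorted(nx.connected_components(net), key=lambda c: min(c))


def classify_clusters(net: nx.Graph, hub_min_degree: int = 3) -> list[ClusterReport]:
    """Label every component isolated (exactly one cliff) or coordinated
    (two or more overlapping cliffs)."""
    reports = []
    for i, comp in enumerate(components(net)):
        sub = net.subgraph(comp)
        n_edges = sub.number_of_edges()
        reports.append(
            ClusterReport(
                component_id=i,
                n_nodes=sub.number_of_nodes(),
                n_edges=n_edges,
                kind="isolated" if n_edges == 1 else "coordinated",
                hubs=find_hubs(sub, hub_min_degree),
            )
        )
    return reports


def find_hubs(net: nx.Graph, min_degree: int = 3) -> list[tuple[str, int]]:
    """Nodes of degree >= min_degree, sorted by degree descending then id."""
    if min_degree < 2:
        raise ValueError("a hub needs at least degree 2")
    hubs = [(cid, d) for cid, d in net.degree() if d >= min_degree]
    return sorted(hubs, key=lambda t: (-t[1], t[0]))


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tdelta_pki\tgeneration\tcriterion\ttarget_id\n")
        for a, b, data in sorted(net.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{data['delta_pki']:.6g}\t{data['generation']}"
                f"\t{data['criterion']}\t{data['target_id']}\n"
            )


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, str(path))


def cluster_table(reports: Sequence[ClusterReport]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "component_id": r.component_id,
                "n_nodes": r.n_nodes,
                "n_edges": r.n_edges,
                "kind": r.kind,
                "hubs": ";".join(f"{cid}:{d}" for cid, d in r.hubs),
            }
            for r in reports
        ]
    )
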