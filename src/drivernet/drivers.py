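"""Minimum dominating set key-driver detection.

A node dominates itself and its out-neighbors; undirected edges dominate
both ways.  The exact optimum comes from an integer linear program (HiGHS
via scipy); a brute-force enumerator serves as an oracle on small instances
and for documenting ties.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import lil_matrix

from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)


def _dominators(network: RegulatoryNetwork) -> tuple[list[str], dict[str, set[str]]]:
    """Per node v: the set of nodes whose selection covers v (v itself plus
    every u with an arc u -> v; undirected edges count both ways)."""
    nodes = sorted(network.nodes)
    cover: dict[str, set[str]] = {v: {v} for v in nodes}
    for e in network.edges.values():
        cover[e.target].add(e.source)
        if not e.directed:
            cover[e.source].add(e.target)
    return nodes, cover


def is_dominating(network: RegulatoryNetwork, selected: set[str]) -> bool:
    """Independent checker: every node is selected or has a selected in-neighbor."""
    _, cover = _dominators(network)
    return all(cover[v] & selected for v in network.nodes)


def mds_ilp(network: RegulatoryNetwork) -> set[str]:
    """Exact minimum dominating set via ILP; raises if not proved optimal."""
    if not network.nodes:
        raise ValueError("mds_ilp: empty network")
    nodes, cover = _dominators(network)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    a = lil_matrix((n, n))
    for v in nodes:
        for u in cover[v]:
            a[idx[v], idx[u]] = 1.0
    res = milp(
        c=np.ones(n),
        constraints=LinearConstraint(a.tocsr(), lb=np.ones(n), ub=np.inf),
        integrality=np.ones(n),
        bounds=(0, 1),
    )
    if res.status != 0:
        raise RuntimeError(f"mds_ilp: solver did not prove optimality ({res.message})")
    selected = {nodes[i] for i in range(n) if res.x[i] > 0.5}
    assert is_dominating(network, selected), "ILP returned a non-dominating set"
    assert len(selected) == round(res.fun)
    logger.info("mds_ilp: optimum %d / %d nodes", len(selected), n)
    return selected


def mds_bruteforce(
    network: RegulatoryNetwork, max_nodes: int = 20
) -> tuple[int, list[set[str]]]:
    """Exhaustive search by increasing cardinality; returns the optimal size
    and ALL optimal sets.  Only for instances with <= ``max_nodes`` nodes."""
    nodes, cover = _dominators(network)
    if len(nodes) > max_nodes:
        raise ValueError(f"mds_bruteforce: {len(nodes)} nodes exceeds cap {max_nodes}")
    for size in range(0, len(nodes) + 1):
        hits = [
            set(combo)
            for combo in itertools.combinations(nodes, size)
            if all(cover[v] & set(combo) for v in nodes)
        ]
        if hits:
            return size, hits
    raise AssertionError("unreachable: full node set always dominates")


@dataclass
class DriverRow:
    node: str
    node_type: str
    module: int | None
    out_degree: int
    in_degree: int
    druggable: bool | None = None


def drivers_report(
    network: RegulatoryNetwork,
    drivers: set[str],
    modules: pd.Series | None = None,
    druggable: set[str] | None = None,
) -> pd.DataFrame:
    """Per-driver annotation table (type, module, degrees, druggability)."""
    missing = drivers - network.nodes
    if missing:
        raise ValueError(f"drivers_report: drivers not in network: {sorted(missing)[:5]}")
    g = network.to_networkx()
    rows = []
    for node in sorted(drivers):
        rows.append(
            DriverRow(
                node=node,
                node_type=network.node_types[node],
                module=int(modules[node]) if modules is not None and node in modules.index else None,
                out_degree=g.out_degree(node),
                in_degree=g.in_degree(node),
                druggable=(node in druggable) if druggable is not None else None,
            ).__dict__
        )
    df = pd.DataFrame(rows, columns=["node", "node_type", "module",
                                     "out_degree", "in_degree", "druggable"])
    if modules is not None and not df.empty:
        df = df.sort_values(["module", "node"], na_position="last").reset_index(drop=True)
    return df


def module_drivers(
    networks: dict[int, RegulatoryNetwork],
    modules: pd.Series | None = None,
    druggable: set[str] | None = None,
) -> tuple[dict[int, set[str]], pd.DataFrame]:
    """Solve the MDS per module network and concatenate the reports."""
    per_module: dict[int, set[str]] = {}
    reports = []
    for label in sorted(networks):
        drv = mds_ilp(networks[label])
        per_module[label] = drv
        rep = drivers_report(networks[label], drv, modules, druggable)
        rep["module"] = label
        reports.append(rep)
    report = (
        pd.concat(reports, ignore_index=True)
        if reports
        else pd.DataFrame(columns=["node", "node_type", "module",
                                   "out_degree", "in_degree", "druggable"])
    )
    return per_module, report
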