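"""Signed causal networks and context-specific mechanistic models.

A :class:`PriorNetwork` is a signed directed graph of literature-style causal
interactions (kinase -> substrate, TF -> target, ...) that may also contain
phenotype nodes (e.g. ``DNA_damage``).  Given inferred protein activities,
:func:`build_naive_network` keeps the sign-consistent induced subgraph, and
:func:`connect_to_phenotype` extracts every sign-consistent simple path from a
modulated protein to the phenotype, yielding a :class:`MechanisticModel` — a
context-specific explanation of how the modulated proteins drive (or oppose)
the phenotype.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SIGNS = (-1, 1)


class PriorNetwork:
    """Signed directed causal graph with optional phenotype nodes.

    Edges carry a sign in {+1, -1} and a free-text mechanism.  Parallel edges
    with identical (source, target, sign) are deduplicated; a duplicated pair
    with *conflicting* signs is kept as two edges, preserving literature
    ambiguity.  Phenotype nodes are sinks: they may not have outgoing edges.
    """

    def __init__(self) -> None:
        self.graph = nx.MultiDiGraph()
        self.phenotypes: set[str] = set()

    # -- construction ------------------------------------------------------
    def add_node(self, name: str, node_class: str = "other", phenotype: bool = False) -> None:
        self.graph.add_node(str(name), node_class=node_class, phenotype=bool(phenotype))
        if phenotype:
            self.phenotypes.add(str(name))

    def add_edge(self, source: str, target: str, sign: int, mechanism: str = "") -> None:
        sign = int(sign)
        if sign not in VALID_SIGNS:
            raise ValueError(f"edge sign must be +1 or -1, got {sign!r}")
        if source in self.phenotypes:
            raise ValueError(f"phenotype node {source!r} cannot have outgoing edges")
        for node in (source, target):
            if node not in self.graph:
                self.add_node(node)
        # key=sign makes identical (u, v, sign) rows idempotent while keeping
        # sign conflicts as two distinct parallel edges
        if not self.graph.has_edge(source, target, key=sign):
            self.graph.add_edge(source, target, key=sign, sign=sign, mechanism=mechanism)

    # -- queries -----------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_class(self, node: str) -> str:
        return self.graph.nodes[node].get("node_class", "other")

    def is_phenotype(self, node: str) -> bool:
        return node in self.phenotypes

    def edge_list(self) -> list[tuple[str, str, int, str]]:
        """All edges as sorted (source, target, sign, mechanism) tuples."""
        edges = [
            (u, v, int(d["sign"]), d.get("mechanism", ""))
            for u, v, d in self.graph.edges(data=True)
        ]
        return sorted(edges)

    def out_edges_signed(self, node: str) -> list[tuple[str, int]]:
        """Outgoing (target, sign) pairs, sorted for deterministic traversal."""
        if node not in self.graph:
            return []
        return sorted(
            (v, int(d["sign"])) for _, v, d in self.graph.out_edges(node, data=True)
        )

    def copy(self) -> "PriorNetwork":
        out = PriorNetwork()
        out.graph = self.graph.copy()
        out.phenotypes = set(self.phenotypes)
        return out


@dataclass(frozen=True, order=True)
class SignedPath:
    """A simple directed path with one committed sign per traversed edge."""

    nodes: tuple[str, ...]
    edge_signs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.edge_signs) + 1:
            raise ValueError("a path over k edges must have k+1 nodes")

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    @property
    def sign(self) -> int:
        return int(math.prod(self.edge_signs)) if self.edge_signs else 1

    def __len__(self) -> int:
        return len(self.edge_signs)


@dataclass
class MechanisticModel:
    """Sign-consistent subnetwork connecting modulated proteins to a phenotype.

    Node attributes on ``graph``: ``sign`` (inferred activity sign; 0 for
    unscored intermediates), ``score`` (activity score, NaN for unscored) and
    ``node_class``.  Edge attribute: ``sign``.
    """

    graph: nx.MultiDiGraph
    phenotype: str
    direction: int
    paths: tuple[SignedPath, ...] = ()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_sign(self, node: str) -> int:
        return int(self.graph.nodes[node].get("sign", 0))

    def node_set(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_set(self) -> set[tuple[str, str, int]]:
        return {(u, v, int(d["sign"])) for u, v, d in self.graph.edges(data=True)}

    def sources(self) -> set[str]:
        return {p.source for p in self.paths}

    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "node": n,
                "sign": int(d.get("sign", 0)),
                "score": d.get("score", float("nan")),
                "node_class": d.get("node_class", "other"),
                "is_phenotype": n == self.phenotype,
            }
            for n, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["node", "sign", "score", "node_class", "is_phenotype"])

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "sign": s}
            for u, v, s in sorted(self.edge_set())
        ]
        return pd.DataFrame(rows, columns=["source", "target", "sign"])

    def paths_json(self) -> str:
        payload = [
            {"nodes": list(p.nodes), "edge_signs": list(p.edge_signs)}
            for p in sorted(self.paths)
        ]
        return json.dumps(payload, indent=2, sort_keys=True)


def _empty_model(phenotype: str, direction: int) -> MechanisticModel:
    return MechanisticModel(graph=nx.MultiDiGraph(), phenotype=phenotype,
                            direction=direction, paths=())


def build_naive_network(activities: pd.DataFrame, prior: PriorNetwork) -> PriorNetwork:
    """Induced sign-consistent subgraph of the prior on activity-scored proteins.

    Keeps proteins with a nonzero inferred ``sign`` that occur in the prior,
    and keeps an edge (u, v, sign) only when ``sign(u) * sign = sign(v)``,
    i.e. the literature interaction can explain the observed activity change
    of the target.  Self-loops are removed.
    """
    if activities.empty:
        logger.warning("empty activity table: naive network is empty")
        return PriorNetwork()
    signs = {
        str(p): int(row["sign"])
        for p, row in activities.iterrows()
        if int(row["sign"]) != 0
    }
    scores = {str(p): float(row["score"]) for p, row in activities.iterrows()}
    keep = sorted(set(signs) & set(prior.graph.nodes))
    if not keep:
        logger.warning("no scored protein occurs in the prior network")
        return PriorNetwork()
    sub = PriorNetwork()
    for n in keep:
        sub.add_node(n, node_class=prior.node_class(n))
        sub.graph.nodes[n]["sign"] = signs[n]
        sub.graph.nodes[n]["score"] = scores.get(n, float("nan"))
    for u, v, sign, mech in prior.edge_list():
        if u == v:
            continue
        if u in signs and v in signs and signs[u] * sign == signs[v]:
            sub.add_edge(u, v, sign, mech)
            # add_edge resets node attrs? no: nodes already exist
    return sub


def connect_to_phenotype(
    subgraph: PriorNetwork,
    prior: PriorNetwork,
    phenotype: str,
    direction: int,
    max_len: int = 4,
) -> MechanisticModel:
    """Connect activity-modulated proteins to the phenotype node.

    Enumerates every simple directed path of at most ``max_len`` edges from
    each scored node to ``phenotype`` through the full prior.  A path is kept
    iff

    * source activity sign times the product of edge signs equals
      ``direction`` (the causal chain explains the phenotype change), and
    * at every scored node met along the way the propagated sign matches
      that node's inferred activity sign.

    Intermediate nodes without an inferred activity are allowed: the prior
    may route signal through proteins the data did not score.  The model is
    the union of all kept paths plus the sign-consistent subgraph edges among
    retained nodes.
    """
    if phenotype not in prior:
        raise ValueError(f"phenotype node {phenotype!r} absent from the prior network")
    if direction not in VALID_SIGNS:
        raise ValueError(f"direction must be +1 or -1, got {direction!r}")
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")

    signs = {
        n: int(subgraph.graph.nodes[n]["sign"])
        for n in subgraph.graph.nodes
        if int(subgraph.graph.nodes[n].get("sign", 0)) != 0
    }
    if not signs:
        logger.warning("no scored nodes: mechanistic model is empty")
        return _empty_model(phenotype, direction)

    kept: set[SignedPath] = set()

    def _dfs(src_sign: int, path: list[str], edge_signs: list[int], prod: int) -> None:
        here = path[-1]
        for nxt, esign in prior.out_edges_signed(here):
            if nxt == here or nxt in path:
                continue
            new_prod = prod * esign
            if nxt == phenotype:
                if src_sign * new_prod == direction:
                    kept.add(SignedPath(tuple(path + [nxt]), tuple(edge_signs + [esign])))
                continue
            if nxt in signs and src_sign * new_prod != signs[nxt]:
                continue
            if len(edge_signs) + 1 < max_len:
                _dfs(src_sign, path + [nxt], edge_signs + [esign], new_prod)

    for src in sorted(signs):
        _dfs(signs[src], [src], [], 1)

    if not kept:
        logger.warning("no sign-consistent path reaches %r", phenotype)
        return _empty_model(phenotype, direction)

    retained = sorted({n for p in kept for n in p.nodes})
    edges: set[tuple[str, str, int]] = set()
    for p in kept:
        for (u, v), s in zip(zip(p.nodes[:-1], p.nodes[1:]), p.edge_signs):
            edges.add((u, v, s))
    retained_set = set(retained)
    for u, v, s, _ in subgraph.edge_list():
        if u in retained_set and v in retained_set:
            edges.add((u, v, s))

    graph = nx.MultiDiGraph()
    for n in retained:
        graph.add_node(
            n,
            sign=signs.get(n, 0),
            score=float(subgraph.graph.nodes[n].get("score", float("nan")))
            if n in subgraph.graph
            else float("nan"),
            node_class=prior.node_class(n) if n in prior else "other",
        )
    for u, v, s in sorted(edges):
        graph.add_edge(u, v, key=s, sign=s)
    return MechanisticModel(graph=graph, phenotype=phenotype, direction=direction,
                            paths=tuple(sorted(kept)))


def extract_circuit(
    model: MechanisticModel, gene_set: Iterable[str], phenotype: str | None = None
) -> MechanisticModel:
    """Functional circuit: the sub-model whose path sources lie in ``gene_set``.

    Used to focus a model on one biological process (e.g. the members of a GO
    term such as regulation of cyclin-dependent kinase activity).  Retains
    every model edge between circuit nodes, so extracting with the full
    source set returns the model itself.
    """
    members = {str(g) for g in gene_set}
    kept = tuple(sorted(p for p in model.paths if p.source in members))
    if not kept:
        return _empty_model(phenotype or model.phenotype, model.direction)
    retained = sorted({n for p in kept for n in p.nodes})
    graph = model.graph.subgraph(retained).copy()
    return MechanisticModel(graph=graph, phenotype=phenotype or model.phenotype,
                            direction=model.direction, paths=kept)


def model_diff(a: MechanisticModel, b: MechanisticModel) -> dict:
    """Node and edge set differences between two models (sorted, deterministic)."""
    na, nb = a.node_set(), b.node_set()
    ea, eb = a.edge_set(), b.edge_set()
    return {
        "nodes_only_a": sorted(na - nb),
        "nodes_only_b": sorted(nb - na),
        "nodes_shared": sorted(na & nb),
        "edges_only_a": sorted(ea - eb),
        "edges_only_b": sorted(eb - ea),
        "edges_shared": sorted(ea & eb),
    }


def validate_model(model: MechanisticModel, max_len: int | None = None) -> list[str]:
    """Check every structural invariant of a mechanistic model.

    Returns a list of human-readable violations (empty list = valid):

    * the phenotype has no outgoing edges;
    * every edge between two scored nodes is sign-consistent;
    * every node lies on at least one kept path;
    * every kept path starts at a scored node, ends at the phenotype, respects
      scored-node signs along the way, and its aggregate sign matches the
      requested phenotype direction.
    """
    problems: list[str] = []
    g = model.graph
    if g.number_of_nodes() == 0:
        return problems
    if model.phenotype in g and g.out_degree(model.phenotype) > 0:
        problems.append(f"phenotype {model.phenotype!r} has outgoing edges")
    signs = {n: int(d.get("sign", 0)) for n, d in g.nodes(data=True)}
    for u, v, d in g.edges(data=True):
        s = int(d["sign"])
        if signs.get(u, 0) != 0 and signs.get(v, 0) != 0 and signs[u] * s != signs[v]:
            problems.append(f"inconsistent edge {u}->{v} (sign {s:+d})")
    on_path = {n for p in model.paths for n in p.nodes}
    for n in g.nodes:
        if n not in on_path:
            problems.append(f"node {n!r} lies on no phenotype path")
    edge_set = model.edge_set()
    for p in model.paths:
        if max_len is not None and len(p) > max_len:
            problems.append(f"path {p.nodes} exceeds max_len={max_len}")
        if len(set(p.nodes)) != len(p.nodes):
            problems.append(f"path {p.nodes} is not simple")
        if p.target != model.phenotype:
            problems.append(f"path {p.nodes} does not end at the phenotype")
        src_sign = signs.get(p.source, 0)
        if src_sign == 0:
            problems.append(f"path source {p.source!r} has no activity sign")
            continue
        prod = 1
        for (u, v), s in zip(zip(p.nodes[:-1], p.nodes[1:]), p.edge_signs):
            if (u, v, s) not in edge_set:
                problems.append(f"path edge {u}->{v} ({s:+d}) missing from model")
            prod *= s
            if v != model.phenotype and signs.get(v, 0) != 0 and src_sign * prod != signs[v]:
                problems.append(f"path {p.nodes}: sign mismatch at {v!r}")
        if src_sign * prod != model.direction:
            problems.append(f"path {p.nodes}: aggregate sign != direction")
    return problems
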