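"""Directed acyclic graph over detected QTL from ordinal genotype codes.

Significant markers often share an identical genotype vector across the
family (perfect linkage at the sample size); those collapse to one
representative node before structure learning.  The DAG itself is learned
by greedy hill-climbing over edge additions, deletions and reversals,
scoring each structure with a BIC-penalised multinomial log-likelihood of
the ordinal genotype codes (each node's local distribution is a
conditional multinomial given its parents' joint configuration).
Acyclicity is enforced at every accepted move and the best of several
random restarts is kept.  Edge orientation within a Markov-equivalence
class is not identifiable from observational data; orientations are
reported as learned, up to equivalence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .gio import MarkerSet

__all__ = ["QtlDag", "dedupe_segregation", "learn_dag", "annotate_modules"]


@dataclass
class QtlDag:
    """Learned QTL network: nodes, directed edges, modules and hubs."""

    graph: nx.DiGraph
    score: float
    score_trace: list = field(default_factory=list)
    representative_of: dict = field(default_factory=dict)
    node_kinds: dict = field(default_factory=dict)
    hubs: list = field(default_factory=list)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list:
        return list(self.graph.edges)

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)

    def skeleton(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    def to_dot(self) -> str:
        lines = ["digraph qtl {"]
        for n in self.nodes:
            kinds = ",".join(sorted(self.node_kinds.get(n, ())))
            shape = ' [style=bold]' if n in self.hubs else ""
            lines.append(f'  "{n}" [label="{n}\\n{kinds}"]{shape};')
        for u, v in self.graph.edges:
            lines.append(f'  "{u}" -> "{v}";')
        lines.append("}")
        return "\n".join(lines)

    def summary(self) -> str:
        lines = [
            f"QTL DAG: {len(self.nodes)} nodes, {len(self.edges)} edges, "
            f"score {self.score:.3f}",
            f"  hubs: {self.hubs}",
        ]
        return "\n".join(lines)


def dedupe_segregation(ms: MarkerSet, significant: list) -> tuple:
    """Collapse markers with identical genotype vectors to one node each.

    Returns ``(unique_markers, representative_of)`` where the mapping sends
    every significant marker to its representative (first in genomic
    order).
    """
    order = {mk: i for i, mk in enumerate(ms.markers)}
    missing = [mk for mk in significant if mk not in order]
    if missing:
        raise KeyError(f"markers absent from the marker set: {missing[:5]}")
    sig = sorted(set(significant), key=lambda mk: order[mk])
    seen = {}
    representative_of = {}
    for mk in sig:
        key = ms.genotypes[:, order[mk]].tobytes()
        if key not in seen:
            seen[key] = mk
        representative_of[mk] = seen[key]
    unique = sorted(set(representative_of.values()), key=lambda mk: order[mk])
    return unique, representative_of


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class _BicScorer:
    """BIC-penalised multinomial local scores with caching."""

    def __init__(self, data: np.ndarray, cards: np.ndarray):
        self.data = data  # (n, p) ordinal codes 0..card-1
        self.cards = cards
        self.n = data.shape[0]
        self._cache = {}

    def local(self, v: int, parents: frozenset) -> float:
        key = (v, parents)
        if key in self._cache:
            return self._cache[key]
        child = self.data[:, v]
        r = int(self.cards[v])
        if parents:
            ps = sorted(parents)
            # joint parent configuration index
            cfg = np.zeros(self.n, dtype=np.int64)
            q = 1
            for p in ps:
                cfg += self.data[:, p] * q
                q *= int(self.cards[p])
        else:
            cfg = np.zeros(self.n, dtype=np.int64)
            q = 1
        flat = cfg * r + child
        counts = np.bincount(flat, minlength=q * r).reshape(q, r)
        row_tot = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(
                counts > 0,
                counts * np.log(counts / np.where(row_tot > 0, row_tot, 1)),
                0.0,
            ).sum()
        penalty = 0.5 * math.log(self.n) * (r - 1) * q
        score = float(ll - penalty)
        self._cache[key] = score
        return score

    def total(self, graph: nx.DiGraph, idx: dict) -> float:
        return sum(
            self.local(idx[v], frozenset(idx[p] for p in graph.predecessors(v)))
            for v in graph.nodes
        )


def _candidate_moves(graph: nx.DiGraph, nodes: list, max_parents: int):
    for u, v in itertools.permutations(nodes, 2):
        if graph.has_edge(u, v):
            yield ("delete", u, v)
            if graph.in_degree(u) < max_parents:
                yield ("reverse", u, v)
        elif graph.in_degree(v) < max_parents:
            yield ("add", u, v)


def _apply(graph: nx.DiGraph, move):
    op, u, v = move
    if op == "add":
        graph.add_edge(u, v)
    elif op == "delete":
        graph.remove_edge(u, v)
    else:
        graph.remove_edge(u, v)
        graph.add_edge(v, u)


def _undo(graph: nx.DiGraph, move):
    op, u, v = move
    if op == "add":
        graph.remove_edge(u, v)
    elif op == "delete":
        graph.add_edge(u, v)
    else:
        graph.remove_edge(v, u)
        graph.add_edge(u, v)


def _creates_cycle(graph: nx.DiGraph, move) -> bool:
    op, u, v = move
    if op == "delete":
        return False
    if op == "add":
        return nx.has_path(graph, v, u)
    graph.remove_edge(u, v)
    cyc = nx.has_path(graph, u, v)
    graph.add_edge(u, v)
    return cyc


def learn_dag(
    columns: pd.DataFrame,
    score: str = "bic",
    max_parents: int = 3,
    n_restarts: int = 3,
    seed: int = 0,
) -> QtlDag:
    """Greedy hill-climbing DAG search over ordinal genotype columns.

    ``columns`` holds one ordinal-coded column per (uniquely segregating)
    QTL; missing codes are not supported (drop or impute upstream).
    Scores are BIC-penalised multinomial log-likelihoods; each restart
    begins from a random sparse DAG and the best-scoring endpoint is kept.
    Deterministic given ``seed``.
    """
    if max_parents < 1:
        raise ValueError("max_parents must be at least 1")
    if score != "bic":
        raise ValueError(f"unsupported score {score!r}")
    df = pd.DataFrame(columns)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 nodes to learn a DAG")
    if df.isna().any().any() or (df.to_numpy() < 0).any():
        raise ValueError("missing codes are not supported by the DAG learner")
    names = list(df.columns)
    data = df.to_numpy(dtype=np.int64)
    cards = data.max(axis=0) + 1
    cards = np.maximum(cards, 2)
    scorer = _BicScorer(data, cards)
    idx = {v: j for j, v in enumerate(names)}
    rng = np.random.default_rng(seed)

    best_graph, best_score, best_trace = None, -np.inf, []
    for restart in range(max(1, n_restarts)):
        graph = nx.DiGraph()
        graph.add_nodes_from(names)
        if restart > 0:
            order = rng.permutation(len(names))
            for _ in range(len(names) // 2):
                a, b = rng.choice(len(names), size=2, replace=False)
                u, v = (names[order[min(a, b)]], names[order[max(a, b)]])
                if graph.in_degree(v) < max_parents:
                    graph.add_edge(u, v)
        current = scorer.total(graph, idx)
        trace = [current]
        improved = True
        while improved:
            improved = False
            best_move, best_gain = None, 1e-9
            for move in _candidate_moves(graph, names, max_parents):
                if _creates_cycle(graph, move):
                    continue
                op, u, v = move
                gain = 0.0
                pv = frozenset(idx[p] for p in graph.predecessors(v))
                if op == "add":
                    gain = (scorer.local(idx[v], pv | {idx[u]})
                            - scorer.local(idx[v], pv))
                elif op == "delete":
                    gain = (scorer.local(idx[v], pv - {idx[u]})
                            - scorer.local(idx[v], pv))
                else:  # reverse u->v becomes v->u
                    pu = frozenset(idx[p] for p in graph.predecessors(u))
                    gain = (scorer.local(idx[v], pv - {idx[u]})
                            - scorer.local(idx[v], pv)
                            + scorer.local(idx[u], pu | {idx[v]})
                            - scorer.local(idx[u], pu))
                if gain > best_gain:
                    best_move, best_gain = move, gain
            if best_move is not None:
                _apply(graph, best_move)
                current += best_gain
                trace.append(current)
                improved = True
        if current > best_score:
            best_graph, best_score, best_trace = graph, current, trace

    dag = QtlDag(graph=best_graph, score=best_score, score_trace=best_trace)
    assert dag.is_acyclic()
    return dag


def annotate_modules(dag: QtlDag, membership: dict,
                     n_hubs: int = None) -> QtlDag:
    """Attach descriptor-type labels, modules and hub QTL to a learned DAG.

    ``membership`` maps each node to the set of descriptor kinds it was
    detected for (multi-membership = pleiotropy).  Hubs are the top-degree
    nodes; the default count scales as ceil(0.25 * nodes).  The module
    summary (``dag.graph.graph['module_summary']``) counts edges within
    and between descriptor-type groups.
    """
    dag.node_kinds = {n: frozenset(membership.get(n, ())) for n in dag.nodes}
    if dag.nodes:
        if n_hubs is None:
            n_hubs = math.ceil(0.25 * len(dag.nodes))
        deg = sorted(
            ((dag.graph.in_degree(n) + dag.graph.out_degree(n), str(n), n)
             for n in dag.nodes), reverse=True,
        )
        dag.hubs = [n for d, _, n in deg[:n_hubs] if d > 0]
    cross = {}
    for u, v in dag.edges:
        ku = ",".join(sorted(dag.node_kinds[u])) or "none"
        kv = ",".join(sorted(dag.node_kinds[v])) or "none"
        cross[(ku, kv)] = cross.get((ku, kv), 0) + 1
    dag.graph.graph["module_summary"] = cross
    return dag
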