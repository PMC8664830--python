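"""Derived summaries: co-membership graphs, pathway graphs, and per-condition
tables."""

from __future__ import annotations

import itertools
from pathlib import Path

import networkx as nx
import pandas as pd

from .classify import ReactionClassification, CATEGORIES
from .model import MetabolicModel
from .tradeoffs import TradeOffSet


def build_tradeoff_graph(tradeoffs: TradeOffSet) -> nx.Graph:
    """Reaction co-membership graph: nodes are reactions appearing in any
    trade-off variable support; an edge connects two reactions co-occurring
    in at least one support, weighted by the co-occurrence count.  A
    trade-off of size s contributes C(s, 2) edge increments."""
    graph = nx.Graph()
    for t in tradeoffs:
        members = sorted(t.variable_support)
        graph.add_nodes_from(members)
        for a, b in itertools.combinations(members, 2):
            if graph.has_edge(a, b):
                graph[a][b]["weight"] += 1
            else:
                graph.add_edge(a, b, weight=1)
    ordered = nx.Graph()  # deterministic lexicographic node/edge order
    ordered.add_nodes_from(sorted(graph.nodes))
    ordered.add_edges_from(sorted((min(a, b), max(a, b),
                                   {"weight": d["weight"]})
                                  for a, b, d in graph.edges(data=True)))
    return ordered


def build_pathway_graph(tradeoffs: TradeOffSet, model: MetabolicModel,
                        include_fixed: bool = False) -> nx.Graph:
    """Subsystem-level graph: nodes are pathway labels; the weight of an edge
    is the number of trade-offs containing at least one reaction from each of
    the two pathways (counted once per trade-off and pair).  Reactions may
    carry several labels; each label counts once per trade-off."""
    if not any(model.subsystems[j] for j in range(model.n_reactions)):
        raise ValueError(
            "model carries no subsystem annotations; pathway graphs require "
            "a labeled model")
    graph = nx.Graph()
    for t in tradeoffs:
        members = set(t.variable_support)
        if include_fixed:
            members |= set(t.fixed_support)
        labels = sorted({lab for rid in members
                         for lab in model.subsystems[model.reaction_index(rid)]})
        graph.add_nodes_from(labels)
        for a, b in itertools.combinations(labels, 2):
            if graph.has_edge(a, b):
                graph[a][b]["weight"] += 1
            else:
                graph.add_edge(a, b, weight=1)
    return graph


def summarize_conditions(results: list[tuple[str, ReactionClassification,
                                             TradeOffSet]]) -> pd.DataFrame:
    """Per-condition table: reaction-category counts, total trade-offs, and
    the trade-off size histogram (serialized as ``size:count`` pairs)."""
    rows = []
    for label, classification, tradeoffs in results:
        counts = classification.counts()
        hist = tradeoffs.size_histogram()
        rows.append({
            "condition": label,
            **{c: counts[c] for c in CATEGORIES},
            "n_tradeoffs": len(tradeoffs),
            "size_histogram": ";".join(f"{s}:{n}" for s, n in hist.items()),
        })
    columns = ["condition", *CATEGORIES, "n_tradeoffs", "size_histogram"]
    return pd.DataFrame(rows, columns=columns)


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def write_edge_tsv(graph: nx.Graph, path: str | Path) -> None:
    """Plain TSV edge list (source, target, weight), lexicographic order."""
    lines = ["source\ttarget\tweight"]
    for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
        lines.append(f"{a}\t{b}\t{graph[a][b]['weight']}")
    Path(path).write_text("\n".join(lines) + "\n")
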