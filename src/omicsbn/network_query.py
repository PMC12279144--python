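"""Interrogate learned or averaged networks.

Markov blankets, induced sub-networks, degree summaries, class-by-class edge
percentages and a structural Hamming distance for recovery scoring.  All
operations accept either a :class:`~omicsbn.model_core.Dag`, a DataFrame with
``from``/``to`` columns (the thresholded average-network format), or a plain
iterable of (parent, child) pairs.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .model_core import Dag, VariableMeta

TABLE_CLASSES = ("clinical", "metabolite", "protein", "expression")


def _edge_pairs(edges) -> list[tuple[str, str]]:
    if isinstance(edges, Dag):
        return sorted(edges.edges)
    if isinstance(edges, pd.DataFrame):
        return [(str(f), str(t)) for f, t in zip(edges["from"], edges["to"])]
    return [(p, c) for p, c in edges]


def _node_set(edges, pairs: list[tuple[str, str]]) -> set[str]:
    if isinstance(edges, Dag):
        return set(edges.nodes)
    return {n for e in pairs for n in e}


def markov_blanket(edges, node: str, nodes: Iterable[str] | None = None) -> set[str]:
    """Parents, children and co-parents of children of ``node``.

    The blanket is all information needed to predict the node and its
    children; the node itself is excluded.  ``nodes`` optionally widens the
    known-node universe (an isolated node then has an empty blanket rather
    than being an error).
    """
    pairs = _edge_pairs(edges)
    known = _node_set(edges, pairs)
    if nodes is not None:
        known |= set(nodes)
    if node not in known:
        raise KeyError(f"unknown node {node!r}")
    parents = {p for p, c in pairs if c == node}
    children = {c for p, c in pairs if p == node}
    spouses = {p for p, c in pairs if c in children}
    return (parents | children | spouses) - {node}


def subnetwork(edges, node_set: Iterable[str]):
    """Induced subgraph: edges with both endpoints in ``node_set``.

    Paths through excluded nodes are not contracted.  For DataFrame input the
    strength/direction columns are carried through.
    """
    keep = set(node_set)
    if isinstance(edges, pd.DataFrame):
        mask = edges["from"].isin(keep) & edges["to"].isin(keep)
        return edges.loc[mask].reset_index(drop=True)
    return [(p, c) for p, c in _edge_pairs(edges) if p in keep and c in keep]


def degree_summary(edges) -> dict[str, float]:
    """Mean out-edges per parent and mean in-edges per child.

    A "parent" is any node with at least one outgoing edge, a "child" any
    node with at least one incoming edge, so
    #edges = mean_out x #parents = mean_in x #children exactly.
    """
    pairs = _edge_pairs(edges)
    if not pairs:
        raise ValueError("degree summary of an empty edge list is undefined")
    n_edges = len(pairs)
    parents = {p for p, _ in pairs}
    children = {c for _, c in pairs}
    return {
        "mean_out_per_parent": n_edges / len(parents),
        "mean_in_per_child": n_edges / len(children),
    }


def class_edge_matrix(
    edges,
    meta: Sequence[VariableMeta],
    classes: tuple[str, ...] = TABLE_CLASSES,
) -> pd.DataFrame:
    """Row-percentages of directed edges by (from-class, to-class).

    By default allele-score nodes are excluded and only edges among the four
    substantive classes are tabulated (allele-score edges are fixed by
    construction and reported separately); rows with no outgoing edges are
    NaN.  Rows with edges sum to 100.
    """
    vclass = {v.name: v.vclass for v in meta}
    pairs = _edge_pairs(edges)
    counts = pd.DataFrame(0.0, index=list(classes), columns=list(classes))
    for p, c in pairs:
        if p not in vclass or c not in vclass:
            raise KeyError(f"edge endpoint without metadata: ({p!r}, {c!r})")
        cp, cc = vclass[p], vclass[c]
        if cp in classes and cc in classes:
            counts.loc[cp, cc] += 1
    totals = counts.sum(axis=1)
    pct = counts.div(totals.where(totals > 0), axis=0) * 100.0
    pct.index.name = "from_class"
    pct.columns.name = "to_class"
    return pct


def allele_score_edges(edges, meta: Sequence[VariableMeta]) -> list[tuple[str, str]]:
    """Edges with an allele-score endpoint (kept out of the class matrix)."""
    vclass = {v.name: v.vclass for v in meta}
    return [
        (p, c)
        for p, c in _edge_pairs(edges)
        if vclass.get(p) == "allele_score" or vclass.get(c) == "allele_score"
    ]


def shd(true_dag: Dag, learned: Dag) -> int:
    """Structural Hamming distance: insertions + deletions + reversals."""
    if set(true_dag.nodes) != set(learned.nodes):
        raise ValueError("SHD requires identical node sets")
    true_pairs = {frozenset(e) for e in true_dag.edges}
    learned_pairs = {frozenset(e) for e in learned.edges}
    dist = len(true_pairs ^ learned_pairs)  # missing or extra adjacencies
    for pair in true_pairs & learned_pairs:
        a, b = sorted(pair)
        if ((a, b) in true_dag.edges) != ((a, b) in learned.edges):
            dist += 1  # present both ways but reversed
    return dist
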