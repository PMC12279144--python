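"""Constrained greedy hill-climbing over DAGs for the lowest-BIC network.

The search starts from the empty graph plus any required edges and repeatedly
applies the best score-improving move among single-edge additions, deletions
and reversals that keep the graph acyclic and respect the constraint set and
the CLG typing rule (no continuous parent of a discrete node).  Steepest
descent with lexicographic tie-breaking makes the result deterministic for a
given seed; optional random restarts perturb the current optimum with a few
random legal moves and re-climb, keeping the best local optimum found.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .model_core import (
    CONTINUOUS,
    DISCRETE,
    ConstraintSet,
    Dag,
    DataMatrix,
    VariableMeta,
    check_constraints,
    is_acyclic,
)
from .scoring import ScoringEngine

_MOVE_KINDS = ("add", "delete", "reverse")
# Stop when no move improves the score by more than this (guards float noise).
_IMPROVE_TOL = 1e-9


@dataclass
class SearchParams:
    max_iterations: int = 10_000
    random_restarts: int = 0
    seed: int = 0
    move_set: tuple[str, ...] = _MOVE_KINDS

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        bad = set(self.move_set) - set(_MOVE_KINDS)
        if bad:
            raise ValueError(f"unknown move kinds: {sorted(bad)}")


class Move(NamedTuple):
    kind: str
    parent: str
    child: str

    @property
    def sort_key(self) -> tuple:
        return (self.child, self.parent, self.kind)


class _State:
    """Mutable parent-set representation used during the climb."""

    def __init__(self, nodes: Sequence[str], edges=()):
        self.nodes = list(nodes)
        self.parents: dict[str, set[str]] = {n: set() for n in nodes}
        self.children: dict[str, set[str]] = {n: set() for n in nodes}
        for p, c in edges:
            self.parents[c].add(p)
            self.children[p].add(c)

    def has_edge(self, p: str, c: str) -> bool:
        return p in self.parents[c]

    def add(self, p: str, c: str) -> None:
        self.parents[c].add(p)
        self.children[p].add(c)

    def remove(self, p: str, c: str) -> None:
        self.parents[c].discard(p)
        self.children[p].discard(c)

    def reaches(self, src: str, dst: str, skip_edge=None) -> bool:
        """Is there a directed path src -> ... -> dst (optionally ignoring one edge)?"""
        stack = [src]
        seen = {src}
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            for w in self.children[u]:
                if skip_edge is not None and (u, w) == skip_edge:
                    continue
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def to_dag(self) -> Dag:
        edges = [(p, c) for c, ps in self.parents.items() for p in ps]
        return Dag(self.nodes, edges)


def _edge_allowed(
    p: str, c: str, constraints: ConstraintSet, kinds: dict[str, str]
) -> bool:
    if (p, c) in constraints.forbidden_edges:
        return False
    if c in constraints.parent_only or c in constraints.no_parents:
        return False
    if kinds[c] == DISCRETE and kinds[p] == CONTINUOUS:
        return False
    return True


def _iter_moves(state: _State, constraints: ConstraintSet, kinds, move_set):
    nodes = state.nodes
    required = constraints.required_edges
    if "add" in move_set:
        for p in nodes:
            for c in nodes:
                if p == c or state.has_edge(p, c) or state.has_edge(c, p):
                    continue
                if not _edge_allowed(p, c, constraints, kinds):
                    continue
                if state.reaches(c, p):
                    continue  # would close a cycle
                yield Move("add", p, c)
    if "delete" in move_set:
        for c in nodes:
            for p in state.parents[c]:
                if (p, c) in required:
                    continue
                yield Move("delete", p, c)
    if "reverse" in move_set:
        for c in nodes:
            for p in state.parents[c]:
                if (p, c) in required:
                    continue
                if not _edge_allowed(c, p, constraints, kinds):
                    continue
                # after dropping p->c, a remaining path p ~> c would close a
                # cycle with the new edge c->p
                if state.reaches(p, c, skip_edge=(p, c)):
                    continue
                yield Move("reverse", p, c)


def legal_moves(
    dag: Dag,
    constraints: ConstraintSet,
    meta: Sequence[VariableMeta],
    move_set: tuple[str, ...] = _MOVE_KINDS,
) -> list[Move]:
    """All single-edge moves preserving acyclicity, roles and CLG typing."""
    kinds = {v.name: v.dtype for v in meta}
    state = _State(dag.nodes, dag.edges)
    moves = list(_iter_moves(state, constraints, kinds, move_set))
    return sorted(moves, key=lambda m: m.sort_key)


def _move_delta(move: Move, state: _State, engine: ScoringEngine, current: dict) -> float:
    p, c = move.parent, move.child
    if move.kind == "add":
        return engine.family_bic(c, state.parents[c] | {p}) - current[c]
    if move.kind == "delete":
        return engine.family_bic(c, state.parents[c] - {p}) - current[c]
    delta = engine.family_bic(c, state.parents[c] - {p}) - current[c]
    delta += engine.family_bic(p, state.parents[p] | {c}) - current[p]
    return delta


def _climb(state: _State, engine, constraints, kinds, move_set, max_iterations):
    current = {n: engine.family_bic(n, state.parents[n]) for n in state.nodes}
    for _ in range(max_iterations):
        best_move = None
        best_delta = -_IMPROVE_TOL  # only accept strict improvements
        for move in _iter_moves(state, constraints, kinds, move_set):
            delta = _move_delta(move, state, engine, current)
            if delta < best_delta - _IMPROVE_TOL:
                best_move, best_delta = move, delta
            elif (
                best_move is not None
                and delta <= best_delta + _IMPROVE_TOL
                and move.sort_key < best_move.sort_key
            ):
                best_move, best_delta = move, min(best_delta, delta)
        if best_move is None:
            break
        p, c = best_move.parent, best_move.child
        if best_move.kind == "add":
            state.add(p, c)
        elif best_move.kind == "delete":
            state.remove(p, c)
        else:
            state.remove(p, c)
            state.add(c, p)
            current[p] = engine.family_bic(p, state.parents[p])
        current[c] = engine.family_bic(c, state.parents[c])
    return state, sum(current.values())


def _perturbed_copy(
    state: _State,
    constraints: ConstraintSet,
    kinds,
    move_set,
    rng: np.random.Generator,
    n_perturb: int = 5,
) -> _State:
    """Copy of ``state`` with a few random legal moves applied (restart seed)."""
    edges = [(p, c) for c, ps in state.parents.items() for p in ps]
    new = _State(state.nodes, edges)
    for _ in range(n_perturb):
        moves = list(_iter_moves(new, constraints, kinds, move_set))
        if not moves:
            break
        move = moves[int(rng.integers(0, len(moves)))]
        p, c = move.parent, move.child
        if move.kind == "add":
            new.add(p, c)
        elif move.kind == "delete":
            new.remove(p, c)
        else:
            new.remove(p, c)
            new.add(c, p)
    return new


def best_fit_network(
    data: DataMatrix,
    constraints: ConstraintSet | None = None,
    params: SearchParams | None = None,
    engine: ScoringEngine | None = None,
) -> Dag:
    """Hill-climb to a local BIC optimum satisfying the constraints.

    Requires complete data (impute upstream).  Deterministic for a given
    seed: steepest descent, ties broken lexicographically by
    (child, parent, move kind).
    """
    constraints = constraints or ConstraintSet()
    params = params or SearchParams()
    engine = engine or ScoringEngine(data)
    kinds = {v.name: v.dtype for v in data.variables}
    nodes = data.names

    start = Dag(nodes, constraints.required_edges)
    if not is_acyclic(start):
        raise ValueError("required edges contain a directed cycle")
    violations = check_constraints(start, constraints, data.variables)
    if violations:
        raise ValueError(f"required edges violate constraints: {violations}")

    state = _State(nodes, constraints.required_edges)
    best_state, best_score = _climb(
        state, engine, constraints, kinds, params.move_set, params.max_iterations
    )
    if params.random_restarts > 0:
        rng = np.random.default_rng(params.seed)
        for _ in range(params.random_restarts):
            alt = _perturbed_copy(best_state, constraints, kinds, params.move_set, rng)
            alt, score = _climb(
                alt, engine, constraints, kinds, params.move_set, params.max_iterations
            )
            if score < best_score - _IMPROVE_TOL:
                best_state, best_score = alt, score
    return best_state.to_dag()
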