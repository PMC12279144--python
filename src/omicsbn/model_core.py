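"""Typed variables, data matrices, DAGs and edge/role constraints.

These are the shared containers for the whole pipeline: a
:class:`VariableMeta` records a variable's statistical type (continuous or
discrete) and its biological class (clinical, metabolite, protein, gene
expression or allele score); a :class:`DataMatrix` is a samples x variables
table of mixed values with an explicit missingness mask; a :class:`Dag` is the
unit of structure search and scoring; and a :class:`ConstraintSet` encodes the
edge and role restrictions placed on the search (allele scores act only as
parents of the variable they were built for, sex has no parents, and discrete
nodes may never have continuous parents under the conditional linear-Gaussian
model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
DISCRETE = "discrete"
DTYPES = (CONTINUOUS, DISCRETE)
VCLASSES = ("clinical", "metabolite", "protein", "expression", "allele_score")


@dataclass(frozen=True)
class VariableMeta:
    """Name, statistical type and biological class of one variable.

    Discrete variables carry their category labels in ``levels``; allele
    scores are weighted dosage sums and hence always continuous.
    """

    name: str
    dtype: str
    vclass: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.dtype not in DTYPES:
            raise ValueError(f"unknown dtype {self.dtype!r} for {self.name!r}")
        if self.vclass not in VCLASSES:
            raise ValueError(f"unknown vclass {self.vclass!r} for {self.name!r}")
        if self.dtype == DISCRETE and len(self.levels) < 2:
            raise ValueError(f"discrete variable {self.name!r} needs >=2 levels")
        if self.vclass == "allele_score" and self.dtype != CONTINUOUS:
            raise ValueError(f"allele score {self.name!r} must be continuous")
        object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))

    @property
    def is_discrete(self) -> bool:
        return self.dtype == DISCRETE


def _check_unique_names(variables: Sequence[VariableMeta]) -> None:
    names = [v.name for v in variables]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate variable names: {dup}")


class DataMatrix:
    """Samples x variables table of mixed values with a missingness mask.

    Continuous columns are stored as float64 with NaN marking missing cells;
    discrete columns are pandas Categoricals over their declared levels, with
    NaN again marking missing cells.  Columns are kept in metadata order.
    """

    def __init__(self, frame: pd.DataFrame, variables: Sequence[VariableMeta]):
        _check_unique_names(variables)
        self.variables = list(variables)
        names = [v.name for v in self.variables]
        missing_cols = [n for n in names if n not in frame.columns]
        if missing_cols:
            raise ValueError(f"data lacks declared variables: {missing_cols}")
        frame = frame.loc[:, names].copy()
        for v in self.variables:
            col = frame[v.name]
            if v.is_discrete:
                cat = pd.Categorical(col.astype(object), categories=v.levels)
                bad = col.notna() & pd.isna(cat)
                if bad.any():
                    vals = sorted(set(col[bad].astype(str)))
                    raise ValueError(
                        f"undeclared levels {vals} in discrete variable {v.name!r}"
                    )
                frame[v.name] = cat
            else:
                frame[v.name] = pd.to_numeric(col, errors="raise").astype(float)
        if frame.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        all_missing = [n for n in names if frame[n].isna().all()]
        if all_missing:
            raise ValueError(f"variables with no observed values: {all_missing}")
        self.frame = frame

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.frame.isna()

    def meta(self, name: str) -> VariableMeta:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def is_complete(self) -> bool:
        return not self.frame.isna().any().any()

    def copy(self) -> "DataMatrix":
        return DataMatrix(self.frame.copy(), list(self.variables))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DataMatrix({self.n_samples} samples x {self.n_variables} variables)"


class Dag:
    """Directed graph over named nodes; the unit of search and scoring.

    Construction validates node names and rejects self-edges; acyclicity is a
    separate check (:func:`is_acyclic`) so that candidate edge sets can be
    represented and tested.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        self.nodes = tuple(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        node_set = set(self.nodes)
        edge_set = set()
        for parent, child in edges:
            if parent not in node_set or child not in node_set:
                raise ValueError(f"edge ({parent!r}, {child!r}) uses undeclared node")
            if parent == child:
                raise ValueError(f"self-edge on {parent!r}")
            edge_set.add((parent, child))
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)

    def parents(self, node: str) -> set[str]:
        if node not in self.nodes:
            raise KeyError(node)
        return {p for p, c in self.edges if c == node}

    def children(self, node: str) -> set[str]:
        if node not in self.nodes:
            raise KeyError(node)
        return {c for p, c in self.edges if p == node}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dag):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((frozenset(self.nodes), self.edges))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Dag({len(self.nodes)} nodes, {len(self.edges)} edges)"


def is_acyclic(dag: Dag) -> bool:
    """True iff the edge set contains no directed cycle."""
    return nx.is_directed_acyclic_graph(dag.to_networkx())


def topological_order(dag: Dag) -> list[str]:
    """Parents-before-children order, lexicographic among ties.

    Raises ``ValueError`` on cyclic input.
    """
    try:
        return list(nx.lexicographical_topological_sort(dag.to_networkx()))
    except nx.NetworkXUnfeasible as exc:
        raise ValueError("graph contains a directed cycle") from exc


class Violation(NamedTuple):
    """One broken constraint: the offending edge (or node) and the rule."""

    edge: tuple[str, str] | None
    rule: str
    message: str


@dataclass
class ConstraintSet:
    """Required/forbidden edges plus role constraints on nodes.

    ``parent_only`` nodes accept no incoming edges (allele scores: the
    direction of effect can only run from genotype outward); ``no_parents``
    nodes likewise accept none (e.g. sex).  The prohibition of continuous
    parents for discrete children is automatic under the CLG model and is
    enforced at checking/search time rather than stored edge-by-edge.
    """

    required_edges: set[tuple[str, str]] = field(default_factory=set)
    forbidden_edges: set[tuple[str, str]] = field(default_factory=set)
    parent_only: set[str] = field(default_factory=set)
    no_parents: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.required_edges = set(map(tuple, self.required_edges))
        self.forbidden_edges = set(map(tuple, self.forbidden_edges))
        overlap = self.required_edges & self.forbidden_edges
        if overlap:
            raise ValueError(f"edges both required and forbidden: {sorted(overlap)}")
        for p, c in self.required_edges:
            if c in self.parent_only:
                raise ValueError(f"required edge into parent-only node {c!r}")
            if c in self.no_parents:
                raise ValueError(f"required edge into no-parent node {c!r}")

    @classmethod
    def for_allele_scores(
        cls,
        meta: Sequence[VariableMeta],
        anchors: Mapping[str, str],
        *,
        require_anchor_edges: bool = True,
        no_parents: Iterable[str] = (),
        lock_between_scores: bool = True,
    ) -> "ConstraintSet":
        """Build the study's constraint scheme from allele-score anchors.

        Each allele score is constrained as a parent of the variable it was
        constructed for and no other edges are permitted to or from it.
        ``lock_between_scores`` additionally forbids score-score edges (the
        grammar supports either reading).
        """
        _check_unique_names(meta)
        names = [v.name for v in meta]
        score_names = {v.name for v in meta if v.vclass == "allele_score"}
        unknown = set(anchors) - score_names
        if unknown:
            raise ValueError(f"anchors declared for non-allele-score nodes: {sorted(unknown)}")
        required = set()
        forbidden = set()
        for score, target in anchors.items():
            if target not in names:
                raise KeyError(target)
            if require_anchor_edges:
                required.add((score, target))
            for other in names:
                if other in (score, target):
                    continue
                if other in score_names and not lock_between_scores:
                    continue
                forbidden.add((score, other))
        return cls(
            required_edges=required,
            forbidden_edges=forbidden,
            parent_only=set(score_names),
            no_parents=set(no_parents),
        )


def check_constraints(
    dag: Dag, constraints: ConstraintSet, meta: Sequence[VariableMeta]
) -> list[Violation]:
    """List every role/edge constraint the DAG breaks (empty list = valid)."""
    kinds = {v.name: v.dtype for v in meta}
    missing = [n for n in dag.nodes if n not in kinds]
    if missing:
        raise KeyError(f"nodes without metadata: {missing}")
    out: list[Violation] = []
    for edge in sorted(constraints.required_edges):
        if edge not in dag.edges:
            out.append(Violation(edge, "missing_required", f"required edge {edge} absent"))
    for edge in sorted(dag.edges):
        parent, child = edge
        if edge in constraints.forbidden_edges:
            out.append(Violation(edge, "forbidden_edge", f"forbidden edge {edge} present"))
        if child in constraints.parent_only:
            out.append(
                Violation(edge, "edge_into_parent_only", f"{child!r} admits no incoming edges")
            )
        if child in constraints.no_parents:
            out.append(
                Violation(edge, "edge_into_no_parents", f"{child!r} admits no parents")
            )
        if kinds[child] == DISCRETE and kinds[parent] == CONTINUOUS:
            out.append(
                Violation(
                    edge,
                    "continuous_parent_of_discrete",
                    f"discrete {child!r} cannot have continuous parent {parent!r}",
                )
            )
    return out
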