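"""Bootstrap model averaging: edge strength and direction, analytic threshold.

The data are resampled with replacement (whole individuals, never cells), the
best-fit network is learned on each replicate, and every directed edge is
tallied.  For an unordered node pair {a, b}:

* strength  = proportion of replicates containing a->b or b->a,
* direction = proportion of those replicates with the edge pointing a->b.

These are informally called the edge's "posterior probabilities", though they
are bootstrap proportions, not draws from a Bayesian posterior.  A strength
threshold separating supported edges from noise can be estimated analytically
following Scutari & Nagarajan: the constant c minimising the L1 distance
between the empirical CDF of the strengths and c over [0, 1) is found, and
the threshold is the corresponding quantile of the strengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model_core import ConstraintSet, Dag, DataMatrix
from .scoring import ScoringEngine
from .structure_search import SearchParams, best_fit_network

PAIR_COLUMNS = ["node_a", "node_b", "strength", "direction_a_to_b"]


@dataclass
class AverageNetwork:
    """Per-pair bootstrap tallies.

    ``pairs`` has one row per unordered node pair with strength > 0, node_a <
    node_b lexicographically; strengths are multiples of 1/n_replicates and
    direction_a_to_b + direction_b_to_a = 1.
    """

    pairs: pd.DataFrame
    n_replicates: int
    nodes: tuple[str, ...]
    seed: int | None = None

    @classmethod
    def from_replicates(
        cls,
        dags: Sequence[Dag],
        nodes: Iterable[str] | None = None,
        seed: int | None = None,
    ) -> "AverageNetwork":
        """Tally a list of replicate DAGs into strengths and directions."""
        if not dags:
            raise ValueError("need at least one replicate")
        if nodes is None:
            nodes = dags[0].nodes
        nodes = tuple(nodes)
        r = len(dags)
        counts: dict[tuple[str, str], int] = {}
        for dag in dags:
            for p, c in dag.edges:
                counts[(p, c)] = counts.get((p, c), 0) + 1
        rows = []
        for a, b in sorted({tuple(sorted(k)) for k in counts}):
            fwd = counts.get((a, b), 0)
            rev = counts.get((b, a), 0)
            rows.append((a, b, (fwd + rev) / r, fwd / (fwd + rev)))
        pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
        return cls(pairs=pairs, n_replicates=r, nodes=nodes, seed=seed)

    @property
    def strengths(self) -> np.ndarray:
        return self.pairs["strength"].to_numpy()


def bootstrap_average(
    data: DataMatrix,
    constraints: ConstraintSet | None = None,
    params: SearchParams | None = None,
    n_replicates: int = 1000,
    seed: int = 0,
) -> AverageNetwork:
    """Learn an average network from ``n_replicates`` bootstrap refits.

    One master seed spawns an independent seed per replicate, so replicates
    are reproducible individually and the result is identical whether they
    are run sequentially or in parallel.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    params = params or SearchParams()
    base_engine = ScoringEngine(data)
    n = data.n_samples
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    dags = []
    for child in children:
        rng = np.random.default_rng(child)
        rows = rng.integers(0, n, size=n)
        engine = base_engine.resample(rows)
        rep_params = SearchParams(
            max_iterations=params.max_iterations,
            random_restarts=params.random_restarts,
            seed=int(rng.integers(0, 2**31 - 1)),
            move_set=params.move_set,
        )
        dags.append(best_fit_network(data, constraints, rep_params, engine=engine))
    avg = AverageNetwork.from_replicates(dags, nodes=data.names, seed=seed)
    return avg


def estimate_strength_threshold(strengths: Iterable[float]) -> float:
    """Analytic significance threshold on edge strengths (Scutari's method).

    Finds the level c in [0, 1] minimising the L1 distance between the
    empirical CDF of the strengths and the constant c over [0, 1), then
    returns the c-quantile of the strengths.  Edges at or above the returned
    value are deemed significant.
    """
    s = np.sort(np.asarray(list(strengths), dtype=float))
    if s.size == 0:
        raise ValueError("empty strength list")
    if s.min() < 0 or s.max() > 1:
        raise ValueError("strengths must lie in [0, 1]")
    # Piecewise-constant empirical CDF on [0, 1): segment values and lengths.
    knots = np.unique(np.concatenate(([0.0], s[s < 1.0], [1.0])))
    lengths = np.diff(knots)
    values = np.searchsorted(s, knots[:-1], side="right") / s.size
    keep = lengths > 0
    lengths, values = lengths[keep], values[keep]
    # L1 minimiser over constants = weighted median of the CDF values.
    order = np.argsort(values, kind="stable")
    values, lengths = values[order], lengths[order]
    cum = np.cumsum(lengths)
    c_star = values[np.searchsorted(cum, cum[-1] / 2.0)]
    return float(np.quantile(s, c_star))


def threshold_network(
    avg: AverageNetwork,
    strength_thr: float,
    direction_thr: float = 0.5,
    strength_inclusive: bool = False,
) -> pd.DataFrame:
    """Extract the significant, oriented edge list from an average network.

    Pairs with strength above ``strength_thr`` are kept (strictly above by
    default, matching the display rule "greater than 0.5"; the analytic
    threshold is applied inclusively via ``strength_inclusive``).  Each kept
    pair is oriented in its majority direction; an exact 0.5 tie is oriented
    toward the lexicographically larger node name and flagged unresolved.
    When ``direction_thr`` > 0.5, pairs whose majority direction falls below
    it (strictly) are dropped.

    Returns a DataFrame with columns from, to, strength, direction,
    direction_resolved.
    """
    if not 0.0 <= strength_thr <= 1.0 or not 0.0 <= direction_thr <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    rows = []
    for tup in avg.pairs.itertuples(index=False):
        a, b, strength, d_ab = tup
        if strength_inclusive:
            if strength < strength_thr:
                continue
        elif strength <= strength_thr:
            continue
        resolved = d_ab != 0.5
        if d_ab > 0.5:
            frm, to, direction = a, b, d_ab
        elif d_ab < 0.5:
            frm, to, direction = b, a, 1.0 - d_ab
        else:  # tie: orient toward the lexicographically larger name
            frm, to, direction = a, b, 0.5
        if direction_thr > 0.5 and direction < direction_thr:
            continue
        rows.append((frm, to, strength, direction, resolved))
    out = pd.DataFrame(
        rows, columns=["from", "to", "strength", "direction", "direction_resolved"]
    )
    return out.sort_values(["from", "to"], ignore_index=True)
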