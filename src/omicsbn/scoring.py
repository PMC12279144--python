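"""Decomposable BIC network score for mixed discrete/continuous data.

The model is the conditional linear-Gaussian (CLG) family: a continuous node
is Gaussian with a linear regression on its continuous parents, fitted
separately within each configuration of its discrete parents; a discrete node
is multinomial within each configuration of its (necessarily discrete)
parents.  The network score is a penalized negative log-likelihood,

    BIC(G) = sum_v [ -2 logL(v | parents_v) + k_v ln n ],

with natural logs and lower = better fit.  The score decomposes over
node-parent families, which makes local search moves cheap to evaluate.

Parameters are counted only for parent configurations actually observed in
the data; unobserved cells contribute neither likelihood nor parameters, so
scores stay finite with many discrete levels.  A family whose maximum
likelihood is undefined (some observed configuration has fewer observations
than regression parameters) is flagged invalid and scores +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import CONTINUOUS, DISCRETE, DataMatrix, Dag

# Relative residual-variance floor: perfect in-sample fits (degenerate or
# deterministic synthetic inputs) must score finitely.
_VAR_FLOOR_REL = 1e-12
_VAR_FLOOR_ABS = 1e-300


@dataclass(frozen=True)
class FamilyScore:
    """Fit summary for one node given one parent set."""

    node: str
    parents: frozenset
    loglik: float
    n_params: int
    n_obs: int
    valid: bool = True

    @property
    def bic(self) -> float:
        if not self.valid:
            return math.inf
        return -2.0 * self.loglik + self.n_params * math.log(self.n_obs)


class ScoringEngine:
    """Caches family scores for one (complete) dataset.

    The cache is keyed by (node, sorted parent tuple) and is only ever an
    optimisation: ``family_score`` must return the same value the uncached
    computation would.  ``resample`` produces an engine for a bootstrap
    replicate sharing variable metadata but slicing the value arrays.
    """

    def __init__(self, data: DataMatrix):
        if not data.is_complete():
            raise ValueError("scoring requires complete data; impute first")
        self._kinds: dict[str, str] = {}
        self._cols: dict[str, np.ndarray] = {}
        self._nlevels: dict[str, int] = {}
        for v in data.variables:
            self._kinds[v.name] = v.dtype
            col = data.frame[v.name]
            if v.is_discrete:
                codes = np.asarray(col.cat.codes, dtype=np.int64)
                self._cols[v.name] = codes
                self._nlevels[v.name] = len(v.levels)
            else:
                self._cols[v.name] = np.asarray(col, dtype=float)
        self.n_obs = data.n_samples
        self._log_n = math.log(self.n_obs)
        self._cache: dict[tuple, FamilyScore] = {}

    def resample(self, rows: np.ndarray) -> "ScoringEngine":
        new = object.__new__(ScoringEngine)
        new._kinds = self._kinds
        new._nlevels = self._nlevels
        new._cols = {k: v[rows] for k, v in self._cols.items()}
        new.n_obs = len(rows)
        new._log_n = math.log(new.n_obs)
        new._cache = {}
        return new

    def invalidate(self) -> None:
        """Drop all cached family scores (call after any data change)."""
        self._cache.clear()

    # -- scoring -----------------------------------------------------------
    def family_score(self, node: str, parents=()) -> FamilyScore:
        key = (node, tuple(sorted(parents)))
        hit = self._cache.get(key)
        if hit is None:
            hit = self._score_family(node, key[1])
            self._cache[key] = hit
        return hit

    def family_bic(self, node: str, parents=()) -> float:
        return self.family_score(node, parents).bic

    def network_score(self, dag: Dag) -> float:
        return sum(self.family_bic(v, dag.parents(v)) for v in dag.nodes)

    def _config_ids(self, disc_parents: tuple[str, ...]) -> np.ndarray:
        """Map each row to an integer id of its discrete-parent configuration."""
        ids = np.zeros(self.n_obs, dtype=np.int64)
        for p in disc_parents:
            ids = ids * self._nlevels[p] + self._cols[p]
        return ids

    def _score_family(self, node: str, parents: tuple[str, ...]) -> FamilyScore:
        if node not in self._kinds:
            raise KeyError(node)
        disc = tuple(p for p in parents if self._kinds[p] == DISCRETE)
        cont = tuple(p for p in parents if self._kinds[p] == CONTINUOUS)
        pset = frozenset(parents)
        if self._kinds[node] == DISCRETE:
            if cont:
                raise ValueError(
                    f"discrete node {node!r} cannot have continuous parents {cont}"
                )
            return self._score_discrete(node, disc, pset)
        return self._score_continuous(node, disc, cont, pset)

    def _score_discrete(self, node, disc_parents, pset) -> FamilyScore:
        y = self._cols[node]
        n_levels = self._nlevels[node]
        loglik = 0.0
        n_configs = 0
        for rows in self._config_groups(disc_parents):
            counts = np.bincount(y[rows], minlength=n_levels).astype(float)
            n_c = counts.sum()
            nz = counts > 0
            loglik += float(np.sum(counts[nz] * np.log(counts[nz] / n_c)))
            n_configs += 1
        n_params = (n_levels - 1) * n_configs
        return FamilyScore(node, pset, loglik, max(n_params, 1), self.n_obs)

    def _score_continuous(self, node, disc_parents, cont_parents, pset) -> FamilyScore:
        y_all = self._cols[node]
        p_reg = 1 + len(cont_parents)  # intercept + slopes
        var_y = float(np.var(y_all))
        floor = max(_VAR_FLOOR_REL * var_y, _VAR_FLOOR_ABS)
        if cont_parents:
            x_all = np.column_stack([self._cols[p] for p in cont_parents])
        loglik = 0.0
        n_params = 0
        for rows in self._config_groups(disc_parents):
            y = y_all[rows]
            n_c = y.size
            if n_c < p_reg:
                return FamilyScore(node, pset, math.nan, 0, self.n_obs, valid=False)
            if cont_parents:
                x = np.empty((n_c, p_reg))
                x[:, 0] = 1.0
                x[:, 1:] = x_all[rows]
                beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
                resid = y - x @ beta
                rss = float(resid @ resid)
            else:
                rss = float(np.sum((y - y.mean()) ** 2))
            sigma2 = max(rss / n_c, floor)
            loglik += -0.5 * n_c * math.log(2.0 * math.pi * sigma2) - rss / (2.0 * sigma2)
            n_params += p_reg + 1  # + variance
        return FamilyScore(node, pset, loglik, n_params, self.n_obs)

    def _config_groups(self, disc_parents: tuple[str, ...]):
        """Yield row-index arrays, one per observed discrete-parent configuration."""
        if not disc_parents:
            yield np.arange(self.n_obs)
            return
        ids = self._config_ids(disc_parents)
        order = np.argsort(ids, kind="stable")
        sorted_ids = ids[order]
        boundaries = np.flatnonzero(np.diff(sorted_ids)) + 1
        for chunk in np.split(order, boundaries):
            yield chunk


def family_loglik(node: str, parents, data: DataMatrix) -> tuple[float, int]:
    """One-shot (log-likelihood, parameter count) for a single family."""
    fs = ScoringEngine(data).family_score(node, parents)
    if not fs.valid:
        return math.nan, 0
    return fs.loglik, fs.n_params


def family_bic(node: str, parents, data: DataMatrix) -> float:
    return ScoringEngine(data).family_bic(node, parents)


def network_score(dag: Dag, data: DataMatrix) -> float:
    """Total BIC of a DAG: sum of family BICs over all nodes (lower = better)."""
    return ScoringEngine(data).network_score(dag)
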