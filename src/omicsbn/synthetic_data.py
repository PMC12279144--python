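"""Ground-truth CLG networks and datasets emulating the study's structure.

The generator produces a random conditional linear-Gaussian network over the
five variable classes (clinical, metabolite, protein, expression, allele
score) with class-assortative edge placement (same-class edges favoured,
mirroring the strong diagonal of the observed class-edge table), allele
scores as root nodes with exactly one child each backed by simulated SNP
dosages, ancestral sampling of datasets, and structured missingness
injection, including a "direct-like" preset: T2D case/control labels,
block-missing clinical variables such that no individual is complete, and a
small group of individuals missing every protein.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics import GenotypeMatrix
from .model_core import (
    CONTINUOUS,
    DISCRETE,
    ConstraintSet,
    Dag,
    DataMatrix,
    VariableMeta,
    topological_order,
)

_CLASS_PREFIX = {
    "clinical": "cli",
    "metabolite": "met",
    "protein": "pro",
    "expression": "exp",
}


@dataclass
class ContinuousParams:
    """Per-configuration linear-Gaussian family for one continuous node."""

    intercepts: dict[tuple, float]
    coefficients: dict[str, float]  # continuous parents, shared across configs
    residual_sd: float


@dataclass
class DiscreteParams:
    """Per-configuration multinomial tables for one discrete node."""

    tables: dict[tuple, np.ndarray]


@dataclass
class SnpEffect:
    """SNPs, weights and target effect behind one allele score."""

    snp_ids: list[str]
    mafs: np.ndarray
    weights: np.ndarray
    target: str
    effect: float  # coefficient applied to the raw score in the target's family


@dataclass
class GroundTruthModel:
    dag: Dag
    meta: list[VariableMeta]
    parameters: dict[str, ContinuousParams | DiscreteParams]
    snp_effects: dict[str, SnpEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kinds = {v.name: v.dtype for v in self.meta}
        for p, c in self.dag.edges:
            if kinds[c] == DISCRETE and kinds[p] == CONTINUOUS:
                raise ValueError("ground truth violates CLG typing")
        for score in self.snp_effects:
            if self.dag.parents(score):
                raise ValueError(f"allele score {score!r} must be a root")
            if len(self.dag.children(score)) != 1:
                raise ValueError(f"allele score {score!r} must have exactly one child")

    def constraints(self, no_parents: Iterable[str] = ()) -> ConstraintSet:
        """The study-style constraint set implied by the model's anchors."""
        anchors = {s: e.target for s, e in self.snp_effects.items()}
        return ConstraintSet.for_allele_scores(
            self.meta, anchors, no_parents=no_parents
        )

    @property
    def discrete_parent_levels(self) -> dict[str, tuple[str, ...]]:
        return {v.name: v.levels for v in self.meta if v.is_discrete}


def _config_iter(levels_per_parent: Sequence[int]):
    if not levels_per_parent:
        yield ()
        return
    yield from itertools.product(*(range(k) for k in levels_per_parent))


def simulate_model(
    n_per_class: Mapping[str, int],
    max_in_degree: int = 3,
    edge_density: float = 0.15,
    effect_range: tuple[float, float] = (0.5, 1.0),
    seed: int = 0,
    assortativity: float = 0.8,
    n_discrete_clinical: int = 0,
    discrete_levels: int = 2,
    residual_sd: float = 1.0,
    n_snps_per_score: int = 5,
) -> GroundTruthModel:
    """Random constraint-respecting ground-truth model.

    ``n_per_class`` maps class names to counts.  Edges are sampled over a
    random topological order of the non-score nodes; a same-class pair is
    accepted with probability ``2 * assortativity * edge_density`` and a
    cross-class pair with ``2 * (1 - assortativity) * edge_density``
    (assortativity 0.5 = no class preference).  Edge coefficients have
    magnitude drawn from ``effect_range`` with random sign.  Each allele
    score is a root with exactly one child, its designated target, and is
    backed by ``n_snps_per_score`` simulated SNPs; its coefficient is scaled
    by the score's theoretical SD so anchors carry effects comparable to
    other parents.
    """
    rng = np.random.default_rng(seed)
    counts = {c: int(n_per_class.get(c, 0)) for c in _CLASS_PREFIX}
    n_scores = int(n_per_class.get("allele_score", 0))
    if min(counts.values()) < 0 or n_scores < 0 or max_in_degree < 1:
        raise ValueError("counts must be >= 0 and max_in_degree >= 1")

    meta: list[VariableMeta] = []
    for vclass, prefix in _CLASS_PREFIX.items():
        for i in range(counts[vclass]):
            name = f"{prefix}_{i + 1:03d}"
            if vclass == "clinical" and i < n_discrete_clinical:
                levels = tuple(f"L{j}" for j in range(discrete_levels))
                meta.append(VariableMeta(name, DISCRETE, "clinical", levels))
            else:
                meta.append(VariableMeta(name, CONTINUOUS, vclass))
    substantive = [v.name for v in meta]
    kinds = {v.name: v.dtype for v in meta}
    vclass_of = {v.name: v.vclass for v in meta}

    # random topological order, then assortative edge sampling
    order = list(rng.permutation(substantive))
    edges: list[tuple[str, str]] = []
    in_deg = {n: 0 for n in substantive}
    for i, child in enumerate(order):
        candidates = list(order[:i])
        rng.shuffle(candidates)
        for parent in candidates:
            if in_deg[child] >= max_in_degree:
                break
            if kinds[child] == DISCRETE and kinds[parent] == CONTINUOUS:
                continue
            same = vclass_of[parent] == vclass_of[child]
            p_edge = 2.0 * edge_density * (assortativity if same else 1.0 - assortativity)
            if rng.random() < min(p_edge, 1.0):
                edges.append((parent, child))
                in_deg[child] += 1

    # allele scores: roots with one child, anchored on continuous targets
    cont_targets = [n for n in substantive if kinds[n] == CONTINUOUS]
    if n_scores > len(cont_targets):
        raise ValueError("more allele scores than continuous target variables")
    targets = [str(t) for t in rng.choice(cont_targets, size=n_scores, replace=False)]
    snp_effects: dict[str, SnpEffect] = {}
    for k, target in enumerate(targets):
        score = f"AS_{target}"
        meta.append(VariableMeta(score, CONTINUOUS, "allele_score"))
        edges.append((score, target))
        mafs = rng.uniform(0.1, 0.5, size=n_snps_per_score)
        weights = rng.uniform(0.2, 1.0, size=n_snps_per_score)
        sd = float(np.sqrt(np.sum(weights**2 * 2.0 * mafs * (1.0 - mafs))))
        magnitude = rng.uniform(*effect_range)
        effect = float(rng.choice([-1.0, 1.0]) * magnitude / sd)
        snp_ids = [f"{score}_snp{j + 1}" for j in range(n_snps_per_score)]
        snp_effects[score] = SnpEffect(snp_ids, mafs, weights, target, effect)

    dag = Dag([v.name for v in meta], edges)
    levels_of = {v.name: v.levels for v in meta if v.is_discrete}

    parameters: dict[str, ContinuousParams | DiscreteParams] = {}
    for v in meta:
        parents = sorted(dag.parents(v.name))
        disc_parents = [p for p in parents if kinds.get(p) == DISCRETE]
        cont_parents = [p for p in parents if kinds.get(p, CONTINUOUS) == CONTINUOUS]
        level_counts = [len(levels_of[p]) for p in disc_parents]
        if v.is_discrete:
            tables = {
                cfg: rng.dirichlet(np.full(len(v.levels), 2.0))
                for cfg in _config_iter(level_counts)
            }
            parameters[v.name] = DiscreteParams(tables)
        else:
            coefs: dict[str, float] = {}
            for p in cont_parents:
                if p in snp_effects:
                    coefs[p] = snp_effects[p].effect
                else:
                    coefs[p] = float(
                        rng.choice([-1.0, 1.0]) * rng.uniform(*effect_range)
                    )
            intercepts = {
                cfg: float(
                    rng.choice([-1.0, 1.0]) * rng.uniform(*effect_range)
                    if disc_parents
                    else rng.normal(0.0, 1.0)
                )
                for cfg in _config_iter(level_counts)
            }
            parameters[v.name] = ContinuousParams(intercepts, coefs, residual_sd)
    return GroundTruthModel(dag, meta, parameters, snp_effects)


def simulate_genotypes(
    n: int,
    mafs: np.ndarray,
    seed: int | np.random.Generator = 0,
    snp_ids: Sequence[str] | None = None,
    chromosome: Sequence | None = None,
    position: Sequence[int] | None = None,
    ld_block_size: int = 1,
    ld_r2: float = 0.0,
) -> GenotypeMatrix:
    """Binomial(2, MAF) dosages, optionally correlated in LD blocks.

    LD is induced by first-order autoregressive allele copying within blocks:
    each haplotype allele is copied from the previous SNP with probability
    sqrt(ld_r2) (the target pairwise correlation of adjacent SNPs with equal
    MAFs), otherwise drawn fresh.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = np.asarray(mafs, dtype=float)
    m = mafs.size
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(m)]
    if chromosome is None:
        chromosome = np.ones(m, dtype=int)
    if position is None:
        position = np.arange(m, dtype=np.int64) * 10_000
    hap = rng.random((n, 2, m)) < mafs  # two haplotypes per individual
    if ld_block_size > 1 and ld_r2 > 0:
        copy_p = float(np.sqrt(ld_r2))
        for j in range(1, m):
            if j % ld_block_size == 0:
                continue  # block boundary: no copying across blocks
            copy = rng.random((n, 2)) < copy_p
            hap[:, :, j] = np.where(copy, hap[:, :, j - 1], hap[:, :, j])
    dosages = hap.sum(axis=1).astype(float)
    return GenotypeMatrix(
        sample_ids=[f"S{i + 1:05d}" for i in range(n)],
        snp_ids=list(snp_ids),
        chromosome=np.asarray(chromosome),
        position=np.asarray(position, dtype=np.int64),
        dosages=dosages,
    )


def simulate_dataset(
    model: GroundTruthModel, n: int, seed: int = 0
) -> tuple[DataMatrix, GenotypeMatrix | None]:
    """Ancestral sampling of ``n`` individuals from the ground truth.

    SNP dosages behind the allele scores are simulated first, score columns
    computed from them, and the remaining nodes sampled in topological
    order: discrete nodes from their per-configuration multinomial tables,
    continuous nodes as intercept(config) + sum(coef x parent) + Gaussian
    noise.  Returns the data and the genotype matrix (None when the model
    has no allele scores).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    kinds = {v.name: v.dtype for v in model.meta}
    levels_of = {v.name: v.levels for v in model.meta if v.is_discrete}
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    genotypes: GenotypeMatrix | None = None
    score_values: dict[str, np.ndarray] = {}
    if model.snp_effects:
        all_ids, all_mafs, all_chrom, all_pos = [], [], [], []
        for k, (score, eff) in enumerate(sorted(model.snp_effects.items())):
            all_ids.extend(eff.snp_ids)
            all_mafs.extend(eff.mafs)
            all_chrom.extend([k + 1] * len(eff.snp_ids))
            all_pos.extend(np.arange(len(eff.snp_ids)) * 10_000)
        genotypes = simulate_genotypes(
            n,
            np.array(all_mafs),
            rng,
            snp_ids=all_ids,
            chromosome=np.array(all_chrom),
            position=np.array(all_pos),
        )
        genotypes.sample_ids = sample_ids
        for score, eff in model.snp_effects.items():
            cols = np.array([genotypes.snp_index(s) for s in eff.snp_ids])
            score_values[score] = genotypes.dosages[:, cols] @ eff.weights

    values: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    for node in topological_order(model.dag):
        if node in score_values:
            values[node] = score_values[node]
            continue
        parents = sorted(model.dag.parents(node))
        disc_parents = [p for p in parents if kinds[p] == DISCRETE]
        cont_parents = [p for p in parents if kinds[p] == CONTINUOUS]
        if disc_parents:
            cfg_codes = np.stack([codes[p] for p in disc_parents], axis=1)
        params = model.parameters[node]
        if kinds[node] == DISCRETE:
            n_levels = len(levels_of[node])
            out = np.empty(n, dtype=np.int64)
            if disc_parents:
                for cfg, probs in params.tables.items():
                    rows = np.all(cfg_codes == np.array(cfg), axis=1)
                    if rows.any():
                        out[rows] = rng.choice(n_levels, size=int(rows.sum()), p=probs)
            else:
                out[:] = rng.choice(n_levels, size=n, p=params.tables[()])
            codes[node] = out
            values[node] = out
        else:
            mean = np.zeros(n)
            if disc_parents:
                for cfg, icept in params.intercepts.items():
                    rows = np.all(cfg_codes == np.array(cfg), axis=1)
                    mean[rows] = icept
            else:
                mean[:] = params.intercepts[()]
            for p in cont_parents:
                mean = mean + params.coefficients[p] * values[p]
            noise = rng.normal(0.0, params.residual_sd, size=n) if params.residual_sd > 0 else 0.0
            values[node] = mean + noise

    columns = {
        v.name: [v.levels[c] for c in codes[v.name]] if v.is_discrete else values[v.name]
        for v in model.meta
    }
    frame = pd.DataFrame(columns, index=pd.Index(sample_ids, name="sample_id"))
    return DataMatrix(frame, model.meta), genotypes


@dataclass
class MissingnessSpec:
    """Blocks of structured missingness.

    Each block is (row selector, variable names, missing fraction); the row
    selector is a boolean array over samples or a callable on sample ids.
    ``ensure_no_complete_row`` masks one extra cell (among the spec's
    variables) in every otherwise-complete row, reproducing datasets where
    no individual is complete.
    """

    blocks: list[tuple[np.ndarray | Callable, Sequence[str], float]]
    ensure_no_complete_row: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for _, _, frac in self.blocks:
            if not 0.0 <= frac <= 1.0:
                raise ValueError("missing fractions must lie in [0, 1]")


def inject_missingness(data: DataMatrix, spec: MissingnessSpec) -> DataMatrix:
    """Mask cells per the spec; observed values are never altered."""
    rng = np.random.default_rng(spec.seed)
    frame = data.frame.copy()
    names = data.names
    spec_vars: set[str] = set()
    for rows, variables, frac in spec.blocks:
        variables = list(variables)
        unknown = [v for v in variables if v not in names]
        if unknown:
            raise KeyError(f"unknown variables in missingness spec: {unknown}")
        spec_vars.update(variables)
        if callable(rows):
            row_mask = np.array([bool(rows(s)) for s in data.sample_ids])
        else:
            row_mask = np.asarray(rows, dtype=bool)
        idx = np.flatnonzero(row_mask)
        for var in variables:
            if frac >= 1.0:
                hit = idx
            else:
                hit = idx[rng.random(idx.size) < frac]
            frame.iloc[hit, names.index(var)] = np.nan
    if spec.ensure_no_complete_row and spec_vars:
        cols = sorted(spec_vars)
        sub = frame[cols]
        complete = ~sub.isna().any(axis=1)
        observed_left = {v: int(frame[v].notna().sum()) for v in cols}
        for i in np.flatnonzero(complete.to_numpy()):
            # never exhaust a variable: each must keep >= 1 observed value
            eligible = [v for v in cols if observed_left[v] > 1]
            if not eligible:
                raise ValueError("cannot break complete rows without exhausting a variable")
            var = eligible[rng.integers(0, len(eligible))]
            frame.iloc[i, names.index(var)] = np.nan
            observed_left[var] -= 1
    all_missing = [v for v in names if frame[v].isna().all()]
    if all_missing:
        raise ValueError(
            f"missingness spec leaves variables with no observed values: {all_missing}"
        )
    return DataMatrix(frame, data.variables)


# ---------------------------------------------------------------------------
# "direct-like" preset
# ---------------------------------------------------------------------------

_DIRECT_CLASS_COUNTS = {
    "clinical": 65,
    "metabolite": 34,
    "protein": 27,
    "expression": 33,
    "allele_score": 101,
}
_DIRECT_N = 3029
_DIRECT_CASES = 795
_DIRECT_NO_PROTEIN = 14


@dataclass
class DirectLikeData:
    """Bundle emitted by the direct-like preset."""

    model: GroundTruthModel
    data: DataMatrix  # with injected missingness
    complete: DataMatrix  # pre-missingness
    genotypes: GenotypeMatrix | None
    t2d: np.ndarray  # 0/1 case labels
    constraints: ConstraintSet


def direct_like(scale: float = 1.0, seed: int = 0) -> DirectLikeData:
    """Synthetic dataset shaped like the study's: at full scale 3029
    individuals (795 T2D cases), 260 mixed variables, block-missing clinical
    variables (no individual complete), and a small group missing all
    proteins.

    ``scale`` shrinks both the variable-class counts and the sample size for
    fast tests while preserving the structure.  T2D is stored as a 0/1
    variable declared continuous, as in the study, so it may have continuous
    parents.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    counts = {
        c: max(1, round(k * scale)) for c, k in _DIRECT_CLASS_COUNTS.items()
    }
    # keep the clinical block viable at small scales: sex/centre-like discrete
    # pair, the T2D indicator, and >= 3 maskable clinical variables
    counts["clinical"] = max(counts["clinical"], 6)
    n_cont_targets = (
        counts["metabolite"] + counts["protein"] + counts["expression"]
        + counts["clinical"] - 2  # discrete sex/centre cannot anchor scores
    )
    counts["allele_score"] = min(counts["allele_score"], n_cont_targets)
    n = max(40, round(_DIRECT_N * scale))
    model = simulate_model(
        counts,
        max_in_degree=3,
        edge_density=min(0.3, 2.5 / max(sum(counts.values()) - counts["allele_score"], 2)),
        effect_range=(0.5, 1.0),
        seed=int(rng.integers(0, 2**31 - 1)),
        n_discrete_clinical=2,  # sex-like (binary) and centre-like
        discrete_levels=2,
        n_snps_per_score=5,
    )
    data, genotypes = simulate_dataset(model, n, seed=int(rng.integers(0, 2**31 - 1)))

    # designate the first continuous clinical variable as the T2D indicator:
    # binarised at the case prevalence, declared continuous as in the study
    clinical_cont = [
        v.name for v in model.meta if v.vclass == "clinical" and not v.is_discrete
    ]
    t2d_var = clinical_cont[0]
    n_cases = max(1, round(_DIRECT_CASES / _DIRECT_N * n))
    col = data.frame[t2d_var].to_numpy(dtype=float)
    cut = np.sort(col)[n - n_cases]
    t2d = (col >= cut).astype(float)
    frame = data.frame.copy()
    frame[t2d_var] = t2d
    complete = DataMatrix(frame, model.meta)

    # missingness: clinical block structure + a few individuals with no proteins
    clinical = [v.name for v in model.meta if v.vclass == "clinical"]
    maskable = [v for v in clinical if v != t2d_var][2:]  # keep sex/centre observed
    cases = t2d == 1.0
    blocks: list[tuple[np.ndarray, Sequence[str], float]] = []
    third = max(1, len(maskable) // 3)
    case_only_missing = maskable[:third]          # no data for cases
    control_only_missing = maskable[third : 2 * third]  # no data for controls
    mcar_vars = maskable[2 * third :]
    if case_only_missing:
        blocks.append((cases, case_only_missing, 1.0))
    if control_only_missing:
        blocks.append((~cases, control_only_missing, 1.0))
    if mcar_vars:
        blocks.append((np.ones(n, dtype=bool), mcar_vars, 0.2))
    proteins = [v.name for v in model.meta if v.vclass == "protein"]
    n_no_protein = max(1, round(_DIRECT_NO_PROTEIN / _DIRECT_N * n))
    no_protein_rows = np.zeros(n, dtype=bool)
    no_protein_rows[rng.choice(n, size=n_no_protein, replace=False)] = True
    blocks.append((no_protein_rows, proteins, 1.0))
    spec = MissingnessSpec(
        blocks=blocks,
        ensure_no_complete_row=True,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    masked = inject_missingness(complete, spec)

    sex_like = next(v.name for v in model.meta if v.is_discrete)
    constraints = model.constraints(no_parents=[sex_like])
    return DirectLikeData(
        model=model,
        data=masked,
        complete=complete,
        genotypes=genotypes,
        t2d=t2d,
        constraints=constraints,
    )
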