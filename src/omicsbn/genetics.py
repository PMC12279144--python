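"""Genetic pre-processing: association scans, Bonferroni variable filtering,
LD clumping, weighted allele scores and the rank-based inverse normal
transform.

Molecular variables enter the network only if robustly genetically
anchored: metabolites and proteins need at least ``min_snps`` SNPs
associated below a Bonferroni-adjusted threshold, gene expression variables
more than one.  For each retained variable a weighted allele score —
the dosage sum over its clumped (LD-independent) significant SNPs, weighted
by estimated allelic effect — provides a parent-only causal anchor that
helps orient non-genetic edges downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenotypeMatrix:
    """Sample x SNP dosage matrix (0/1/2, NaN = missing) with a SNP map."""

    sample_ids: list
    snp_ids: list[str]
    chromosome: np.ndarray
    position: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chromosome = np.asarray(self.chromosome)
        self.position = np.asarray(self.position, dtype=np.int64)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snp_ids):
            raise ValueError("dosage matrix shape inconsistent with ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        if self.chromosome.shape != (m,) or self.position.shape != (m,):
            raise ValueError("SNP map length inconsistent")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        for chrom in np.unique(self.chromosome):
            pos = self.position[self.chromosome == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted within chromosome {chrom!r}")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None

    def dosage_filled(self, cols: np.ndarray | None = None) -> np.ndarray:
        """Dosages with missing cells replaced by the per-SNP mean."""
        g = self.dosages if cols is None else self.dosages[:, cols]
        g = g.copy()
        means = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = means[idx[1]]
        return g


@dataclass(frozen=True)
class AssocResult:
    snp_id: str
    beta: float
    se: float
    pvalue: float


@dataclass
class FilterParams:
    """Thresholds of the genetics-based variable filter."""

    alpha: float = 0.01
    min_snps: int = 20
    expression_min_snps: int = 2
    clinical_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def association_scan(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    covariates: np.ndarray | None = None,
) -> list[AssocResult]:
    """Per-SNP linear regression of ``y`` on dosage plus covariates.

    Covariates (e.g. genetic principal components; an intercept is always
    added) are projected out of both ``y`` and each dosage column
    (Frisch-Waugh), then the per-SNP slope, its standard error and the
    Wald p-value are computed with the correct residual degrees of freedom.
    Missing dosages are mean-imputed per SNP; a monomorphic SNP yields an
    undefined beta and p = 1.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if np.isnan(y).any():
        raise ValueError("phenotype must be complete for tested samples")
    if covariates is None:
        cov = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        cov = np.column_stack([np.ones(n), covariates])
    q, _ = np.linalg.qr(cov)
    y_res = y - q @ (q.T @ y)
    g = genotypes.dosage_filled()
    g_res = g - q @ (q.T @ g)
    df = n - cov.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough samples for the covariate model")
    results = []
    for j, snp in enumerate(genotypes.snp_ids):
        gj = g_res[:, j]
        sxx = float(gj @ gj)
        if sxx <= 1e-12 * n:  # monomorphic (or covariate-collinear) SNP
            results.append(AssocResult(snp, np.nan, np.nan, 1.0))
            continue
        beta = float(gj @ y_res) / sxx
        rss = float(np.sum((y_res - beta * gj) ** 2))
        sigma2 = rss / df
        se = float(np.sqrt(sigma2 / sxx)) if sigma2 > 0 else 0.0
        if se == 0.0:
            p = 0.0 if beta != 0 else 1.0
        else:
            t = beta / se
            p = float(2.0 * stats.t.sf(abs(t), df))
        results.append(AssocResult(snp, beta, se, max(p, 5e-324)))
    return results


def bonferroni_retain(
    pvalues: pd.DataFrame,
    params: FilterParams | None = None,
    rule: str = "min_snps",
    alpha: float | None = None,
) -> dict[str, list[str]]:
    """Retain variables with enough Bonferroni-significant SNPs.

    ``pvalues`` is variables x SNPs.  The significance threshold is
    ``alpha / (number of tests in the scan)`` — i.e. the full matrix size.
    Under ``rule="min_snps"`` a variable needs >= ``params.min_snps``
    significant SNPs; under ``rule="expression"`` more than one
    (>= ``params.expression_min_snps``).  Returns {variable: [significant
    SNPs, p-ascending]} for retained variables only.
    """
    params = params or FilterParams()
    if rule not in ("min_snps", "expression"):
        raise ValueError(f"unknown rule {rule!r}")
    need = params.min_snps if rule == "min_snps" else params.expression_min_snps
    base_alpha = params.alpha if alpha is None else alpha
    threshold = base_alpha / pvalues.size
    out: dict[str, list[str]] = {}
    for var, row in pvalues.iterrows():
        hits = row[row < threshold].sort_values()
        if len(hits) >= need:
            out[str(var)] = [str(s) for s in hits.index]
    return out


def clump(
    assoc: Sequence[AssocResult],
    genotypes: GenotypeMatrix,
    r2_max: float = 0.1,
    window_bp: int = 250_000,
) -> list[str]:
    """Greedy LD clumping: keep index SNPs, discard correlated neighbours.

    Repeatedly takes the lowest-p unclaimed SNP as an index SNP and discards
    unclaimed SNPs on the same chromosome within ``window_bp`` whose squared
    dosage correlation with it exceeds ``r2_max``.  Returns index SNPs in
    p-ascending order.
    """
    if not assoc:
        return []
    cols = np.array([genotypes.snp_index(a.snp_id) for a in assoc])
    g = genotypes.dosage_filled(cols)
    g = g - g.mean(axis=0)
    norms = np.sqrt(np.sum(g**2, axis=0))
    chrom = genotypes.chromosome[cols]
    pos = genotypes.position[cols]
    order = sorted(
        range(len(assoc)), key=lambda i: (assoc[i].pvalue, assoc[i].snp_id)
    )
    claimed = np.zeros(len(assoc), dtype=bool)
    kept: list[str] = []
    for i in order:
        if claimed[i]:
            continue
        claimed[i] = True
        kept.append(assoc[i].snp_id)
        near = (
            ~claimed
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window_bp)
        )
        if near.any():
            idx = np.flatnonzero(near)
            denom = norms[idx] * norms[i]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, (g[:, idx].T @ g[:, i]) / denom, 0.0)
            claimed[idx[r**2 > r2_max]] = True
    return kept


def allele_score(
    genotypes: GenotypeMatrix,
    snps: Sequence[str],
    weights: Mapping[str, float] | Sequence[float],
) -> np.ndarray:
    """Weighted dosage sum per individual: score_i = sum_j w_j * dosage_ij.

    Missing dosages contribute w_j times the SNP's mean dosage.
    """
    if not isinstance(weights, Mapping):
        if len(weights) != len(snps):
            raise ValueError("weights and snps length mismatch")
        weights = dict(zip(snps, weights))
    missing_w = [s for s in snps if s not in weights]
    if missing_w:
        raise KeyError(f"weights undefined for SNPs: {missing_w}")
    cols = np.array([genotypes.snp_index(s) for s in snps], dtype=int)
    g = genotypes.dosage_filled(cols)
    w = np.array([weights[s] for s in snps], dtype=float)
    return g @ w


def inverse_normal_transform(
    x: np.ndarray | Sequence[float], offset: float = 0.5
) -> np.ndarray:
    """Rank-based inverse normal transform; missing values stay missing.

    Uses averaged ranks r and maps to Phi^{-1}((r - c) / (n - 2c + 1)); the
    default rankit offset c = 0.5 gives (r - 0.5)/n, the Blom variant is
    c = 0.375.  Strictly monotone on distinct values; ties share a value.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    vals = x[obs]
    if np.unique(vals).size < 2:
        raise ValueError("inverse normal transform undefined for a constant vector")
    ranks = stats.rankdata(vals, method="average")
    n = vals.size
    out[obs] = stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out
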