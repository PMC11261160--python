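"""Supporting population-genetic summaries.

Per-sample heterozygosities and the inbreeding coefficient FIS, pairwise
Weir-Cockerham FST with permutation significance and Benjamini-Hochberg
FDR control, and PCA of the genotype matrix with most-common-genotype
imputation of missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .matrix import MISSING, GenotypeMatrix

__all__ = ["DiversitySummary", "FstResult", "diversity", "pairwise_fst", "pca_imputed"]


@dataclass
class DiversitySummary:
    label: str
    n_individuals: int
    ho: float   # mean observed heterozygosity over variant loci
    he: float   # mean unbiased expected heterozygosity
    fis: float  # 1 - Ho/He per locus, averaged over loci with He > 0


@dataclass
class FstResult:
    labels: list[str]
    fst: pd.DataFrame          # symmetric, zero diagonal
    p_values: pd.DataFrame
    p_adjusted: pd.DataFrame   # Benjamini-Hochberg across pairs
    permutations: int


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def diversity(matrix: GenotypeMatrix, by: str = "population") -> list[DiversitySummary]:
    """Ho, He and FIS per sample, averaged over variant loci.

    Per locus: Ho is the fraction heterozygous among called genotypes; He
    is ``2 p q * n/(n-1)`` (unbiased); FIS is ``1 - Ho/He`` over loci with
    He > 0.  Loci monomorphic within the sample are excluded from means.
    """
    out: list[DiversitySummary] = []
    for label, sub in matrix.split_by(by).items():
        g = sub.genotypes
        called = g != MISSING
        n = called.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(g == MISSING, 0, g).sum(axis=0) / (2.0 * np.maximum(n, 1))
            ho = (g == 1).sum(axis=0) / np.maximum(n, 1)
            he = 2.0 * p * (1.0 - p) * n / np.maximum(n - 1.0, 1)
        variant = (n >= 2) & (p > 0) & (p < 1)
        if not variant.any():
            out.append(DiversitySummary(label, sub.n_individuals, float("nan"),
                                        float("nan"), float("nan")))
            continue
        fis_locus = 1.0 - ho[variant] / he[variant]
        out.append(
            DiversitySummary(
                label=label,
                n_individuals=sub.n_individuals,
                ho=float(ho[variant].mean()),
                he=float(he[variant].mean()),
                fis=float(fis_locus.mean()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(g_pops: list[np.ndarray]) -> tuple[float, float]:
    """Weir-Cockerham (1984) variance components summed over loci.

    Returns (sum_a, sum_a+b+c); multi-locus FST is their ratio.  Each
    element of ``g_pops`` is an (individuals, loci) allele-count array for
    one population; sample sizes are per-locus called counts.
    """
    r = len(g_pops)
    L = g_pops[0].shape[1]
    n_il = np.stack([(g != MISSING).sum(axis=0) for g in g_pops]).astype(float)  # r x L
    with np.errstate(invalid="ignore", divide="ignore"):
        p_il = np.stack(
            [np.where(g == MISSING, 0, g).sum(axis=0) for g in g_pops]
        ) / (2.0 * np.maximum(n_il, 1))
        h_il = np.stack([(g == 1).sum(axis=0) for g in g_pops]) / np.maximum(n_il, 1)

    ok = (n_il >= 1).all(axis=0)
    n_il, p_il, h_il = n_il[:, ok], p_il[:, ok], h_il[:, ok]

    nbar = n_il.mean(axis=0)
    nc = (r * nbar - (n_il**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n_il * p_il).sum(axis=0) / (r * nbar)
    s2 = (n_il * (p_il - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_il * h_il).sum(axis=0) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2
    usable = np.isfinite(a) & np.isfinite(b) & (nbar > 1) & (nc > 0)
    return float(a[usable].sum()), float((a + b + c)[usable].sum())


def _wc_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    num, den = _wc_components([g1, g2])
    return num / den if den != 0 else float("nan")


def pairwise_fst(
    matrix: GenotypeMatrix,
    permutations: int = 1000,
    seed: int = 0,
    by: str = "population",
) -> FstResult:
    """Pairwise multi-locus Weir-Cockerham FST with permutation p-values.

    The null distribution shuffles population labels of individuals
    (diploid genotypes kept intact); ``p = (1 + #{perm >= obs}) /
    (1 + permutations)``.  BH adjustment is applied across all pairs.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    pops = matrix.split_by(by)
    labels = list(pops)
    if len(labels) < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(seed)

    k = len(labels)
    fst = np.zeros((k, k))
    pval = np.full((k, k), np.nan)
    np.fill_diagonal(pval, 0.0)
    pairs: list[tuple[int, int]] = []
    raw_p: list[float] = []
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = pops[labels[i]].genotypes, pops[labels[j]].genotypes
            obs = _wc_fst(g1, g2)
            fst[i, j] = fst[j, i] = obs
            pooled = np.vstack([g1, g2])
            n1 = g1.shape[0]
            count = 0
            for _ in range(permutations):
                perm = rng.permutation(pooled.shape[0])
                f = _wc_fst(pooled[perm[:n1]], pooled[perm[n1:]])
                if f >= obs:
                    count += 1
            p = (1 + count) / (1 + permutations)
            pairs.append((i, j))
            raw_p.append(p)
    adj = multipletests(raw_p, method="fdr_bh")[1] if raw_p else []
    padj = np.full((k, k), np.nan)
    np.fill_diagonal(padj, 0.0)
    for (i, j), p, q in zip(pairs, raw_p, adj):
        pval[i, j] = pval[j, i] = p
        padj[i, j] = padj[j, i] = q
    idx = pd.Index(labels)
    return FstResult(
        labels=labels,
        fst=pd.DataFrame(fst, index=idx, columns=idx),
        p_values=pd.DataFrame(pval, index=idx, columns=idx),
        p_adjusted=pd.DataFrame(padj, index=idx, columns=idx),
        permutations=permutations,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def impute_modal(matrix: GenotypeMatrix) -> np.ndarray:
    """Replace missing calls with the per-locus modal genotype.

    Ties break toward the smaller allele count; a locus with no called
    genotypes is an error.
    """
    g = matrix.genotypes.astype(np.float64)
    called = matrix.called
    if not called.any(axis=0).all():
        raise ValueError("locus with all genotypes missing")
    out = g.copy()
    for j in np.flatnonzero(~called.all(axis=0)):
        col = g[:, j]
        counts = [(col[called[:, j]] == v).sum() for v in (0, 1, 2)]
        modal = int(np.argmax(counts))  # argmax takes the first (smallest) on ties
        out[~called[:, j], j] = modal
    return out


def pca_imputed(matrix: GenotypeMatrix, components: int = 2) -> np.ndarray:
    """PCA scores of individuals after modal-genotype imputation.

    Columns are centred by the PCA itself; scores are deterministic up to
    the sign of each component.
    """
    if components > min(matrix.n_individuals, matrix.n_loci):
        raise ValueError("components exceeds matrix rank bound")
    filled = impute_modal(matrix)
    return PCA(n_components=components, svd_solver="full").fit_transform(filled)
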