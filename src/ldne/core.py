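"""Single-sample effective-size estimation from linkage disequilibrium.

The estimator measures the squared correlation of Burrows' composite
disequilibrium between all pairs of loci, subtracts the expected
contribution of finite sampling, and converts the residual "drift" LD into
an estimate of the effective number of breeders (single-cohort sample) or
the generational effective size (mixed-age sample).  Confidence intervals
come from a delete-one-individual jackknife that treats the mean pairwise
r-squared as a scaled chi-square variable, countering pseudoreplication
across the O(L^2) locus pairs.

Composite disequilibrium is phase-free: with genotypes coded as
alternate-allele counts ``x, y`` in {0, 1, 2} over the ``n`` individuals
called at both loci,

    Delta = n/(n-1) * [ sum(x * y) / (2 n) - 2 * p_x * p_y ]
    tau_x = p_x (1 - p_x) + (P_hom_alt_x - p_x^2)          # homozygote excess
    r^2   = Delta^2 / (tau_x * tau_y)

(the n/(n-1) factor is the standard small-sample correction of the
composite estimator) and requires no Hardy-Weinberg assumption at either
locus.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .matrix import MISSING, EmptyDataError, GenotypeMatrix

__all__ = [
    "EstimatorConfig",
    "LDStatistics",
    "RawEstimate",
    "LDNeEstimator",
    "screen_loci",
    "pair_r2",
    "expected_sample_r2",
    "ne_from_r2drift",
    "estimate_raw",
    "jackknife_ci",
]

_TAU_EPS = 1e-12


# ---------------------------------------------------------------------------
# Config and result containers
# ---------------------------------------------------------------------------

@dataclass
class EstimatorConfig:
    """Settings for the LD estimator.

    screening
        ``"none"``, ``"no-singletons"`` (drop loci whose minor allele occurs
        as exactly one copy) or ``"pcrit"`` (drop loci with minor-allele
        frequency below ``pcrit``).
    pcrit
        Frequency threshold in (0, 0.5], used when ``screening="pcrit"``.
    exclude_same_chromosome_pairs
        Omit locus pairs sharing a chromosome label (physically linked
        pairs inflate LD; the alternative is the post-hoc chromosome-number
        correction of the adjustment module).
    confidence
        Jackknife CI level; the mating model is random mating throughout.
    """

    screening: str = "no-singletons"
    pcrit: float | None = None
    exclude_same_chromosome_pairs: bool = False
    confidence: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.screening not in ("none", "no-singletons", "pcrit"):
            raise ValueError(f"unknown screening {self.screening!r}")
        if self.screening == "pcrit":
            if self.pcrit is None or not 0.0 < self.pcrit <= 0.5:
                raise ValueError("pcrit must be in (0, 0.5]")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")


@dataclass
class LDStatistics:
    """Pairwise LD summary underlying an estimate."""

    r2_mean: float
    r2_expected: float
    r2_drift: float
    harmonic_mean_s: float
    n_pairs_used: int
    n_pairs_skipped: int


@dataclass
class RawEstimate:
    """LD-method point estimate with jackknife CI; +inf marks an
    indeterminate estimate or bound (drift LD at or below zero)."""

    point: float
    ci_lower: float
    ci_upper: float
    n_loci_used: int
    n_pairs_used: int
    harmonic_mean_s: float
    stats: LDStatistics | None = None
    config: dict[str, Any] = field(default_factory=dict)
    ci_degenerate: bool = False

    def to_dict(self) -> dict[str, Any]:
        def enc(v: float) -> float | str:
            return "inf" if math.isinf(v) else float(v)

        return {
            "point": enc(self.point),
            "ci_lower": enc(self.ci_lower),
            "ci_upper": enc(self.ci_upper),
            "n_loci_used": self.n_loci_used,
            "n_pairs_used": self.n_pairs_used,
            "harmonic_mean_s": self.harmonic_mean_s,
            "config": self.config,
        }


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def screen_loci(matrix: GenotypeMatrix, config: EstimatorConfig) -> GenotypeMatrix:
    """Apply allele screening prior to estimation."""
    if matrix.n_loci == 0:
        raise EmptyDataError("empty matrix")
    if config.screening == "none":
        return matrix
    mac = matrix.minor_allele_count()
    if config.screening == "no-singletons":
        keep = mac != 1
    else:  # pcrit
        alt, tot = matrix.allele_counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.where(tot > 0, np.minimum(alt, tot - alt) / np.maximum(tot, 1), 0.0)
        keep = maf >= config.pcrit
    if not keep.any():
        raise EmptyDataError("all loci removed by allele screening")
    return matrix.take_loci(np.flatnonzero(keep))


def pair_r2(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Squared composite-disequilibrium correlation for one locus pair.

    Computed over individuals called at both loci.  Returns ``(r2, n)``;
    raises ``ValueError`` if either locus is monomorphic within that subset
    (the pair is then undefined and callers skip it).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    ok = (a != MISSING) & (b != MISSING)
    x = a[ok].astype(np.float64)
    y = b[ok].astype(np.float64)
    n = x.size
    if n < 2:
        raise ValueError("fewer than 2 pairwise-complete individuals")
    px = x.mean() / 2.0
    py = y.mean() / 2.0
    tau_x = px * (1 - px) + (np.mean(x == 2) - px**2)
    tau_y = py * (1 - py) + (np.mean(y == 2) - py**2)
    if tau_x <= _TAU_EPS or tau_y <= _TAU_EPS:
        raise ValueError("monomorphic locus in pairwise-complete subset")
    delta = (n / (n - 1.0)) * ((x * y).sum() / (2.0 * n) - 2.0 * px * py)
    return float(delta**2 / (tau_x * tau_y)), int(n)


def expected_sample_r2(n):
    """Expected r-squared due to finite sampling of ``n`` diploids under
    random mating: ``1/n + 3.19/n^2`` for n >= 30, else
    ``0.0018 + 0.907/n + 4.44/n^2``."""
    n = np.asarray(n, dtype=np.float64)
    large = 1.0 / n + 3.19 / n**2
    small = 0.0018 + 0.907 / n + 4.44 / n**2
    out = np.where(n >= 30, large, small)
    return float(out) if out.ndim == 0 else out


def ne_from_r2drift(r2_drift: float, n: float) -> float:
    """Convert drift LD to an effective-size point estimate.

    Uses the random-mating closed form; coefficients differ between the
    large-sample (n >= 30) and small-sample regimes.  Non-positive drift
    LD signals an indeterminate (infinite) estimate.
    """
    if r2_drift <= 0:
        return math.inf
    if n >= 30:
        disc = max(1.0 / 9.0 - 2.76 * r2_drift, 0.0)
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2_drift)
    disc = max(0.308**2 - 2.08 * r2_drift, 0.0)
    return (0.308 + math.sqrt(disc)) / (2.0 * r2_drift)


# ---------------------------------------------------------------------------
# Vectorised pairwise machinery
# ---------------------------------------------------------------------------

def _pair_arrays(g: np.ndarray, chrom: np.ndarray | None, exclude_same_chrom: bool):
    """Flat upper-triangle arrays of pairwise sufficient statistics.

    Everything the estimator and the jackknife need per locus pair is a sum
    over individuals, so leave-one-out values are rank-1 downdates of these
    arrays.  Returns (index pair, called-mask M, per-individual pieces,
    dict of flat arrays).
    """
    m = (g != MISSING).astype(np.float64)
    x0 = np.where(g == MISSING, 0, g).astype(np.float64)
    hom = ((g == 2)).astype(np.float64)

    N = m.T @ m                      # pairwise-complete n
    SX = x0.T @ m                    # sum of locus-a counts over complete pairs
    HX = hom.T @ m                   # count of alt homozygotes at locus a
    SXY = x0.T @ x0                  # sum of products

    iu = np.triu_indices(g.shape[1], k=1)
    flat = {
        "n": N[iu],
        "sxa": SX[iu],
        "sxb": SX.T[iu],
        "hxa": HX[iu],
        "hxb": HX.T[iu],
        "sxy": SXY[iu],
    }
    if exclude_same_chrom and chrom is not None:
        same = chrom[iu[0]] == chrom[iu[1]]
        flat["pair_mask"] = ~same
    else:
        flat["pair_mask"] = np.ones(iu[0].shape[0], dtype=bool)
    return iu, m, x0, hom, flat


def _r2_from_flat(flat: dict[str, np.ndarray]):
    """Per-pair r-squared, weights and validity from flat sums."""
    n = flat["n"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = flat["sxa"] / (2.0 * n)
        pb = flat["sxb"] / (2.0 * n)
        tau_a = pa * (1.0 - pa) + flat["hxa"] / n - pa**2
        tau_b = pb * (1.0 - pb) + flat["hxb"] / n - pb**2
        delta = (n / (n - 1.0)) * (flat["sxy"] / (2.0 * n) - 2.0 * pa * pb)
        r2 = delta**2 / (tau_a * tau_b)
    valid = (n >= 2) & (tau_a > _TAU_EPS) & (tau_b > _TAU_EPS) & flat["pair_mask"]
    return r2, n, valid


def _ld_statistics(flat: dict[str, np.ndarray]) -> LDStatistics:
    r2, n, valid = _r2_from_flat(flat)
    if not valid.any():
        raise EmptyDataError("no usable locus pairs")
    r2v = r2[valid]
    nv = n[valid]
    w = nv
    r2_mean = float(np.average(r2v, weights=w))
    r2_exp = float(np.average(expected_sample_r2(nv), weights=w))
    hmean_s = float(nv.size / np.sum(1.0 / nv))
    return LDStatistics(
        r2_mean=r2_mean,
        r2_expected=r2_exp,
        r2_drift=r2_mean - r2_exp,
        harmonic_mean_s=hmean_s,
        n_pairs_used=int(valid.sum()),
        n_pairs_skipped=int((~valid).sum()),
    )


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def _prepare(matrix: GenotypeMatrix, config: EstimatorConfig) -> GenotypeMatrix:
    screened = screen_loci(matrix, config)
    # monomorphic loci form no informative pairs; drop them up front
    poly = screened.minor_allele_count() > 0
    if poly.sum() < 2:
        raise EmptyDataError("fewer than 2 polymorphic loci after screening")
    screened = screened.take_loci(np.flatnonzero(poly))
    if screened.n_individuals < 10:
        raise EmptyDataError("fewer than 10 individuals")
    if screened.n_individuals < 30:
        warnings.warn(
            f"only {screened.n_individuals} individuals; LD estimates are "
            "noisy below 30",
            stacklevel=3,
        )
    return screened


def estimate_raw(
    matrix: GenotypeMatrix,
    config: EstimatorConfig | None = None,
    compute_ci: bool = True,
) -> RawEstimate:
    """Full LD-method estimate from one genotype sample.

    Mean pairwise r-squared is weighted by the pairwise-complete sample
    size; the point estimate evaluates the drift LD at the harmonic mean
    sample size across pairs.
    """
    config = config or EstimatorConfig()
    screened = _prepare(matrix, config)
    g = screened.genotypes
    chrom = screened.locus_meta["chrom"].to_numpy()
    iu, m, x0, hom, flat = _pair_arrays(
        g, chrom, config.exclude_same_chromosome_pairs
    )
    st = _ld_statistics(flat)
    point = ne_from_r2drift(st.r2_drift, st.harmonic_mean_s)

    if compute_ci and g.shape[0] >= 3:
        lower, upper, degenerate = _jackknife_from_parts(
            iu, m, x0, hom, flat, st, config.confidence
        )
    else:
        lower, upper, degenerate = point, point, True

    return RawEstimate(
        point=point,
        ci_lower=lower,
        ci_upper=upper,
        n_loci_used=g.shape[1],
        n_pairs_used=st.n_pairs_used,
        harmonic_mean_s=st.harmonic_mean_s,
        stats=st,
        config={
            "screening": config.screening,
            "pcrit": config.pcrit,
            "exclude_same_chromosome_pairs": config.exclude_same_chromosome_pairs,
            "confidence": config.confidence,
        },
        ci_degenerate=degenerate,
    )


def _jackknife_from_parts(iu, m, x0, hom, flat, st: LDStatistics, confidence: float):
    """Delete-one-individual jackknife CI.

    The mean pairwise r-squared is modelled as a scaled chi-square with
    effective degrees of freedom ``df = 2 * mean^2 / var_jackknife``; the
    resulting interval on the mean is shifted by the sampling expectation
    and mapped through the (monotone decreasing) drift-to-Ne transform, so
    the upper size bound is infinite whenever the lower drift bound
    touches zero.
    """
    n_ind = m.shape[0]
    loo = np.empty(n_ind)
    base = {k: v for k, v in flat.items()}
    a, b = iu
    for i in range(n_ind):
        mi, xi, hi = m[i], x0[i], hom[i]
        down = {
            "n": base["n"] - mi[a] * mi[b],
            "sxa": base["sxa"] - xi[a] * mi[b],
            "sxb": base["sxb"] - xi[b] * mi[a],
            "hxa": base["hxa"] - hi[a] * mi[b],
            "hxb": base["hxb"] - hi[b] * mi[a],
            "sxy": base["sxy"] - xi[a] * xi[b],
            "pair_mask": base["pair_mask"],
        }
        r2, n, valid = _r2_from_flat(down)
        loo[i] = np.average(r2[valid], weights=n[valid]) if valid.any() else st.r2_mean

    theta = st.r2_mean
    var_j = (n_ind - 1) / n_ind * np.sum((loo - loo.mean()) ** 2)
    if var_j <= 0 or theta <= 0:
        point = ne_from_r2drift(st.r2_drift, st.harmonic_mean_s)
        return point, point, True
    df = 2.0 * theta**2 / var_j
    alpha = 1.0 - confidence
    lo_r2 = df * theta / stats.chi2.ppf(1.0 - alpha / 2.0, df)
    hi_r2 = df * theta / stats.chi2.ppf(alpha / 2.0, df)
    ne_lower = ne_from_r2drift(hi_r2 - st.r2_expected, st.harmonic_mean_s)
    ne_upper = ne_from_r2drift(lo_r2 - st.r2_expected, st.harmonic_mean_s)
    return ne_lower, ne_upper, False


def jackknife_ci(
    matrix: GenotypeMatrix, config: EstimatorConfig | None = None
) -> tuple[float, float]:
    """Convenience wrapper returning only the CI bounds."""
    est = estimate_raw(matrix, config, compute_ci=True)
    return est.ci_lower, est.ci_upper


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class LDNeEstimator(BaseEstimator):
    """Effective-size estimator from linkage disequilibrium.

    A single-sample estimator: ``fit`` consumes one genotype sample (a
    :class:`~ldne.matrix.GenotypeMatrix`, or a plain ``(n_individuals,
    n_loci)`` array of allele counts with ``-1`` for missing) and exposes
    the estimate through fitted attributes.

    Parameters
    ----------
    screening : {"no-singletons", "none", "pcrit"}, default "no-singletons"
        Rare-allele screening applied before pairwise LD is measured.
    pcrit : float or None
        Minor-allele-frequency threshold for ``screening="pcrit"``.
    exclude_same_chromosome_pairs : bool, default False
        Omit locus pairs on the same chromosome.
    confidence : float, default 0.95
        Level of the jackknife confidence interval.
    compute_ci : bool, default True
        Whether to run the delete-one jackknife (the expensive part).

    Attributes
    ----------
    ne_ : float
        Point estimate (effective number of breeders for a single-cohort
        sample; generational Ne for a mixed-age sample); ``inf`` when the
        drift LD is non-positive.
    ci_ : tuple of float
        Jackknife confidence interval; the upper bound may be ``inf``.
    r2_mean_, r2_expected_, r2_drift_ : float
        Weighted mean pairwise r-squared, its sampling expectation, and
        their difference.
    harmonic_mean_s_ : float
        Harmonic mean pairwise-complete sample size.
    n_loci_used_, n_pairs_used_ : int
    estimate_ : RawEstimate
        The full result object.

    Examples
    --------
    >>> from ldne.simulate import SimulationConfig, simulate_discrete_wf
    >>> mat, truth = simulate_discrete_wf(SimulationConfig(
    ...     n_adults=100, n_loci=200, sample_size=50, seed=1))
    >>> est = LDNeEstimator().fit(mat)
    >>> 30 < est.ne_ < 400
    True
    """

    def __init__(
        self,
        screening: str = "no-singletons",
        pcrit: float | None = None,
        exclude_same_chromosome_pairs: bool = False,
        confidence: float = 0.95,
        compute_ci: bool = True,
    ):
        self.screening = screening
        self.pcrit = pcrit
        self.exclude_same_chromosome_pairs = exclude_same_chromosome_pairs
        self.confidence = confidence
        self.compute_ci = compute_ci

    def _config(self) -> EstimatorConfig:
        return EstimatorConfig(
            screening=self.screening,
            pcrit=self.pcrit,
            exclude_same_chromosome_pairs=self.exclude_same_chromosome_pairs,
            confidence=self.confidence,
        )

    def fit(self, X, y=None) -> "LDNeEstimator":
        """Estimate effective size from one genotype sample."""
        if not isinstance(X, GenotypeMatrix):
            X = _as_matrix(np.asarray(X))
        est = estimate_raw(X, self._config(), compute_ci=self.compute_ci)
        self.estimate_ = est
        self.ne_ = est.point
        self.ci_ = (est.ci_lower, est.ci_upper)
        self.r2_mean_ = est.stats.r2_mean
        self.r2_expected_ = est.stats.r2_expected
        self.r2_drift_ = est.stats.r2_drift
        self.harmonic_mean_s_ = est.harmonic_mean_s
        self.n_loci_used_ = est.n_loci_used
        self.n_pairs_used_ = est.n_pairs_used
        return self


def _as_matrix(g: np.ndarray) -> GenotypeMatrix:
    import pandas as pd

    n, L = g.shape
    locus_meta = pd.DataFrame(
        {"id": [f"L{j}" for j in range(L)], "chrom": ["0"] * L, "pos": np.arange(1, L + 1)}
    )
    indiv_meta = pd.DataFrame(
        {"id": [f"I{i}" for i in range(n)], "population": "pop1", "cohort": "cohort1"}
    )
    return GenotypeMatrix(g, locus_meta, indiv_meta)
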