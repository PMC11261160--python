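"""Forward genotype simulators with pedigree-derived demographic truth.

Two modes emulate the data the estimator is designed for:

* ``discrete_wf`` — a discrete-generation Wright-Fisher population
  (multinomial parent sampling, Mendelian transmission of biallelic loci),
  the clean oracle for parameter-recovery tests: true Ne equals the number
  of adults.
* ``age_structured`` — overlapping generations with a yearly cycle: adults
  of age >= alpha spawn a newborn cohort, a fixed number of recruits enter
  the population, adults survive annually up to a maximum age.  Sampling a
  single newborn cohort mimics a young-of-the-year (YOY) collection; a
  cross-age adult sample mimics a mixed-age collection.

Every breeding cycle records a demographic effective number of breeders
from the realised offspring-number distribution,

    Nb = (k_bar * Np - 2) / (k_bar - 1 + Vk / k_bar)

with Np the number of actual parents and k_bar/Vk the mean and variance of
per-parent gamete contributions.  Individual variation in reproductive
success beyond Poisson is introduced by gamma-distributed fecundity
multipliers (variance-inflation factor ``overdispersion``).

Loci are assigned round-robin to chromosomes.  By default transmission is
free recombination everywhere (``recomb_fraction=0.5``); a smaller fraction
creates physical linkage between adjacent loci on a chromosome, used to
probe the linkage bias the adjustment module corrects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "PopulationState",
    "simulate_discrete_wf",
    "simulate_age_structured",
    "sample_yoy_cohort",
    "sample_mixed_adults",
]


@dataclass
class SimulationConfig:
    """Simulation settings; defaults give a snapper-like age-structured
    population at desk scale (maturity 5 y, longevity 40 y, annual adult
    survival 0.85, 24 chromosomes)."""

    mode: str = "age_structured"
    n_adults: int = 100          # discrete mode: constant population size
    cohort_size: int = 1000      # age mode: newborns produced per year
    recruit_size: int = 30       # age mode: newborns surviving to age 1
    alpha: int = 5               # age at maturity (years)
    max_age: int = 40            # longevity (years)
    survival: float = 0.85       # annual adult survival probability
    overdispersion: float = 1.0  # variance-inflation of offspring number (1 = Poisson-like)
    n_loci: int = 1000
    chromosomes: int = 24
    recomb_fraction: float = 0.5  # 0.5 = unlinked (free recombination)
    freq_range: tuple[float, float] = (0.05, 0.95)
    burn_in: int | None = None   # generations (discrete) / years (age mode)
    n_years: int = 60
    sample_size: int = 50
    missing_rate: float = 0.0
    drop_fixed: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("discrete_wf", "age_structured"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 <= self.survival < 1.0 + 1e-9:
            raise ValueError("survival must be in [0, 1)")
        if self.alpha > self.max_age:
            raise ValueError("alpha must be <= max_age")
        if not 0.0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")


@dataclass
class TruthRecord:
    """Pedigree-derived truth for one breeding cycle (or the whole run)."""

    true_nb: float
    true_ne: float | None
    n_parents: int
    k_mean: float
    k_var: float
    n_fixed_dropped: int = 0

    def __post_init__(self) -> None:
        assert self.true_nb > 0
        assert self.true_nb <= 2 * self.n_parents + 1e-9


def _demographic_nb(parent_ids: np.ndarray) -> tuple[float, int, float, float]:
    """Nb from the realised gamete contributions in ``parent_ids``
    (one entry per gamete, i.e. two per offspring)."""
    ids, k = np.unique(parent_ids, return_counts=True)
    np_ = ids.size
    k_mean = float(k.mean())
    k_var = float(k.var(ddof=0))
    nb = (k_mean * np_ - 2.0) / (k_mean - 1.0 + k_var / k_mean)
    return nb, np_, k_mean, k_var


# ---------------------------------------------------------------------------
# Transmission
# ---------------------------------------------------------------------------

def _chrom_assignment(n_loci: int, chromosomes: int) -> np.ndarray:
    return np.arange(n_loci) % chromosomes


def _gametes(
    h0: np.ndarray,
    h1: np.ndarray,
    parents: np.ndarray,
    chrom: np.ndarray,
    recomb: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per entry of ``parents`` from haplotype arrays h0/h1.

    The transmitted haplotype index follows a Markov chain along each
    chromosome: free at the first locus, switching with probability
    ``recomb`` between loci adjacent in the round-robin order.
    """
    k, L = parents.size, h0.shape[1]
    if recomb >= 0.5:
        pick = rng.integers(0, 2, size=(k, L)).astype(bool)
    else:
        switches = rng.random((k, L)) < recomb
        # first locus of each chromosome starts fresh
        first = np.zeros(L, dtype=bool)
        seen: set[int] = set()
        for j in range(L):
            if chrom[j] not in seen:
                first[j] = True
                seen.add(int(chrom[j]))
        switches[:, first] = rng.integers(0, 2, size=(k, int(first.sum()))).astype(bool)
        # cumulative XOR within chromosome, vectorised per chromosome
        pick = np.zeros((k, L), dtype=bool)
        for c in np.unique(chrom):
            idx = np.flatnonzero(chrom == c)
            acc = np.logical_xor.accumulate(switches[:, idx], axis=1)
            pick[:, idx] = acc
    return np.where(pick, h1[parents], h0[parents])


def _init_haplotypes(
    n: int, cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = cfg.freq_range
    p = rng.uniform(lo, hi, size=cfg.n_loci)
    h0 = (rng.random((n, cfg.n_loci)) < p).astype(np.uint8)
    h1 = (rng.random((n, cfg.n_loci)) < p).astype(np.uint8)
    return h0, h1


def _apply_missing(g: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return g
    mask = rng.random(g.shape) < rate
    out = g.astype(np.int8, copy=True)
    out[mask] = MISSING
    return out


def _to_matrix(
    g: np.ndarray,
    chrom: np.ndarray,
    population: str,
    cohort: str,
    ages: np.ndarray | None = None,
    id_prefix: str = "ind",
) -> GenotypeMatrix:
    n, L = g.shape
    locus_meta = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(L)],
            "chrom": [f"chr{int(c) + 1}" for c in chrom],
            "pos": [j // max(chrom.max() + 1, 1) + 1 for j in range(L)],
        }
    )
    indiv = {
        "id": [f"{id_prefix}{i}" for i in range(n)],
        "population": population,
        "cohort": cohort,
    }
    if ages is not None:
        indiv["age"] = ages
    return GenotypeMatrix(g, locus_meta, pd.DataFrame(indiv))


# ---------------------------------------------------------------------------
# Discrete Wright-Fisher
# ---------------------------------------------------------------------------

def simulate_discrete_wf(cfg: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Non-overlapping-generation Wright-Fisher run.

    After a burn-in of ``burn_in`` generations (default: ``n_adults``), a
    final offspring generation is produced and ``sample_size`` individuals
    are returned.  True Ne is the constant adult count.  Loci fixed during
    burn-in are dropped (counted) unless ``drop_fixed=False``.
    """
    rng = np.random.default_rng(cfg.seed)
    N = cfg.n_adults
    chrom = _chrom_assignment(cfg.n_loci, cfg.chromosomes)
    h0, h1 = _init_haplotypes(N, cfg, rng)
    generations = cfg.burn_in if cfg.burn_in is not None else N
    for _ in range(generations):
        moms = rng.integers(0, N, size=N)
        dads = rng.integers(0, N, size=N)
        new_h0 = _gametes(h0, h1, moms, chrom, cfg.recomb_fraction, rng)
        new_h1 = _gametes(h0, h1, dads, chrom, cfg.recomb_fraction, rng)
        h0, h1 = new_h0, new_h1
    # final breeding event, recorded for truth
    moms = rng.integers(0, N, size=N)
    dads = rng.integers(0, N, size=N)
    off_h0 = _gametes(h0, h1, moms, chrom, cfg.recomb_fraction, rng)
    off_h1 = _gametes(h0, h1, dads, chrom, cfg.recomb_fraction, rng)
    nb, np_, k_mean, k_var = _demographic_nb(np.concatenate([moms, dads]))

    g = (off_h0 + off_h1).astype(np.int8)
    keep = np.ones(cfg.n_loci, dtype=bool)
    n_fixed = 0
    if cfg.drop_fixed:
        freq = g.sum(axis=0) / (2.0 * g.shape[0])
        keep = (freq > 0) & (freq < 1)
        n_fixed = int((~keep).sum())
    if cfg.sample_size > N:
        raise ValueError("sample_size exceeds population size")
    pick = rng.choice(N, size=cfg.sample_size, replace=False)
    sample = _apply_missing(g[np.ix_(pick, np.flatnonzero(keep))], cfg.missing_rate, rng)
    matrix = _to_matrix(sample, chrom[keep], "wf", "offspring", id_prefix="wf")
    truth = TruthRecord(
        true_nb=nb, true_ne=float(N), n_parents=np_, k_mean=k_mean, k_var=k_var,
        n_fixed_dropped=n_fixed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Age-structured population
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    """End state of an age-structured run: the standing population, the
    newest newborn cohort, per-cycle truth records, and the parental
    snapshot needed for pedigree audits."""

    h0: np.ndarray
    h1: np.ndarray
    ages: np.ndarray
    newborn_h0: np.ndarray
    newborn_h1: np.ndarray
    newborn_moms: np.ndarray
    newborn_dads: np.ndarray
    parent_h0: np.ndarray
    parent_h1: np.ndarray
    chrom: np.ndarray
    truth: list[TruthRecord] = field(default_factory=list)
    config: SimulationConfig | None = None

    @property
    def n_adults(self) -> int:
        assert self.config is not None
        return int((self.ages >= self.config.alpha).sum())


class ExtinctionError(RuntimeError):
    pass


def simulate_age_structured(cfg: SimulationConfig) -> PopulationState:
    """Run the yearly cycle for ``n_years`` (default 60) years.

    The population is seeded at its stationary age distribution.  Each
    year: adults (age >= alpha) are assigned gamma fecundity weights when
    ``overdispersion > 1``, the newborn cohort is drawn by weighted parent
    choice, ``recruit_size`` newborns recruit into age 1 next year, adults
    survive with the annual probability, and nobody exceeds ``max_age``.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom = _chrom_assignment(cfg.n_loci, cfg.chromosomes)

    # seed standing population at the stationary age structure
    ages_list: list[int] = []
    for a in range(1, cfg.max_age + 1):
        surv_years = max(a - cfg.alpha, 0)  # survival applies from maturity
        expected = cfg.recruit_size * cfg.survival**surv_years
        ages_list.extend([a] * max(int(round(expected)), 0))
    if not ages_list:
        raise ValueError("degenerate configuration: empty initial population")
    ages = np.array(ages_list)
    h0, h1 = _init_haplotypes(ages.size, cfg, rng)

    years = cfg.burn_in if cfg.burn_in is not None else cfg.n_years
    truth: list[TruthRecord] = []
    newborn = None
    for _ in range(years):
        adult_idx = np.flatnonzero(ages >= cfg.alpha)
        if adult_idx.size < 2:
            raise ExtinctionError("fewer than 2 adults; population collapsed")
        if cfg.overdispersion > 1.0:
            shape = 1.0 / (cfg.overdispersion - 1.0)
            w = rng.gamma(shape, (cfg.overdispersion - 1.0), size=adult_idx.size)
            w = np.maximum(w, 1e-12)
            probs = w / w.sum()
        else:
            probs = None
        moms = rng.choice(adult_idx, size=cfg.cohort_size, p=probs)
        dads = rng.choice(adult_idx, size=cfg.cohort_size, p=probs)
        nb, np_, k_mean, k_var = _demographic_nb(np.concatenate([moms, dads]))
        truth.append(
            TruthRecord(true_nb=nb, true_ne=None, n_parents=np_, k_mean=k_mean, k_var=k_var)
        )
        new_h0 = _gametes(h0, h1, moms, chrom, cfg.recomb_fraction, rng)
        new_h1 = _gametes(h0, h1, dads, chrom, cfg.recomb_fraction, rng)
        newborn = (new_h0, new_h1, moms, dads, h0.copy(), h1.copy())

        # survival and ageing
        survive = np.ones(ages.size, dtype=bool)
        adults = ages >= cfg.alpha
        survive[adults] = rng.random(int(adults.sum())) < cfg.survival
        survive &= ages < cfg.max_age
        h0, h1, ages = h0[survive], h1[survive], ages[survive] + 1

        # recruitment of this year's newborns into age 1
        recruit_n = min(cfg.recruit_size, cfg.cohort_size)
        rec = rng.choice(cfg.cohort_size, size=recruit_n, replace=False)
        h0 = np.vstack([h0, new_h0[rec]])
        h1 = np.vstack([h1, new_h1[rec]])
        ages = np.concatenate([ages, np.ones(recruit_n, dtype=ages.dtype)])

    assert newborn is not None
    new_h0, new_h1, moms, dads, ph0, ph1 = newborn
    return PopulationState(
        h0=h0, h1=h1, ages=ages,
        newborn_h0=new_h0, newborn_h1=new_h1,
        newborn_moms=moms, newborn_dads=dads,
        parent_h0=ph0, parent_h1=ph1,
        chrom=chrom, truth=truth, config=cfg,
    )


def sample_yoy_cohort(state: PopulationState, s: int, seed: int = 0) -> GenotypeMatrix:
    """Sample ``s`` individuals uniformly from the newest newborn cohort."""
    cfg = state.config
    assert cfg is not None
    K = state.newborn_h0.shape[0]
    if s > K:
        raise ValueError(f"sample size {s} exceeds cohort size {K}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(K, size=s, replace=False)
    g = (state.newborn_h0[pick] + state.newborn_h1[pick]).astype(np.int8)
    g = _apply_missing(g, cfg.missing_rate, rng)
    return _to_matrix(
        g, state.chrom, "sim", "YOY", ages=np.zeros(s, dtype=int), id_prefix="yoy"
    )


def sample_mixed_adults(
    state: PopulationState,
    s: int,
    age_range: tuple[int, int] | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Sample ``s`` adults uniformly across age classes in ``age_range``."""
    cfg = state.config
    assert cfg is not None
    lo, hi = age_range if age_range is not None else (cfg.alpha, cfg.max_age)
    idx = np.flatnonzero((state.ages >= lo) & (state.ages <= hi))
    if s > idx.size:
        raise ValueError(f"sample size {s} exceeds {idx.size} adults in range")
    rng = np.random.default_rng(seed)
    pick = rng.choice(idx, size=s, replace=False)
    g = (state.h0[pick] + state.h1[pick]).astype(np.int8)
    g = _apply_missing(g, cfg.missing_rate, rng)
    return _to_matrix(
        g, state.chrom, "sim", "mixed-adult",
        ages=state.ages[pick], id_prefix="adult",
    )


def audit_pedigree(state: PopulationState, max_check: int = 50) -> bool:
    """Verify allele conservation: each newborn gamete matches one of its
    recorded parent's haplotypes at every locus."""
    k = min(max_check, state.newborn_h0.shape[0])
    for i in range(k):
        m = state.newborn_moms[i]
        d = state.newborn_dads[i]
        mg = state.newborn_h0[i]
        dg = state.newborn_h1[i]
        m_ok = (mg == state.parent_h0[m]) | (mg == state.parent_h1[m])
        d_ok = (dg == state.parent_h0[d]) | (dg == state.parent_h1[d])
        if not (m_ok.all() and d_ok.all()):
            return False
    return True
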