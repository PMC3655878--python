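"""Generative model for SNP genotypes and correlated quantitative phenotypes.

One biallelic SNP with allele-A frequency ``p`` is simulated under
Hardy-Weinberg equilibrium, so genotype counts (copies of allele A) follow
Binomial(2, p).  Phenotypes are multivariate with an equicorrelated
covariance structure and a multiplicative genotype effect on the mean:
individuals carrying 0, 1 or 2 copies of allele A have all-trait means
1, delta and delta**2 respectively (delta = 1 is the null of no
association).  Non-normal variants apply a monotone marginal transform to
the multivariate normal draw, which preserves the ordinal genotype effect
and the rank correlation between traits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "FAMILIES",
    "SimulationConfig",
    "GenotypeVector",
    "PhenotypeMatrix",
    "hwe_genotype_probs",
    "simulate_genotypes",
    "genotype_mean",
    "equicorrelation_matrix",
    "simulate_phenotypes",
    "simulate_dataset",
    "add_missingness",
]

FAMILIES = ("normal", "lognormal", "chisq")


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, a Generator, or None."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of one simulation scenario.

    Parameters
    ----------
    allele_freq
        Frequency of allele A, in (0, 1).  0.3 is used throughout the
        reference simulation study.
    n_samples
        Number of individuals n.
    n_phenotypes
        Number of traits m.
    effect_size
        Multiplicative genotype effect delta (> 0); the per-genotype trait
        means are 1, delta, delta**2 for 0/1/2 copies of allele A.
        delta = 1 is the null hypothesis.
    correlation
        Common pairwise trait correlation r.  The equicorrelation matrix is
        positive definite iff r > -1/(m-1).
    family
        Marginal distribution family: "normal", "lognormal" or "chisq".
    n_replicates
        Monte-Carlo replicates R used by the power engine.
    seed
        Root seed; replicate k draws from an independent counter-based
        stream so it is reproducible in isolation.
    """

    allele_freq: float = 0.3
    n_samples: int = 300
    n_phenotypes: int = 10
    effect_size: float = 1.2
    correlation: float = 0.5
    family: str = "normal"
    n_replicates: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise ValueError(f"allele_freq must be in (0, 1), got {self.allele_freq}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be a positive integer")
        if self.n_phenotypes < 1:
            raise ValueError("n_phenotypes must be a positive integer")
        if not self.effect_size > 0:
            raise ValueError("effect_size (delta) must be > 0")
        m = self.n_phenotypes
        if m > 1 and not (-1.0 / (m - 1) < self.correlation < 1.0):
            raise ValueError(
                f"correlation r={self.correlation} outside (-1/(m-1), 1) = "
                f"({-1.0 / (m - 1):.4f}, 1) for m={m}: equicorrelation matrix "
                "not positive definite"
            )
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def null(self) -> "SimulationConfig":
        """The matched null scenario (delta = 1, all else equal)."""
        return self.replace(effect_size=1.0)


@dataclass
class GenotypeVector:
    """Per-sample allele-A counts (0/1/2) for one SNP, with missingness mask."""

    counts: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]
    name: str = "snp"

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1:
            raise ValueError("genotype counts must be one-dimensional")
        if self.missing_mask is None:
            mask = np.zeros(counts.shape, dtype=bool)
        else:
            mask = np.asarray(self.missing_mask, dtype=bool)
            if mask.shape != counts.shape:
                raise ValueError("missing_mask shape does not match counts")
        if np.issubdtype(counts.dtype, np.floating):
            mask = mask | np.isnan(counts)
            counts = np.where(mask, 0, counts)
        counts = counts.astype(np.int64)
        observed = counts[~mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("non-missing genotype counts must be in {0, 1, 2}")
        self.counts = counts
        self.missing_mask = mask

    @property
    def n_samples(self) -> int:
        return self.counts.size

    def observed(self) -> np.ndarray:
        return self.counts[~self.missing_mask]


@dataclass
class PhenotypeMatrix:
    """n samples x m quantitative traits, with missingness mask."""

    values: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]
    trait_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("phenotype values must be a 2-D (samples x traits) array")
        if self.missing_mask is None:
            mask = np.zeros(values.shape, dtype=bool)
        else:
            mask = np.asarray(self.missing_mask, dtype=bool)
            if mask.shape != values.shape:
                raise ValueError("missing_mask shape does not match values")
        mask = mask | np.isnan(values)
        if not self.trait_names:
            self.trait_names = [f"trait{j + 1}" for j in range(values.shape[1])]
        elif len(self.trait_names) != values.shape[1]:
            raise ValueError("trait_names length does not match number of columns")
        self.values = values
        self.missing_mask = mask

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.values.shape[1]

    def complete_rows(self) -> np.ndarray:
        """Boolean mask of rows with every trait observed."""
        return ~self.missing_mask.any(axis=1)


def hwe_genotype_probs(allele_freq: float):
    """Hardy-Weinberg genotype probabilities (fAA, fAB, fBB).

    For allele-A frequency p these are (p^2, 2p(1-p), (1-p)^2); at p = 0.3
    the familiar (0.09, 0.42, 0.49).
    """
    p = float(allele_freq)
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    return p * p, 2.0 * p * (1.0 - p), (1.0 - p) * (1.0 - p)


def simulate_genotypes(n: int, allele_freq: float, seed=None) -> GenotypeVector:
    """Draw n genotypes under HWE: two independent Bernoulli(p) alleles each."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    p = float(allele_freq)
    if not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must be in (0, 1), got {p}")
    rng = _as_rng(seed)
    counts = rng.binomial(2, p, size=n)
    return GenotypeVector(counts)


def genotype_mean(count, effect_size: float):
    """Trait mean for a genotype: 1, delta, delta^2 for 0, 1, 2 copies of A.

    Accepts a scalar count or an array of counts.  delta = 1 collapses to
    the null (all genotype means equal 1).
    """
    delta = float(effect_size)
    if not delta > 0:
        raise ValueError("effect_size (delta) must be > 0")
    counts = np.asarray(count)
    if not np.all(np.isin(counts, (0, 1, 2))):
        raise ValueError("genotype count must be 0, 1 or 2")
    table = np.array([1.0, delta, delta * delta])
    out = table[counts.astype(np.int64)]
    if np.isscalar(count) or out.ndim == 0:
        return float(out)
    return out


def equicorrelation_matrix(m: int, r: float) -> np.ndarray:
    """m x m matrix with unit diagonal and constant off-diagonal r.

    Positive definite iff -1/(m-1) < r < 1 (eigenvalues 1+(m-1)r once and
    1-r with multiplicity m-1).
    """
    if m < 1:
        raise ValueError("m must be a positive integer")
    if m > 1 and not (-1.0 / (m - 1) < r < 1.0):
        raise ValueError(
            f"r={r} outside (-1/(m-1), 1) for m={m}: matrix not positive definite"
        )
    out = np.full((m, m), float(r))
    np.fill_diagonal(out, 1.0)
    return out


def _transform_family(x: np.ndarray, family: str) -> np.ndarray:
    """Monotone marginal map producing the non-normal families."""
    if family == "normal":
        return x
    if family == "lognormal":
        return np.exp(x)
    if family == "chisq":
        u = np.clip(stats.norm.cdf(x), 1e-12, 1.0 - 1e-12)
        return stats.chi2.ppf(u, df=3)
    raise ValueError(f"unknown family {family!r}")


def simulate_phenotypes(g: GenotypeVector, config: SimulationConfig, rng=None) -> PhenotypeMatrix:
    """Draw the n x m phenotype matrix given genotypes.

    Row i is multivariate normal with all-coordinate mean
    ``genotype_mean(g_i, delta)``, unit variances and equicorrelation r;
    for non-normal families the same draw is passed through a monotone
    marginal transform.
    """
    if g.missing_mask.any():
        raise ValueError("simulated genotypes must be complete (no missing values)")
    if g.n_samples != config.n_samples:
        raise ValueError(
            f"genotype length {g.n_samples} != config.n_samples {config.n_samples}"
        )
    rng = _as_rng(rng if rng is not None else config.seed)
    n, m = config.n_samples, config.n_phenotypes
    mu = genotype_mean(g.counts, config.effect_size)
    corr = equicorrelation_matrix(m, config.correlation)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, m))
    values = np.asarray(mu).reshape(-1, 1) + z @ chol.T
    values = _transform_family(values, config.family)
    return PhenotypeMatrix(values)


def replicate_rng(config: SimulationConfig, replicate: int = 0, stream: int = 0) -> np.random.Generator:
    """Independent generator for (stream, replicate) under the root seed.

    Counter-based spawning: each replicate is reproducible in isolation and
    distinct streams (e.g. calibration vs power evaluation) never overlap.
    """
    ss = np.random.SeedSequence(entropy=int(config.seed), spawn_key=(int(stream), int(replicate)))
    return np.random.default_rng(ss)


def simulate_dataset(config: SimulationConfig, replicate: int = 0, stream: int = 0):
    """One replicate of the simulation design: (GenotypeVector, PhenotypeMatrix)."""
    rng = replicate_rng(config, replicate, stream)
    g = simulate_genotypes(config.n_samples, config.allele_freq, seed=rng)
    y = simulate_phenotypes(g, config, rng=rng)
    return g, y


def add_missingness(data, rate: float, seed=None):
    """Return a copy with independent Bernoulli(rate) per-cell missingness.

    Works on either a GenotypeVector or a PhenotypeMatrix; used for fixture
    realism, never by the power engine.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    rng = _as_rng(seed)
    if isinstance(data, GenotypeVector):
        extra = rng.random(data.n_samples) < rate
        return GenotypeVector(data.counts.copy(), data.missing_mask | extra, name=data.name)
    if isinstance(data, PhenotypeMatrix):
        extra = rng.random(data.values.shape) < rate
        return PhenotypeMatrix(data.values.copy(), data.missing_mask | extra,
                               trait_names=list(data.trait_names))
    raise TypeError("expected a GenotypeVector or PhenotypeMatrix")
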