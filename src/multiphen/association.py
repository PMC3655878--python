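"""Four strategies for testing one SNP against multiple correlated traits.

Each strategy maps a (PhenotypeMatrix, GenotypeVector) pair to a single
p-value so that SNPs can be compared on a common scale:

``one_by_one``
    Test every trait separately (1-df regression on allele count, or 2-df
    one-way ANOVA across genotype groups) and Bonferroni-correct the
    smallest p-value.
``permutation``
    Use the same per-trait tests but calibrate the minimum p-value (P_min)
    against its permutation null: phenotype rows are shuffled jointly,
    which breaks the association while preserving trait intercorrelation.
``manova``
    One-way MANOVA of all traits on genotype as a 3-level factor (Pillai's
    trace by default, Wilks' lambda available).
``pca``
    Collapse the standardized traits to their first principal component and
    run the univariate test on the PC1 scores (or a joint 2-response
    multivariate test on the first two PCs).

Missing data: the univariate strategies use the pairwise-complete samples
for each trait; permutation, MANOVA and PCA require complete rows.  The
number of samples actually analyzed is always reported.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .simulate import GenotypeVector, PhenotypeMatrix

__all__ = [
    "AssociationResult",
    "bonferroni_pvalue",
    "single_trait_pvalue",
    "one_by_one_test",
    "permutation_minp_test",
    "manova_test",
    "pc_scores",
    "pca_test",
]

_TINY = np.finfo(float).tiny


@dataclass
class AssociationResult:
    """One method's verdict for one SNP.

    ``statistic`` holds the method's own summary: the minimum per-trait
    p-value (P_min) for the univariate strategies, Pillai/Wilks value for
    MANOVA, the F statistic for the PCA regression.
    """

    method: str
    statistic: float
    p_value: float
    n_used: int
    per_trait_p: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# univariate kernels (complete data, vectorized over trait columns)

def _regression_f_p(y_mat: np.ndarray, g: np.ndarray):
    """1-df slope F-test of each column of y_mat on allele count g.

    Returns (F, p) arrays of length m.  Constant columns get F=0, p=1 by
    convention; a constant genotype is a caller error.
    """
    n = g.size
    if n < 3:
        raise ValueError("need at least 3 samples for the regression test")
    gc = g - g.mean()
    sxx = gc @ gc
    if sxx == 0:
        raise ValueError("monomorphic genotype: fewer than two genotype groups")
    yc = y_mat - y_mat.mean(axis=0)
    syy = np.einsum("ij,ij->j", yc, yc)
    sxy = gc @ yc
    ok = syy > 0
    r2 = np.zeros_like(syy)
    np.divide(sxy * sxy, sxx * syy, out=r2, where=ok)
    r2 = np.clip(r2, 0.0, 1.0)
    df = n - 2
    with np.errstate(over="ignore"):
        f_stat = df * r2 / np.maximum(1.0 - r2, _TINY)
    p = np.where(ok, stats.f.sf(f_stat, 1, df), 1.0)
    f_stat = np.where(ok, f_stat, 0.0)
    return f_stat, p


def _anova_f_p(y_mat: np.ndarray, g: np.ndarray):
    """One-way ANOVA F-test of each column of y_mat across genotype groups."""
    groups = np.unique(g)
    k = groups.size
    n = g.size
    if k < 2:
        raise ValueError("monomorphic genotype: fewer than two genotype groups")
    if n - k < 1:
        raise ValueError("not enough samples for the within-group degrees of freedom")
    grand = y_mat.mean(axis=0)
    ssb = np.zeros(y_mat.shape[1])
    for level in groups:
        sel = g == level
        ng = sel.sum()
        d = y_mat[sel].mean(axis=0) - grand
        ssb += ng * d * d
    sst = np.einsum("ij,ij->j", y_mat - grand, y_mat - grand)
    ssw = np.maximum(sst - ssb, 0.0)
    ok = sst > 0
    with np.errstate(over="ignore"):
        f_stat = (ssb / (k - 1)) / np.maximum(ssw / (n - k), _TINY)
    p = np.where(ok, stats.f.sf(f_stat, k - 1, n - k), 1.0)
    f_stat = np.where(ok, f_stat, 0.0)
    return f_stat, p


def _kernel(mode: str):
    if mode == "regression":
        return _regression_f_p
    if mode == "anova":
        return _anova_f_p
    raise ValueError(f"mode must be 'regression' or 'anova', got {mode!r}")


def single_trait_pvalue(y, g: GenotypeVector, mode: str = "regression") -> float:
    """p-value for one quantitative trait against one SNP.

    ``regression``: 1-df F-test of the slope of y on allele count (additive
    coding).  ``anova``: F-test of genotype-group means (k-1 df for the k
    observed groups).  Samples missing in either y or g are dropped.
    A constant trait returns p = 1 by convention; fewer than two genotype
    groups raise.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != g.n_samples:
        raise ValueError("y must be a length-n vector matching the genotypes")
    keep = ~np.isnan(y) & ~g.missing_mask
    if keep.sum() < 3:
        raise ValueError("need at least 3 samples with both trait and genotype observed")
    _, p = _kernel(mode)(y[keep, None], g.counts[keep])
    return float(p[0])


def bonferroni_pvalue(per_trait_p) -> float:
    """Family-wise corrected p-value min(1, m * min(p)).

    Comparing it to alpha is equivalent to comparing min(p) to alpha/m.
    """
    per_trait_p = np.asarray(per_trait_p, dtype=float)
    return float(min(1.0, per_trait_p.size * per_trait_p.min()))


def one_by_one_test(Y: PhenotypeMatrix, g: GenotypeVector, mode: str = "regression") -> AssociationResult:
    """Per-trait tests with Bonferroni family-wise correction.

    Each trait is tested on its pairwise-complete samples; the reported
    p_value is min(1, m * P_min) so a single number is comparable to alpha.
    """
    if Y.n_samples != g.n_samples:
        raise ValueError("phenotypes and genotypes have different sample counts")
    kern = _kernel(mode)
    m = Y.n_phenotypes
    per_trait = np.empty(m)
    complete = ~Y.missing_mask.any(axis=1) & ~g.missing_mask
    if complete.all():
        _, per_trait = kern(Y.values, g.counts)
    else:
        for j in range(m):
            keep = ~Y.missing_mask[:, j] & ~g.missing_mask
            if keep.sum() < 3:
                raise ValueError(
                    f"trait {Y.trait_names[j]!r}: fewer than 3 samples with "
                    "both trait and genotype observed"
                )
            _, pj = kern(Y.values[keep, j][:, None], g.counts[keep])
            per_trait[j] = pj[0]
    n_used = int((~g.missing_mask & ~Y.missing_mask.all(axis=1)).sum())
    return AssociationResult(
        method="one_by_one",
        statistic=float(per_trait.min()),
        p_value=bonferroni_pvalue(per_trait),
        n_used=n_used,
        per_trait_p=per_trait,
    )


def _complete_case(Y: PhenotypeMatrix, g: GenotypeVector):
    keep = Y.complete_rows() & ~g.missing_mask
    return Y.values[keep], g.counts[keep], int(keep.sum())


def permutation_minp_test(
    Y: PhenotypeMatrix,
    g: GenotypeVector,
    n_perms: int = 1000,
    seed=None,
    mode: str = "regression",
    exhaustive: bool = False,
) -> AssociationResult:
    """Permutation test of the minimum per-trait p-value (P_min).

    Phenotype rows are permuted jointly while genotypes stay in place, so
    the permutation null preserves the correlation among traits.  The
    reported p-value is the proportion of permuted P_min values less than
    or equal to the observed one, using the (1+b)/(1+B) estimator for
    sampled permutations (exact proportion over all n! orderings when
    ``exhaustive``).  Complete-case rows only.
    """
    yk, gk, n_used = _complete_case(Y, g)
    if n_used < 3:
        raise ValueError("need at least 3 complete-case samples")
    kern = _kernel(mode)
    _, obs_p = kern(yk, gk)
    observed = float(obs_p.min())

    if exhaustive:
        if n_used > 8:
            raise ValueError("exhaustive enumeration supported only for n <= 8")
        perms = np.array(list(itertools.permutations(range(n_used))))
    else:
        if n_perms < 100:
            warnings.warn(
                f"n_perms={n_perms} < 100 gives a very coarse permutation p-value",
                UserWarning,
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((n_perms, n_used)), axis=1)

    # Permuting rows of Y jointly is equivalent to permuting g: only the
    # pairing matters, and the trait intercorrelation rides with the rows.
    if mode == "regression":
        pmin_perm = _perm_minp_regression(yk, gk, perms)
    else:
        pmin_perm = np.empty(len(perms))
        for b, perm in enumerate(perms):
            _, p = kern(yk, gk[perm])
            pmin_perm[b] = p.min()

    # inclusive tail, with a hair of tolerance for float noise on exact ties
    hits = int(np.sum(pmin_perm <= observed * (1.0 + 1e-9) + 1e-300))
    if exhaustive:
        p_value = hits / len(perms)
    else:
        p_value = (1.0 + hits) / (len(perms) + 1.0)
    return AssociationResult(
        method="permutation",
        statistic=observed,
        p_value=float(p_value),
        n_used=n_used,
        per_trait_p=obs_p,
    )


def _perm_minp_regression(yk: np.ndarray, gk: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Vectorized permuted P_min for the regression kernel.

    The per-trait p is monotone decreasing in the squared correlation, so
    the minimum p per permutation is the p of the maximum r^2.
    """
    n = gk.size
    gc = gk - gk.mean()
    sxx = gc @ gc
    if sxx == 0:
        raise ValueError("monomorphic genotype: fewer than two genotype groups")
    yc = yk - yk.mean(axis=0)
    syy = np.einsum("ij,ij->j", yc, yc)
    ok = syy > 0
    if not ok.any():
        return np.ones(len(perms))
    gp = gc[perms]                      # (B, n) centered permuted genotypes
    sxy = gp @ yc[:, ok]                # (B, m_ok)
    r2 = sxy * sxy / (sxx * syy[ok])
    r2max = np.clip(r2.max(axis=1), 0.0, 1.0)
    df = n - 2
    with np.errstate(over="ignore"):
        f_stat = df * r2max / np.maximum(1.0 - r2max, _TINY)
    return stats.f.sf(f_stat, 1, df)


# ---------------------------------------------------------------------------
# MANOVA

def _find_collinear(yk: np.ndarray, names) -> str:
    corr = np.corrcoef(yk, rowvar=False)
    worst = ""
    for i in range(corr.shape[0]):
        for j in range(i + 1, corr.shape[1]):
            if abs(corr[i, j]) > 1 - 1e-10:
                worst = f" (traits {names[i]!r} and {names[j]!r} are collinear)"
    return worst


def _manova_f_p(yk: np.ndarray, gk: np.ndarray, statistic: str, names=None):
    """One-way MANOVA from the between (H) and within (E) SSCP matrices."""
    n, p = yk.shape
    groups = np.unique(gk)
    k = groups.size
    if k < 2:
        raise ValueError("monomorphic genotype: fewer than two genotype groups")
    if n <= p + k:
        raise ValueError(f"need n > m + #groups ({p} + {k}) complete cases, have {n}")
    grand = yk.mean(axis=0)
    h_mat = np.zeros((p, p))
    for level in groups:
        sel = gk == level
        d = yk[sel].mean(axis=0) - grand
        h_mat += sel.sum() * np.outer(d, d)
    yc = yk - grand
    total = yc.T @ yc
    e_mat = total - h_mat

    if np.linalg.matrix_rank(e_mat) < p:
        names = names or [f"trait{j + 1}" for j in range(p)]
        raise ValueError(
            "singular residual covariance in MANOVA" + _find_collinear(yk, names)
        )

    q = k - 1                            # hypothesis df
    ve = n - k                           # error df
    if statistic == "pillai":
        value = float(np.trace(np.linalg.solve(h_mat + e_mat, h_mat)))
        s = min(p, q)
        m1 = (abs(p - q) - 1) / 2.0
        n1 = (ve - p - 1) / 2.0
        df1 = s * (2 * m1 + s + 1)
        df2 = s * (2 * n1 + s + 1)
        value = min(value, s * (1 - 1e-15))
        f_stat = (df2 / df1) * value / (s - value)
    elif statistic == "wilks":
        value = float(np.linalg.det(e_mat) / np.linalg.det(h_mat + e_mat))
        value = min(max(value, _TINY), 1.0)
        pq = p * q
        t = 1.0
        if p * p + q * q - 5 > 0:
            t = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
        w = ve + q - (p + q + 1) / 2.0
        df1 = pq
        df2 = w * t - (pq - 2) / 2.0
        lam_t = value ** (1.0 / t)
        f_stat = (1.0 - lam_t) / lam_t * df2 / df1
    else:
        raise ValueError(f"statistic must be 'pillai' or 'wilks', got {statistic!r}")
    if df2 <= 0:
        raise ValueError("not enough error degrees of freedom for the F approximation")
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return value, float(f_stat), p_value


def manova_test(Y: PhenotypeMatrix, g: GenotypeVector, statistic: str = "pillai") -> AssociationResult:
    """One-way MANOVA of all traits on genotype as a categorical factor.

    Pillai's trace (default, robust) or Wilks' lambda; p-values via the
    standard F approximations (Rao's for Wilks, exact when min(m, k-1) <= 2).
    Complete-case rows only.
    """
    yk, gk, n_used = _complete_case(Y, g)
    value, _, p_value = _manova_f_p(yk, gk, statistic, names=Y.trait_names)
    return AssociationResult(
        method="manova", statistic=value, p_value=p_value, n_used=n_used
    )


# ---------------------------------------------------------------------------
# PCA

def pc_scores(Y: PhenotypeMatrix, k: int = 1, standardize: bool = True):
    """Principal components of the traits (complete rows).

    By default traits are column-standardized first (correlation-matrix
    PCA), so PC1 is the variance-maximizing weighted combination with
    weights insensitive to trait units.  Returns (scores n_complete x k,
    loadings m x k, variance_explained length k).  Loadings are
    orthonormal, ordered by decreasing variance, with each column's sign
    fixed so that its loading sum is >= 0.
    """
    rows = Y.complete_rows()
    x = Y.values[rows]
    n, m = x.shape
    if not 1 <= k <= m:
        raise ValueError(f"k must be in 1..m={m}, got {k}")
    if n <= m:
        raise ValueError(f"need more complete rows ({n}) than traits ({m}) for PCA")
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [Y.trait_names[j] for j in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance trait(s): {bad}")
        x = x / sd
    _, svals, vt = np.linalg.svd(x, full_matrices=False)
    eig = svals * svals / (n - 1)
    var_explained = eig / eig.sum()
    loadings = vt[:k].T
    flip = loadings.sum(axis=0) < 0
    loadings[:, flip] *= -1.0
    scores = x @ loadings
    return scores, loadings, var_explained[:k]


def pca_test(
    Y: PhenotypeMatrix,
    g: GenotypeVector,
    k: int = 1,
    mode: str = "regression",
    standardize: bool = True,
) -> AssociationResult:
    """Association test on the leading principal component(s).

    k=1: the univariate test (regression or ANOVA) on the PC1 scores — the
    traits collapsed to one derived phenotype.  k=2: joint 2-response
    multivariate test of genotype on the first two score columns via the
    MANOVA machinery.  Rows must be complete in the traits; among those,
    samples with missing genotype are dropped from the test.
    """
    rows = Y.complete_rows()
    scores, _, _ = pc_scores(Y, k=k, standardize=standardize)
    keep = ~g.missing_mask[rows]
    sk = scores[keep]
    gk = g.counts[rows][keep]
    n_used = int(keep.sum())
    if n_used < 3:
        raise ValueError("need at least 3 samples with complete traits and genotype")
    if k == 1:
        f_stat, p = _kernel(mode)(sk, gk)
        return AssociationResult(
            method="pca", statistic=float(f_stat[0]), p_value=float(p[0]), n_used=n_used
        )
    if k == 2:
        value, _, p_value = _manova_f_p(sk, gk, "pillai", names=["PC1", "PC2"])
        return AssociationResult(
            method="pca", statistic=value, p_value=p_value, n_used=n_used
        )
    raise ValueError(f"k must be 1 or 2, got {k}")
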