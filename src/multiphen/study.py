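"""Candidate-SNP study tables: readers, the four-method ranking workflow,
and synthetic fixture studies.

The expected on-disk layout is two tab-delimited tables sharing a sample-ID
column: genotypes (samples x SNPs, values 0/1/2 or two-letter strings such
as "AC"; "NA" for missing) and phenotypes (samples x quantitative traits;
non-numeric columns are kept as sample metadata for subsetting).  For
string-coded genotypes the counted allele ("allele A") defaults to the
alphabetically first letter observed in the column.

The real candidate-gene dataset this workflow was designed around (a
schizophrenia cognition study: ~51 candidate SNPs, five correlated IQ and
memory scores, heavy genotype missingness) is not public, so
``make_fixture`` builds synthetic studies of the same shape with planted
associated SNPs and a ground-truth sidecar.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import association as assoc
from .power import METHODS, _validate_methods
from .simulate import (
    GenotypeVector,
    PhenotypeMatrix,
    equicorrelation_matrix,
    genotype_mean,
)

__all__ = [
    "CandidateStudy",
    "RankingReport",
    "read_study",
    "rank_snps",
    "make_fixture",
    "write_study",
    "format_top_table",
]

logger = logging.getLogger(__name__)

NA = "NA"


@dataclass
class CandidateStudy:
    """Joined genotype and phenotype tables for a set of candidate SNPs.

    ``genotypes``: samples x SNPs allele-A counts (float, NaN = missing);
    ``phenotypes``: samples x traits (float, NaN = missing); ``metadata``:
    non-numeric phenotype-file columns (e.g. a case/control group label);
    ``allele_a``: the counted allele letter per string-coded SNP.
    """

    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    metadata: pd.DataFrame = None  # type: ignore[assignment]
    allele_a: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.genotypes.index)
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise ValueError("genotype and phenotype tables must share the same samples")
        if not self.genotypes.index.is_unique:
            raise ValueError("sample IDs must be unique")

    @property
    def snps(self) -> List[str]:
        return list(self.genotypes.columns)

    @property
    def traits(self) -> List[str]:
        return list(self.phenotypes.columns)

    def genotype_vector(self, snp: str) -> GenotypeVector:
        col = self.genotypes[snp].to_numpy(dtype=float)
        return GenotypeVector(col, name=snp)

    def phenotype_matrix(self) -> PhenotypeMatrix:
        return PhenotypeMatrix(self.phenotypes.to_numpy(dtype=float),
                               trait_names=self.traits)

    def subset(self, column: str, value) -> "CandidateStudy":
        """Restrict to samples whose metadata ``column`` equals ``value``
        (e.g. patients only)."""
        if column not in self.metadata.columns:
            raise KeyError(f"no metadata column {column!r}; have {list(self.metadata.columns)}")
        keep = self.metadata[column].astype(str) == str(value)
        if not keep.any():
            raise ValueError(f"no samples with {column} == {value!r}")
        return CandidateStudy(
            self.genotypes.loc[keep],
            self.phenotypes.loc[keep],
            self.metadata.loc[keep],
            dict(self.allele_a),
        )


def _parse_genotype_column(series: pd.Series, snp: str):
    """Parse one genotype column to float counts with NaN missing.

    Numeric 0/1/2 pass through; two-letter strings are counted against the
    alphabetically first allele letter in the column.
    """
    raw = series.astype("string")
    isna = raw.isna() | raw.str.strip().str.upper().eq(NA) | raw.str.strip().eq("")
    vals = raw[~isna].str.strip()
    out = pd.Series(np.nan, index=series.index, dtype=float)
    if vals.empty:
        return out, None
    numeric = pd.to_numeric(vals, errors="coerce")
    if numeric.notna().all():
        bad = ~numeric.isin((0, 1, 2))
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"SNP {snp!r}, sample {row!r}: genotype {vals[row]!r} is not 0/1/2"
            )
        out[vals.index] = numeric.astype(float)
        return out, None
    letters = sorted({c for v in vals for c in v})
    bad = ~(vals.str.len().eq(2) & vals.str.isalpha())
    if bad.any() or len(letters) > 2:
        row = bad.idxmax() if bad.any() else vals.index[0]
        raise ValueError(
            f"SNP {snp!r}, sample {row!r}: cannot parse genotype token {series[row]!r}"
        )
    allele_a = letters[0]
    out[vals.index] = vals.str.count(allele_a).astype(float)
    return out, allele_a


def read_study(geno_path, pheno_path, sample_col: Optional[str] = None) -> CandidateStudy:
    """Read and join the genotype and phenotype tables.

    The first column (or ``sample_col``) is the sample ID; tables are
    joined on the intersection of IDs.  Per-SNP missing rates and per-trait
    completeness are logged at INFO level.
    """
    geno_raw = pd.read_csv(geno_path, sep="\t", dtype=str)
    pheno_raw = pd.read_csv(pheno_path, sep="\t", dtype=str)
    for name, frame in (("genotype", geno_raw), ("phenotype", pheno_raw)):
        if frame.shape[1] < 2:
            raise ValueError(f"{name} table needs a sample-ID column plus data columns")
    key_g = sample_col or geno_raw.columns[0]
    key_p = sample_col or pheno_raw.columns[0]
    geno_raw = geno_raw.set_index(key_g)
    pheno_raw = pheno_raw.set_index(key_p)
    common = geno_raw.index.intersection(pheno_raw.index)
    if len(common) == 0:
        raise ValueError("no overlapping sample IDs between genotype and phenotype tables")
    geno_raw = geno_raw.loc[common]
    pheno_raw = pheno_raw.loc[common]

    allele_a: Dict[str, str] = {}
    geno = {}
    for snp in geno_raw.columns:
        parsed, letter = _parse_genotype_column(geno_raw[snp], snp)
        geno[snp] = parsed
        if letter is not None:
            allele_a[snp] = letter
        logger.info("SNP %s: missing rate %.2f", snp, parsed.isna().mean())
    geno = pd.DataFrame(geno, index=geno_raw.index)

    pheno = {}
    meta = {}
    for col in pheno_raw.columns:
        cleaned = pheno_raw[col].astype("string").str.strip()
        cleaned = cleaned.mask(cleaned.str.upper().eq(NA) | cleaned.eq(""))
        numeric = pd.to_numeric(cleaned, errors="coerce")
        if numeric.notna().sum() >= cleaned.notna().sum() and numeric.notna().any():
            pheno[col] = numeric.astype(float)
            logger.info("trait %s: completeness %.2f", col, numeric.notna().mean())
        else:
            meta[col] = pheno_raw[col]
    if not pheno:
        raise ValueError("phenotype table contains no numeric trait columns")
    pheno = pd.DataFrame(pheno, index=pheno_raw.index)
    meta = pd.DataFrame(meta, index=pheno_raw.index)
    return CandidateStudy(geno, pheno, meta, allele_a)


@dataclass
class RankingReport:
    """Per-(SNP, method) association results with per-method rankings."""

    results: pd.DataFrame                  # snp, method, statistic, p_value, n_used
    rankings: Dict[str, List[str]]         # method -> SNPs sorted ascending by p
    top: Dict[str, pd.DataFrame]           # method -> top-k rows
    mean_trait_correlation: float          # r-bar over complete cases
    n_complete: int                        # samples with all traits observed
    top_k: int = 5


def _snp_seed(root_seed: int, snp: str) -> np.random.SeedSequence:
    # keyed by SNP label so results do not depend on column order
    return np.random.SeedSequence(entropy=int(root_seed), spawn_key=(zlib.crc32(snp.encode()),))


def rank_snps(
    study: CandidateStudy,
    methods: Sequence[str] = METHODS,
    mode: str = "regression",
    n_perms: int = 1000,
    seed: int = 0,
    n_pcs: int = 1,
    manova_statistic: str = "pillai",
    top_k: int = 5,
) -> RankingReport:
    """Run every requested method on every SNP and rank by p-value.

    Per-SNP failures (monomorphic SNPs, too few complete cases, ...) are
    logged and reported as NA rows; they never abort the run.  Ties in
    p-value are broken by SNP label.  Also reports the mean pairwise trait
    correlation (r-bar) and the complete-case sample count, the summary
    statistics a study table is usually headed with.
    """
    methods = _validate_methods(methods)
    if not study.snps or not study.traits:
        raise ValueError("study must contain at least one SNP and one trait")
    y = study.phenotype_matrix()
    rows = []
    for snp in study.snps:
        g = study.genotype_vector(snp)
        for method in methods:
            try:
                if method == "one_by_one":
                    res = assoc.one_by_one_test(y, g, mode=mode)
                elif method == "permutation":
                    res = assoc.permutation_minp_test(
                        y, g, n_perms=n_perms, seed=np.random.default_rng(_snp_seed(seed, snp)),
                        mode=mode,
                    )
                elif method == "manova":
                    res = assoc.manova_test(y, g, statistic=manova_statistic)
                else:
                    res = assoc.pca_test(y, g, k=n_pcs, mode=mode)
                rows.append((snp, method, res.statistic, res.p_value, res.n_used))
            except ValueError as err:
                logger.warning("SNP %s, method %s failed: %s", snp, method, err)
                rows.append((snp, method, np.nan, np.nan, 0))
    results = pd.DataFrame(rows, columns=["snp", "method", "statistic", "p_value", "n_used"])

    rankings = {}
    top = {}
    for method in methods:
        sub = results[results.method == method].sort_values(
            ["p_value", "snp"], kind="stable", na_position="last"
        )
        rankings[method] = sub["snp"].tolist()
        top[method] = sub.head(top_k).reset_index(drop=True)

    complete = y.complete_rows()
    n_complete = int(complete.sum())
    corr = np.corrcoef(y.values[complete], rowvar=False)
    if corr.ndim == 2 and corr.shape[0] > 1:
        iu = np.triu_indices_from(corr, k=1)
        rbar = float(np.mean(corr[iu]))
    else:
        rbar = float("nan")
    return RankingReport(results, rankings, top, rbar, n_complete, top_k)


def format_top_table(report: RankingReport) -> str:
    """Human-readable wide table: one row-pair per method, top SNPs and p's."""
    lines = [
        f"mean pairwise trait correlation r-bar = {report.mean_trait_correlation:.2f}; "
        f"complete cases n = {report.n_complete}"
    ]
    for method, frame in report.top.items():
        lines.append(method + "\t" + "\t".join(frame["snp"]))
        lines.append("" + "\t" + "\t".join(f"{p:.3g}" for p in frame["p_value"]))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# synthetic fixtures

_PROFILES = ("schizophrenia_like", "tiny")
_LETTERS = "ACGT"


def _build_fixture(profile: str, seed: int, delta: float, n_planted: int):
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(7,)))
    if profile == "schizophrenia_like":
        n, n_snps, m, r = 456, 51, 5, 0.6
        n_cases = 216
        missing_lo, missing_hi = 0.21, 0.56
        string_coded = True
    elif profile == "tiny":
        n, n_snps, m, r = 20, 2, 2, 0.5
        n_cases = n
        missing_lo = missing_hi = 0.0
        string_coded = False
        n_planted = min(n_planted, 1)
    else:
        raise ValueError(f"profile must be one of {_PROFILES}, got {profile!r}")

    samples = [f"S{i + 1:04d}" for i in range(n)]
    snp_names = [f"snp{j + 1:03d}" for j in range(n_snps)]
    planted = snp_names[:n_planted]

    freqs = rng.uniform(0.1, 0.5, size=n_snps)
    freqs[0] = 0.3  # planted SNP at the canonical allele frequency
    counts = rng.binomial(2, freqs, size=(n, n_snps)).astype(float)

    # phenotypes: equicorrelated traits whose means follow the planted SNPs
    mu = np.ones(n)
    for j, snp in enumerate(snp_names):
        if snp in planted:
            mu = mu * genotype_mean(counts[:, j].astype(int), delta)
    chol = np.linalg.cholesky(equicorrelation_matrix(m, r))
    pheno = mu[:, None] + rng.standard_normal((n, m)) @ chol.T

    missing_rates = rng.uniform(missing_lo, missing_hi, size=n_snps)
    geno_cols = {}
    alleles = {}
    for j, snp in enumerate(snp_names):
        col = counts[:, j].copy()
        col[rng.random(n) < missing_rates[j]] = np.nan
        if string_coded:
            a, b = sorted(rng.choice(list(_LETTERS), size=2, replace=False))
            alleles[snp] = a
            tokens = np.array([a + a, a + b, b + b])  # counts of allele a: 2, 1, 0
            geno_cols[snp] = [
                NA if np.isnan(c) else tokens[2 - int(c)] for c in col
            ]
        else:
            geno_cols[snp] = [NA if np.isnan(c) else str(int(c)) for c in col]
    geno = pd.DataFrame(geno_cols, index=pd.Index(samples, name="sample_id"))

    pheno_frame = pd.DataFrame(
        {f"trait{k + 1}": pheno[:, k] for k in range(m)},
        index=pd.Index(samples, name="sample_id"),
    )
    group = ["case"] * n_cases + ["control"] * (n - n_cases)
    meta = pd.DataFrame({"group": group}, index=pheno_frame.index) if n_cases < n else \
        pd.DataFrame(index=pheno_frame.index)

    truth = {
        "profile": profile,
        "seed": int(seed),
        "delta": float(delta),
        "planted_snps": planted,
        "allele_freqs": {s: round(float(f), 6) for s, f in zip(snp_names, freqs)},
        "n_samples": n,
        "n_traits": m,
        "trait_correlation": r,
        "missing_rates": {s: round(float(mr), 6) for s, mr in zip(snp_names, missing_rates)},
    }
    return geno, pheno_frame, meta, alleles, truth


def make_fixture(
    profile: str = "schizophrenia_like",
    seed: int = 0,
    out_prefix: Optional[str] = None,
    delta: float = 1.3,
    n_planted: int = 1,
):
    """Synthetic candidate-SNP study with planted associated SNPs.

    ``schizophrenia_like``: 456 samples (216 cases + 240 controls), 51
    string-coded SNPs with per-SNP missing rates drawn in [0.21, 0.56],
    5 traits with pairwise correlation 0.6.  ``tiny``: <= 20 samples,
    2 numeric SNPs, 2 traits, no missingness (unit-test scale).

    Returns (CandidateStudy, truth dict); if ``out_prefix`` is given also
    writes ``<prefix>.geno.tsv``, ``<prefix>.pheno.tsv`` and the
    ground-truth sidecar ``<prefix>.truth.json`` (byte-identical for a
    fixed seed).
    """
    geno_str, pheno_frame, meta, alleles, truth = _build_fixture(profile, seed, delta, n_planted)
    if out_prefix is not None:
        geno_str.to_csv(f"{out_prefix}.geno.tsv", sep="\t")
        out = pheno_frame.copy()
        if not meta.empty:
            out = pd.concat([meta, out], axis=1)
        out.to_csv(f"{out_prefix}.pheno.tsv", sep="\t", float_format="%.6g", na_rep=NA)
        with open(f"{out_prefix}.truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
    # in-memory study: parse the string-coded genotypes the same way the
    # reader would, so round-trips are exact
    geno = {}
    for snp in geno_str.columns:
        parsed, _ = _parse_genotype_column(geno_str[snp], snp)
        geno[snp] = parsed
    study = CandidateStudy(pd.DataFrame(geno, index=geno_str.index),
                           pheno_frame, meta, alleles)
    return study, truth


def write_study(study: CandidateStudy, out_prefix: str) -> None:
    """Write a study back to ``<prefix>.geno.tsv`` / ``<prefix>.pheno.tsv``."""
    geno = study.genotypes.copy()
    for col in geno.columns:
        geno[col] = geno[col].map(lambda v: NA if pd.isna(v) else str(int(v)))
    geno.to_csv(f"{out_prefix}.geno.tsv", sep="\t")
    pheno = study.phenotypes.copy()
    if not study.metadata.empty:
        pheno = pd.concat([study.metadata, pheno], axis=1)
    pheno.to_csv(f"{out_prefix}.pheno.tsv", sep="\t", float_format="%.6g", na_rep=NA)
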