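"""Allele-frequency and genotype-phenotype statistics for a small cohort.

Subjects carry a biallelic genotype (0/1/2 copies of the minor allele),
a quantitative anticoagulant phenotype (anti-FXa activity as percent of
a reference plasma pool), and adjustment covariates (age, sex and the
rs2227589 intron-1 genotype). Comparisons follow a dominant model:
carriers (1 or 2 copies) versus non-carriers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError, InsufficientDataError

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["id", "genotype", "antifxa", "age", "sex", "rs2227589"]


@dataclass(frozen=True)
class SummaryGroup:
    """n / mean / sd summary of one genotype group's phenotype."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise InsufficientDataError("summary group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class MafResult:
    maf: float
    n_genotyped: int
    het: int
    hom_minor: int

    @property
    def carriers(self) -> int:
        return self.het + self.hom_minor


@dataclass(frozen=True)
class TTestResult:
    t_pooled: float
    df_pooled: float
    p_pooled: float
    t_welch: float
    df_welch: float
    p_welch: float
    group_carrier: SummaryGroup | None = None
    group_noncarrier: SummaryGroup | None = None


@dataclass(frozen=True)
class AssociationResult:
    """Carrier-status coefficient from a covariate-adjusted linear model."""

    effect: float
    se: float
    p: float
    df: float
    n: int
    covariates: tuple[str, ...]


def read_cohort_tsv(path_or_handle) -> pd.DataFrame:
    """Read a cohort TSV with header id, genotype, antifxa, age, sex, rs2227589."""
    df = pd.read_csv(path_or_handle, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    return df


def maf(cohort: pd.DataFrame) -> MafResult:
    """Minor allele frequency and carrier counts under listwise deletion.

    MAF = (het + 2*hom_minor) / (2 * n_genotyped). The genotype column is
    assumed minor-allele oriented (0/1/2 copies of the minor allele);
    frequencies above 0.5 are reported as-is with a warning so the caller
    can re-orient.
    """
    geno = pd.to_numeric(cohort["genotype"], errors="coerce").dropna()
    if geno.empty:
        raise InsufficientDataError("no non-missing genotypes")
    n = int(geno.size)
    het = int((geno == 1).sum())
    hom = int((geno == 2).sum())
    freq = (het + 2 * hom) / (2 * n)
    if freq > 0.5:
        logger.warning("allele frequency %.3f > 0.5: genotype column is not "
                       "minor-allele oriented", freq)
    return MafResult(maf=freq, n_genotyped=n, het=het, hom_minor=hom)


def hwe_exact(het: int, hom_minor: int, hom_major: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts as or less probable than the observed one
    (the standard exact HWE test used for genotyping QC).
    """
    if min(het, hom_minor, hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = het + hom_minor + hom_major
    if n < 1:
        raise ValueError("at least one genotyped subject required")
    rare = 2 * hom_minor + het
    if rare == 0 or rare == 2 * n:
        return 1.0

    # log-probability of each possible het count with fixed allele counts
    def logprob(h: int) -> float:
        hm = (rare - h) // 2
        hM = n - h - hm
        return (
            h * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hm + 1)
            - math.lgamma(hM + 1)
            + math.lgamma(rare + 1)
            + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )

    h_values = [h for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2)]
    logs = np.array([logprob(h) for h in h_values])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[h_values.index(het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _carrier_split(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    df = cohort[["genotype", "antifxa"]].apply(pd.to_numeric, errors="coerce")
    n_missing = int(df.isna().any(axis=1).sum())
    if n_missing:
        logger.info("excluding %d subjects with missing genotype/phenotype",
                    n_missing)
    df = df.dropna()
    carriers = df.loc[df["genotype"] > 0, "antifxa"].to_numpy(float)
    noncarriers = df.loc[df["genotype"] == 0, "antifxa"].to_numpy(float)
    return carriers, noncarriers


def dominant_ttest(cohort: pd.DataFrame) -> TTestResult:
    """Two-sample t-test of the phenotype, carriers vs non-carriers.

    Returns both the pooled-variance (classical Student) and the Welch
    unequal-variance versions.
    """
    carriers, noncarriers = _carrier_split(cohort)
    if len(carriers) < 2 or len(noncarriers) < 2:
        raise InsufficientDataError(
            f"each genotype group needs n >= 2 (carriers={len(carriers)}, "
            f"non-carriers={len(noncarriers)})"
        )
    pooled = stats.ttest_ind(carriers, noncarriers, equal_var=True)
    welch = stats.ttest_ind(carriers, noncarriers, equal_var=False)
    return TTestResult(
        t_pooled=float(pooled.statistic),
        df_pooled=float(pooled.df),
        p_pooled=float(pooled.pvalue),
        t_welch=float(welch.statistic),
        df_welch=float(welch.df),
        p_welch=float(welch.pvalue),
        group_carrier=SummaryGroup(
            len(carriers), float(carriers.mean()), float(carriers.std(ddof=1))
        ),
        group_noncarrier=SummaryGroup(
            len(noncarriers), float(noncarriers.mean()),
            float(noncarriers.std(ddof=1)),
        ),
    )


def ttest_from_summary(g1: SummaryGroup, g2: SummaryGroup) -> TTestResult:
    """Two-sample t-test from (n, mean, sd) summaries, pooled and Welch."""
    pooled = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=True
    )
    welch = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=False
    )
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    if v1 + v2 > 0:
        df_w = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    else:
        df_w = g1.n + g2.n - 2
    return TTestResult(
        t_pooled=float(pooled.statistic),
        df_pooled=float(g1.n + g2.n - 2),
        p_pooled=float(pooled.pvalue),
        t_welch=float(welch.statistic),
        df_welch=float(df_w),
        p_welch=float(welch.pvalue),
        group_carrier=g1,
        group_noncarrier=g2,
    )


def adjusted_association(
    cohort: pd.DataFrame, covariates: Sequence[str] = ("age", "sex", "rs2227589")
) -> AssociationResult:
    """Least-squares linear model antifxa ~ carrier + covariates.

    ``carrier`` is the dominant-model indicator (genotype > 0). The
    rs2227589 covariate likewise enters as a carrier indicator; ``sex``
    and any other non-numeric covariates are dummy-coded. Returns the
    carrier coefficient, its standard error and two-sided p-value.
    """
    import statsmodels.api as sm

    df = cohort.copy()
    df["genotype"] = pd.to_numeric(df["genotype"], errors="coerce")
    df["antifxa"] = pd.to_numeric(df["antifxa"], errors="coerce")
    df = df.dropna(subset=["genotype", "antifxa"] + list(covariates))
    if df.empty:
        raise InsufficientDataError("no complete cases for the association model")

    X = pd.DataFrame(index=df.index)
    X["carrier"] = (df["genotype"] > 0).astype(float)
    for cov in covariates:
        col = df[cov]
        if cov == "rs2227589":
            X[cov] = (pd.to_numeric(col, errors="coerce") > 0).astype(float)
        elif pd.api.types.is_numeric_dtype(col):
            X[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    X = sm.add_constant(X, has_constant="add")

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        offenders = _collinear_columns(X)
        raise CollinearityError(
            f"design matrix rank deficient; dependent columns: {offenders}",
            columns=offenders,
        )
    fit = sm.OLS(df["antifxa"].astype(float), X).fit()
    return AssociationResult(
        effect=float(fit.params["carrier"]),
        se=float(fit.bse["carrier"]),
        p=float(fit.pvalues["carrier"]),
        df=float(fit.df_resid),
        n=int(len(df)),
        covariates=tuple(c for c in X.columns if c not in ("const", "carrier")),
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Name columns lying in the span of the columns before them."""
    offenders = []
    M = X.to_numpy(float)
    for j in range(1, M.shape[1]):
        prior = M[:, :j]
        col = M[:, j]
        resid = col - prior @ np.linalg.lstsq(prior, col, rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(col)):
            offenders.append(str(X.columns[j]))
    return offenders


def mean_ci(
    n: int, mean: float, sd: float, level: float = 0.95, use_t: bool = False
) -> tuple[float, float]:
    """Confidence interval for a mean from (n, mean, sd).

    Uses the normal quantile by default (z(0.95) = 1.959964...), matching
    how reference-pool intervals are conventionally quoted; set
    ``use_t`` for the t-quantile version.
    """
    if n < 2:
        raise InsufficientDataError("mean_ci needs n >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if use_t:
        q = stats.t.ppf(0.5 + level / 2, df=n - 1)
    else:
        q = stats.norm.ppf(0.5 + level / 2)
    half = q * sd / math.sqrt(n)
    return (mean - half, mean + half)
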