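"""Genotype coding and per-SNP linear regression of expression on genotype.

Each SNP is tested separately by ordinary least squares of the (already
merged) expression phenotype on a numeric genotype coding:

* additive   — count of minor alleles (0/1/2), 1-df Wald t test
* dominant   — carrier indicator (>=1 minor allele), 1-df
* recessive  — homozygous-minor indicator, 1-df
* genotypic  — additive term plus a heterozygote-deviation indicator
  (the ADD + DOMDEV parameterization); significance is the 2-df joint F
  test of both genotype terms, while the reported beta/se belong to the
  additive term.

For 1-df models the Wald statistic is beta/se with p from the t
distribution on n-2 degrees of freedom; the genotypic F uses F(2, n-3).
Missing genotypes are excluded per SNP (complete cases per SNP, never
listwise across the region).  The minor allele, and hence the MAF, is
determined on the analyzed sample set; an exact 50/50 allele-frequency tie
is broken toward the alphabetically first allele so codings are
deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DataError
from .expression_io import MergedPhenotype
from .genotype_io import MISSING_ALLELE, GenotypeDataset

logger = logging.getLogger(__name__)

#: Reported p-value when the fit is perfect (zero residual variance).
P_FLOOR = 1e-300

GENOTYPE_CLASSES = ("homMajor", "het", "homMinor")


class GeneticModel(str, Enum):
    ADDITIVE = "additive"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    GENOTYPIC = "genotypic"

    @property
    def n_columns(self) -> int:
        return 2 if self is GeneticModel.GENOTYPIC else 1


@dataclass
class CodedDesign:
    """Numeric regressor column(s) for one SNP under one genetic model.

    ``columns`` holds one vector (1-df models) or two (genotypic: additive
    then heterozygote indicator), over the non-missing samples listed in
    ``kept_index``.  ``degenerate`` marks monomorphic SNPs (or a genotypic
    design with fewer than three observed genotype classes); such designs
    carry no columns and yield an NA p downstream.
    """

    snp_id: str
    model: GeneticModel
    minor_allele: Optional[str]
    major_allele: Optional[str]
    columns: List[np.ndarray]
    kept_index: np.ndarray
    minor_count: np.ndarray  # per kept sample: 0/1/2 minor alleles
    degenerate: bool = False
    degenerate_reason: Optional[str] = None

    @property
    def n_used(self) -> int:
        return len(self.kept_index)

    @property
    def maf(self) -> float:
        if self.n_used == 0:
            return float("nan")
        return float(self.minor_count.sum()) / (2 * self.n_used)


@dataclass
class FitResult:
    beta: float
    se: float
    statistic: float
    df: Tuple[int, int]
    p: float  # NaN when degenerate


@dataclass
class AssociationResult:
    """Per-SNP, per-probe regression output plus genotype-class summaries."""

    snp_id: str
    chromosome: str
    position_bp: int
    model: GeneticModel
    n_used: int
    minor_allele: Optional[str]
    maf: float
    beta: float
    se: float
    statistic: float
    df: Tuple[int, int]
    p: float
    class_counts: Dict[str, int] = field(default_factory=dict)
    class_means: Dict[str, float] = field(default_factory=dict)
    class_sds: Dict[str, float] = field(default_factory=dict)

    @property
    def is_degenerate(self) -> bool:
        return math.isnan(self.p)


def _minor_major(calls: np.ndarray, kept: np.ndarray, snp_id: str):
    """Determine (minor, major) among non-missing calls; ties break alphabetically."""
    flat = calls[kept].ravel()
    alleles, counts = np.unique(flat, return_counts=True)
    order = {a: c for a, c in zip(alleles.tolist(), counts.tolist())}
    symbols = sorted(order)  # alphabetical
    if len(symbols) > 2:
        raise DataError(f"SNP {snp_id}: more than 2 alleles observed: {symbols}")
    if len(symbols) < 2:
        return None, (symbols[0] if symbols else None)
    a, b = symbols
    if order[a] < order[b]:
        return a, b
    if order[b] < order[a]:
        return b, a
    return a, b  # exact tie: alphabetically first is "minor"


def code_genotypes(calls: np.ndarray, model: GeneticModel, snp_id: str = "?") -> CodedDesign:
    """Code one SNP's allele pairs (shape (n, 2)) under a genetic model.

    Samples with missing calls are excluded via ``kept_index``.  A
    monomorphic SNP returns a degenerate design rather than raising.
    """
    model = GeneticModel(model)
    calls = np.asarray(calls)
    kept = np.nonzero(~(calls == MISSING_ALLELE).all(axis=1))[0]
    if kept.size == 0:
        return CodedDesign(
            snp_id=snp_id, model=model, minor_allele=None, major_allele=None,
            columns=[], kept_index=kept, minor_count=np.empty(0),
            degenerate=True, degenerate_reason="all calls missing",
        )
    minor, major = _minor_major(calls, kept, snp_id)
    if minor is None:
        return CodedDesign(
            snp_id=snp_id, model=model, minor_allele=None, major_allele=major,
            columns=[], kept_index=kept,
            minor_count=np.zeros(kept.size),
            degenerate=True, degenerate_reason="monomorphic",
        )
    add = (calls[kept] == minor).sum(axis=1).astype(float)
    if model is GeneticModel.ADDITIVE:
        cols = [add]
    elif model is GeneticModel.DOMINANT:
        cols = [(add >= 1).astype(float)]
    elif model is GeneticModel.RECESSIVE:
        cols = [(add == 2).astype(float)]
    else:
        het = (add == 1).astype(float)
        if len(np.unique(add)) < 3:
            return CodedDesign(
                snp_id=snp_id, model=model, minor_allele=minor, major_allele=major,
                columns=[], kept_index=kept, minor_count=add,
                degenerate=True,
                degenerate_reason="genotypic model needs 3 genotype classes",
            )
        cols = [add, het]
    design = CodedDesign(
        snp_id=snp_id, model=model, minor_allele=minor, major_allele=major,
        columns=cols, kept_index=kept, minor_count=add,
    )
    # a coding column constant across samples carries no information
    if not design.degenerate and any(np.ptp(c) == 0 for c in cols):
        design.degenerate = True
        design.degenerate_reason = f"constant {model.value} coding"
        design.columns = []
    return design


def fit_wald(design: CodedDesign, phenotype: Sequence[float]) -> FitResult:
    """OLS fit of phenotype on the coded genotype, with Wald t or joint F test.

    ``phenotype`` is aligned with the full sample list the design was coded
    from; the design's ``kept_index`` selects the complete cases.  A perfect
    fit (zero residual variance) reports an infinite statistic and the
    p-value floor rather than dividing by zero.
    """
    nan = float("nan")
    if design.degenerate:
        return FitResult(nan, nan, nan, (0, 0), nan)
    y = np.asarray(phenotype, dtype=float)[design.kept_index]
    n = y.size
    k = len(design.columns)  # genotype regressors
    if n < k + 2:
        logger.warning("SNP %s: n=%d too small for %d-df model", design.snp_id, n, k)
        return FitResult(nan, nan, nan, (k, max(n - k - 1, 0)), nan)

    X = np.column_stack([np.ones(n)] + design.columns)
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        return FitResult(nan, nan, nan, (k, n - k - 1), nan)
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    rss = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    # a perfect fit leaves only floating-point rounding in the residuals
    if rss0 > 0 and rss <= 1e-24 * rss0:
        rss = 0.0
    df_resid = n - k - 1
    sigma2 = rss / df_resid
    beta = float(coef[1])

    if k == 1:
        se = math.sqrt(max(sigma2 * XtX_inv[1, 1], 0.0))
        if se == 0.0:
            logger.info("SNP %s: perfect fit, reporting p floor", design.snp_id)
            return FitResult(beta, 0.0, math.inf * np.sign(beta or 1.0), (1, df_resid), P_FLOOR)
        t = beta / se
        p = 2.0 * stats.t.sf(abs(t), df_resid)
        return FitResult(beta, se, float(t), (1, df_resid), max(float(p), P_FLOOR))

    # genotypic: joint F of ADD + DOMDEV against the intercept-only model
    se = math.sqrt(max(sigma2 * XtX_inv[1, 1], 0.0))
    if sigma2 == 0.0:
        logger.info("SNP %s: perfect fit, reporting p floor", design.snp_id)
        return FitResult(beta, se, math.inf, (2, df_resid), P_FLOOR)
    F = ((rss0 - rss) / 2.0) / sigma2
    p = stats.f.sf(F, 2, df_resid)
    return FitResult(beta, se, float(F), (2, df_resid), max(float(p), P_FLOOR))


def class_summaries(
    calls: np.ndarray, phenotype: Sequence[float], snp_id: str = "?"
) -> Tuple[Dict[str, int], Dict[str, float], Dict[str, float]]:
    """Per-genotype-class counts, phenotype means and sample SDs (n-1).

    Classes are keyed homMajor/het/homMinor relative to the minor allele of
    the analyzed samples.  Empty classes report count 0 and NaN mean/sd; a
    singleton class has NaN sd.
    """
    nan = float("nan")
    design = code_genotypes(calls, GeneticModel.ADDITIVE, snp_id=snp_id)
    counts = {c: 0 for c in GENOTYPE_CLASSES}
    means = {c: nan for c in GENOTYPE_CLASSES}
    sds = {c: nan for c in GENOTYPE_CLASSES}
    if design.kept_index.size == 0:
        return counts, means, sds
    y = np.asarray(phenotype, dtype=float)[design.kept_index]
    by_code = {"homMajor": 0.0, "het": 1.0, "homMinor": 2.0}
    for cls, code in by_code.items():
        vals = y[design.minor_count == code]
        counts[cls] = int(vals.size)
        if vals.size >= 1:
            means[cls] = float(vals.mean())
        if vals.size >= 2:
            sds[cls] = float(vals.std(ddof=1))
    return counts, means, sds


def run_association(
    ds: GenotypeDataset, merged: MergedPhenotype, model: GeneticModel
) -> List[AssociationResult]:
    """Fit every SNP of ``ds`` against the merged phenotype, in map order.

    Missing-genotype exclusion is independent per SNP.  Degenerate SNPs
    produce rows with NaN statistics instead of raising.
    """
    model = GeneticModel(model)
    if ds.sample_ids != list(merged.individual_ids):
        raise DataError("genotype samples and merged phenotype are not aligned")
    y = np.asarray(merged.phenotype, dtype=float)
    out: List[AssociationResult] = []
    for j, snp in enumerate(ds.snps):
        calls = ds.snp_calls(j)
        design = code_genotypes(calls, model, snp_id=snp.snp_id)
        fit = fit_wald(design, y)
        counts, means, sds = class_summaries(calls, y, snp_id=snp.snp_id)
        if design.degenerate:
            logger.info("SNP %s: degenerate (%s)", snp.snp_id, design.degenerate_reason)
        out.append(
            AssociationResult(
                snp_id=snp.snp_id,
                chromosome=snp.chromosome,
                position_bp=snp.position_bp,
                model=model,
                n_used=design.n_used,
                minor_allele=design.minor_allele,
                maf=design.maf,
                beta=fit.beta,
                se=fit.se,
                statistic=fit.statistic,
                df=fit.df,
                p=fit.p,
                class_counts=counts,
                class_means=means,
                class_sds=sds,
            )
        )
    return out
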