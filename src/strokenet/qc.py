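"""Hardy-Weinberg QC and SNP-versus-risk-factor / subtype association scans.

The HWE check is the classical goodness-of-fit chi-square with df=1 against
expected proportions (p^2, 2pq, q^2).  Association scans mirror the genotype
groupings reported for this kind of cohort: a binary coding against a
continuous factor uses the point-biserial correlation test, a three-level
genotypic coding uses one-way ANOVA, and any coding against a binary factor
(smoking, drinking, subtype membership) uses a Pearson chi-square on the
contingency table.  All p-values are reported raw; a Benjamini-Hochberg
post-processor is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_cohort import CodedGenotype, GenotypeMatrix


class DegenerateInputError(ValueError):
    """Raised when a test's inputs carry no usable contrast."""


@dataclass
class HweResult:
    snp_id: str
    n_major_hom: int
    n_het: int
    n_minor_hom: int
    allele_freq: float           # frequency of the allele counted by dosage
    expected: tuple[float, float, float]
    chi2: float
    df: int
    p_value: float
    monomorphic: bool = False


@dataclass
class AssocResult:
    snp_id: str
    coding: str
    factor: str
    test: str
    statistic: float
    p_value: float
    n: int


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, snp_id: str = "") -> HweResult:
    """Goodness-of-fit chi-square test for Hardy-Weinberg equilibrium.

    Counts are (major hom, het, minor hom); the statistic is Pearson's
    chi-square of observed genotype counts against (p^2, 2pq, q^2) * N with
    one degree of freedom (three classes, one estimated allele frequency).
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count: {counts}")
    total = sum(counts)
    if total <= 0:
        raise ValueError("no genotyped subjects")
    q = (2 * n_aa + n_Aa) / (2 * total)   # minor/dosage-counted allele
    p = 1.0 - q
    expected = (p * p * total, 2 * p * q * total, q * q * total)
    if q in (0.0, 1.0):
        return HweResult(snp_id, *counts, q, expected, 0.0, 1, 1.0, monomorphic=True)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return HweResult(snp_id, *counts, q, expected, float(chi2), 1, pval)


def hwe_scan(g: GenotypeMatrix) -> pd.DataFrame:
    """HWE test for every SNP in the matrix; one row per SNP."""
    rows = []
    for snp in g.snp_ids:
        r = hwe_test(*g.genotype_counts(snp), snp_id=snp)
        rows.append({
            "snp_id": snp, "n_major_hom": r.n_major_hom, "n_het": r.n_het,
            "n_minor_hom": r.n_minor_hom, "maf": r.allele_freq,
            "chi2": r.chi2, "p_value": r.p_value, "monomorphic": r.monomorphic,
        })
    return pd.DataFrame(rows)


def _pairwise_complete(*arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        mask &= ~np.isnan(np.asarray(a, dtype=float))
    return tuple(np.asarray(a, dtype=float)[mask] for a in arrays)


def assoc_scan(coded: CodedGenotype, factor: np.ndarray,
               factor_name: str = "factor", factor_binary: bool | None = None) -> AssocResult:
    """Test one coded SNP against one risk factor.

    Binary coding x continuous factor -> point-biserial correlation t-test;
    3-level genotypic coding x continuous factor -> one-way ANOVA F-test;
    any coding x binary factor -> Pearson chi-square on the contingency table.
    Missing values are removed pairwise.
    """
    x, y = _pairwise_complete(coded.values, np.asarray(factor, dtype=float))
    if len(x) == 0:
        raise DegenerateInputError("no complete pairs")
    levels = np.unique(x)
    if len(levels) < 2:
        raise DegenerateInputError(f"{coded.snp_id}: single genotype group present")
    if factor_binary is None:
        factor_binary = set(np.unique(y)) <= {0.0, 1.0}
    if factor_binary:
        table = np.array([[np.sum((x == g) & (y == v)) for v in np.unique(y)]
                          for g in levels])
        if len(np.unique(y)) < 2:
            raise DegenerateInputError(f"{factor_name}: constant factor")
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise DegenerateInputError("contingency table has an empty margin")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return AssocResult(coded.snp_id, coded.coding, factor_name,
                           "pearson_chi2", float(chi2), float(p), len(x))
    if np.ptp(y) == 0:
        raise DegenerateInputError(f"{factor_name}: constant factor")
    if len(levels) == 2:
        r, p = stats.pointbiserialr((x == levels.max()).astype(int), y)
        return AssocResult(coded.snp_id, coded.coding, factor_name,
                           "point_biserial", float(r), float(p), len(x))
    groups = [y[x == g] for g in levels]
    f, p = stats.f_oneway(*groups)
    return AssocResult(coded.snp_id, coded.coding, factor_name,
                       "anova_f", float(f), float(p), len(x))


def subtype_scan(coded: CodedGenotype, subtype_indicator: np.ndarray,
                 subtype_name: str = "subtype", yates: bool = False) -> AssocResult:
    """2x2 Pearson chi-square of a binary genotype contrast vs subtype membership."""
    x, y = _pairwise_complete(coded.values, np.asarray(subtype_indicator, dtype=float))
    levels = np.unique(x)
    if len(levels) != 2:
        raise DegenerateInputError("subtype scan requires exactly two genotype groups")
    table = np.array([[np.sum((x == g) & (y == v)) for v in (0.0, 1.0)] for g in levels])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("contingency table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return AssocResult(coded.snp_id, coded.coding, subtype_name,
                       "pearson_chi2_yates" if yates else "pearson_chi2",
                       float(chi2), float(p), len(x))


def chi2_2x2(table: np.ndarray, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on an arbitrary 2x2 table (helper for subtype contrasts)."""
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateInputError("zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return float(chi2), float(p)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional post-processor)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
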