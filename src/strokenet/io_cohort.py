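"""Cohort I/O: genotype matrices, phenotype tables and genotype codings.

Genotypes are stored as minor-allele dosages (0, 1, 2; NaN for missing) in a
subjects x SNPs matrix.  Phenotypes carry case/control status, the TOAST
stroke subtype for cases, and the quantitative risk factors (BMI, blood
pressures, glucose, lipid panel) plus age/sex/smoking/drinking used as
mediators and association factors downstream.

File dialects: genotypes as plain TSV (subject_id + one column per rsID,
values 0/1/2/NA); phenotypes as CSV with the canonical column names in
:data:`PHENOTYPE_COLUMNS`; a converter accepts VCF (GT field only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Coding = Literal["additive", "dominant", "recessive", "genotypic"]

#: canonical phenotype column order; risk factors use clinical units
#: (BMI kg/m2, BP mmHg, glucose/lipids mmol/L, age years).
PHENOTYPE_COLUMNS = [
    "subject_id", "status", "subtype",
    "BMI", "systolic_BP", "diastolic_BP",
    "Glu", "TC", "TG", "HDL", "LDL",
    "age", "sex", "smoking", "drinking",
]

RISK_FACTORS = ["BMI", "systolic_BP", "diastolic_BP", "Glu", "TC", "TG", "HDL", "LDL"]
SUBTYPES = ["atherothrombosis", "lacunar", "combination"]

# columns that must be strictly positive when present
_POSITIVE_FACTORS = {"BMI", "systolic_BP", "diastolic_BP", "TC", "TG", "HDL", "LDL", "Glu"}


class CohortParseError(ValueError):
    """Malformed cohort input file."""


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix.

    ``dosages`` is a float array so that NaN can encode missing calls;
    every non-missing entry must be 0, 1 or 2.
    """

    subject_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray
    allele_labels: dict[str, tuple[str, str]] | None = None  # snp -> (major, minor)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n != len(self.subject_ids) or p != len(self.snp_ids):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            bad = vals[~np.isin(vals, [0.0, 1.0, 2.0])]
            raise ValueError(f"dosages must be 0/1/2/NA; found {bad[:5]}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        try:
            j = self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None
        return self.dosages[:, j]

    def genotype_counts(self, snp_id: str) -> tuple[int, int, int]:
        """(n_major_hom, n_het, n_minor_hom) for one SNP, missing excluded."""
        col = self.column(snp_id)
        col = col[~np.isnan(col)]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, columns=self.snp_ids)
        df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class PhenotypeTable:
    """Per-subject outcome, TOAST subtype and risk-factor measurements."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise CohortParseError(f"phenotype table missing columns: {missing}")
        if df["status"].isna().any():
            raise CohortParseError("status must be non-missing for every subject")
        bad_status = set(df["status"].unique()) - {"case", "control"}
        if bad_status:
            raise CohortParseError(f"status must be case/control; found {bad_status}")
        ctrl = df["status"] == "control"
        if (df.loc[ctrl, "subtype"].fillna("none") != "none").any():
            raise CohortParseError("controls must have subtype 'none'")
        if (df.loc[~ctrl, "subtype"].fillna("none") == "none").any():
            raise CohortParseError("cases must carry a TOAST subtype")
        for col in _POSITIVE_FACTORS:
            v = pd.to_numeric(df[col], errors="coerce")
            if ((v <= 0) & v.notna()).any():
                raise CohortParseError(f"{col} must be positive where present")

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].astype(str).tolist()

    def status_vector(self) -> np.ndarray:
        """1 = case, 0 = control."""
        return (self.data["status"] == "case").to_numpy(dtype=int)

    def subtype_indicator(self, subtype: str) -> np.ndarray:
        """Case-of-this-subtype = 1 vs everyone else = 0."""
        if subtype not in SUBTYPES:
            raise KeyError(f"unknown subtype {subtype!r}")
        return (self.data["subtype"] == subtype).to_numpy(dtype=int)

    def factor(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"unknown phenotype column {name!r}")
        return pd.to_numeric(self.data[name], errors="coerce").to_numpy(dtype=float)


@dataclass
class CodedGenotype:
    """A single SNP under one of the paper-style genotype groupings.

    additive keeps the 0/1/2 dosage; dominant contrasts minor-allele carriers
    (dosage >= 1) against non-carriers; recessive contrasts minor homozygotes
    against the rest; genotypic keeps three levels for ANOVA-style tests.
    Missing dosages propagate as NaN.
    """

    snp_id: str
    coding: Coding
    values: np.ndarray
    minor_allele: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        ok = self.values[~np.isnan(self.values)]
        allowed = {"additive": (0, 1, 2), "genotypic": (0, 1, 2),
                   "dominant": (0, 1), "recessive": (0, 1)}[self.coding]
        if ok.size and not np.isin(ok, allowed).all():
            raise ValueError(f"{self.coding} coding values must be in {allowed}")

    @property
    def n_levels(self) -> int:
        return len(np.unique(self.values[~np.isnan(self.values)]))


def recode(g: GenotypeMatrix, snp_id: str, coding: Coding) -> CodedGenotype:
    """Recode one SNP's dosages under the requested genotype grouping."""
    if coding not in ("additive", "dominant", "recessive", "genotypic"):
        raise ValueError(f"unknown coding {coding!r}")
    d = g.column(snp_id).astype(float)
    if coding in ("additive", "genotypic"):
        vals = d.copy()
    elif coding == "dominant":
        vals = np.where(np.isnan(d), np.nan, (d >= 1).astype(float))
    else:  # recessive
        vals = np.where(np.isnan(d), np.nan, (d == 2).astype(float))
    minor = None
    if g.allele_labels and snp_id in g.allele_labels:
        minor = g.allele_labels[snp_id][1]
    return CodedGenotype(snp_id=snp_id, coding=coding, values=vals, minor_allele=minor)


# ---------------------------------------------------------------------------
# readers / writers


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Read a genotype TSV (subject_id + one dosage column per rsID)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise CohortParseError(f"{path}: missing 'subject_id' column")
    snp_ids = [c for c in df.columns if c != "subject_id"]
    dosages = np.full((len(df), len(snp_ids)), np.nan)
    for j, snp in enumerate(snp_ids):
        col = pd.to_numeric(df[snp], errors="coerce")
        raw_na = df[snp].isna() | df[snp].astype(str).str.upper().isin(["NA", "NAN", "."])
        bad = col.isna() & ~raw_na
        ok_vals = col.isin([0, 1, 2]) | col.isna()
        if bad.any() or not ok_vals.all():
            line = int(np.nonzero((bad | ~ok_vals).to_numpy())[0][0]) + 2  # 1-based + header
            raise CohortParseError(f"{path}: invalid dosage for {snp} at line {line}")
        dosages[:, j] = col.to_numpy(dtype=float)
    logger.info("read %d subjects x %d SNPs from %s", len(df), len(snp_ids), path)
    return GenotypeMatrix(df["subject_id"].astype(str).tolist(), snp_ids, dosages)


def write_genotypes_tsv(g: GenotypeMatrix, path) -> None:
    df = g.to_dataframe()
    for snp in g.snp_ids:
        df[snp] = df[snp].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes_csv(path) -> PhenotypeTable:
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subtype" in df.columns:
        df["subtype"] = df["subtype"].fillna("none")
    logger.info("read %d phenotype records from %s", len(df), path)
    return PhenotypeTable(df)


def write_phenotypes_csv(p: PhenotypeTable, path) -> None:
    p.data.to_csv(path, index=False)


def load_cohort(genotype_path, phenotype_path) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Load and align genotype + phenotype files on their shared subjects.

    Subjects present in only one file are dropped with a warning; zero
    overlap is fatal.
    """
    g = read_genotypes_tsv(genotype_path)
    p = read_phenotypes_csv(phenotype_path)
    g_ids, p_ids = g.subject_ids, p.subject_ids
    shared = [s for s in g_ids if s in set(p_ids)]
    if not shared:
        raise CohortParseError("no overlapping subjects between genotype and phenotype files")
    dropped = (len(g_ids) - len(shared)) + (len(p_ids) - len(shared))
    if dropped:
        logger.warning("dropping %d subjects present in only one file", dropped)
    gi = [g_ids.index(s) for s in shared]
    g2 = GenotypeMatrix(shared, g.snp_ids, g.dosages[gi, :], g.allele_labels)
    pdf = p.data.set_index("subject_id").loc[shared].reset_index()
    return g2, PhenotypeTable(pdf)


def genotypes_from_vcf(path) -> GenotypeMatrix:
    """Convert the GT field of a VCF into a minor-allele dosage matrix.

    ALT-allele dosages are re-oriented so that 2 always counts the minor
    allele as observed in this dataset (ties broken lexicographically by
    allele string).
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    alleles: dict[str, tuple[str, str]] = {}
    for rec in vf:
        sid = rec.id or f"{rec.chrom}:{rec.pos}"
        dos = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            dos[i] = sum(1 for a in gt if a == 1)
        ref, alt = rec.ref, rec.alts[0] if rec.alts else "."
        ok = dos[~np.isnan(dos)]
        alt_freq = ok.sum() / (2 * ok.size) if ok.size else 0.0
        flip = alt_freq > 0.5 or (alt_freq == 0.5 and alt > ref)
        if flip:
            dos = np.where(np.isnan(dos), np.nan, 2 - dos)
            alleles[sid] = (alt, ref)
        else:
            alleles[sid] = (ref, alt)
        snp_ids.append(sid)
        rows.append(dos)
    dosages = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    logger.info("converted %d variants for %d samples from %s", len(snp_ids), len(samples), path)
    return GenotypeMatrix(samples, snp_ids, dosages, alleles)
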