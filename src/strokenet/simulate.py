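"""Synthetic cohorts, epistatic penetrance data and miRNA target maps.

Every generator is a pure function of its spec plus the mandatory seed; one
master seed is expanded deterministically per sub-generator so streams are
independent and reproducible.  The generators emulate exactly the structure
the downstream analyses assume:

* genotypes drawn under Hardy-Weinberg equilibrium at stated MAFs,
  independent across SNPs and subjects;
* risk-factor mediators linearly driven by a coded genotype with Gaussian
  noise; binary outcomes from a logistic model with direct (c') and
  mediated (a, b) paths; case-control counts hit exactly by rejection
  (retrospective) sampling;
* k-locus epistatic penetrance tables (including pure-epistasis XOR
  checkerboards with flat marginal penetrance);
* random bipartite miRNA-gene maps with optional planted shared-miRNA
  competing modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cerna import TargetMap
from .io_cohort import (PHENOTYPE_COLUMNS, RISK_FACTORS, SUBTYPES,
                        GenotypeMatrix, PhenotypeTable)

#: plausible adult cohort baselines: (mean, SD) in clinical units
FACTOR_BASELINES: dict[str, tuple[float, float]] = {
    "BMI": (24.5, 3.2),          # kg/m2
    "systolic_BP": (135.0, 18.0),  # mmHg
    "diastolic_BP": (82.0, 10.0),  # mmHg
    "Glu": (5.6, 1.2),           # mmol/L
    "TC": (4.8, 1.0),            # mmol/L
    "TG": (1.6, 0.7),            # mmol/L
    "HDL": (1.3, 0.3),           # mmol/L
    "LDL": (2.9, 0.8),           # mmol/L
}

_SUBTYPE_PROBS = (0.45, 0.35, 0.20)  # atherothrombosis, lacunar, combination

#: default 14-SNP MAF panel for a synthetic stand-in cohort
DEFAULT_MAFS = [0.35, 0.28, 0.42, 0.31, 0.22, 0.38, 0.26, 0.45,
                0.33, 0.29, 0.24, 0.40, 0.36, 0.30]


class SimulationError(RuntimeError):
    pass


@dataclass
class PlantedPathway:
    """One genotype -> mediator -> outcome pathway.

    a   : mediator units added per unit of the coded treatment
    b   : outcome log-odds per unit of mediator deviation from its baseline mean
    c_prime : direct outcome log-odds per unit of coded treatment
    """

    snp: str
    mediator: str
    a: float = 0.0
    b: float = 0.0
    c_prime: float = 0.0
    coding: str = "dominant"


@dataclass
class PenetranceModel:
    """k-locus penetrance table: P(case) per multilocus genotype cell."""

    snps: list[str]
    table: np.ndarray   # shape (3,) * k

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        k = len(self.snps)
        if self.table.shape != (3,) * k:
            raise ValueError(f"penetrance table must have shape {(3,) * k}")
        if np.isnan(self.table).any():
            raise ValueError("penetrance table is missing a cell")
        if ((self.table < 0) | (self.table > 1)).any():
            raise ValueError("penetrance values must lie in [0, 1]")


def xor_penetrance(snps: list[str], low: float = 0.3, high: float = 0.7) -> PenetranceModel:
    """Two-locus checkerboard with flat marginal penetrance at MAF 0.5.

    P(case) = high when the dosage sum is odd, low when even; each SNP's
    marginal penetrance is (low + high) / 2 for every genotype, so the
    interaction is pure epistasis with no main effects.
    """
    if len(snps) != 2:
        raise ValueError("XOR checkerboard is a two-locus pattern")
    g = np.add.outer(np.arange(3), np.arange(3))
    table = np.where(g % 2 == 1, high, low).astype(float)
    return PenetranceModel(list(snps), table)


@dataclass
class CohortSimSpec:
    """Study conditions for the synthetic case-control cohort."""

    seed: int
    n_case: int = 507
    n_control: int = 503
    mafs: list[float] = field(default_factory=lambda: list(DEFAULT_MAFS))
    snp_ids: list[str] | None = None
    pathways: list[PlantedPathway] = field(default_factory=list)
    mediator_sd: float | None = None      # None -> each factor's natural SD
    baseline_logit: float = -0.6          # ~35% sampling prevalence
    penetrance: PenetranceModel | None = None
    subtype_probs: tuple[float, float, float] = _SUBTYPE_PROBS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(not 0 < m <= 0.5 for m in self.mafs):
            raise ValueError("MAFs must lie in (0, 0.5]")
        if self.snp_ids is None:
            self.snp_ids = [f"rs{9000000 + i}" for i in range(len(self.mafs))]
        if len(self.snp_ids) != len(self.mafs):
            raise ValueError("snp_ids and mafs must have equal length")
        for pw in self.pathways:
            if pw.snp not in self.snp_ids:
                raise ValueError(f"pathway SNP {pw.snp} not among snp_ids")
            if pw.mediator not in RISK_FACTORS:
                raise ValueError(f"pathway mediator {pw.mediator} is not a risk factor")
        if self.penetrance is not None:
            for s in self.penetrance.snps:
                if s not in self.snp_ids:
                    raise ValueError(f"penetrance SNP {s} not among snp_ids")

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


@dataclass
class TargetMapSimSpec:
    """Conditions for the random bipartite miRNA -> gene map."""

    seed: int
    m: int = 100                   # miRNAs
    n_genes: int = 200
    target_count_range: tuple[int, int] = (3, 15)   # per-gene t, uniform
    modules: list[tuple[list[str], int]] = field(default_factory=list)
    with_energy: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.target_count_range
        if not 1 <= lo <= hi <= self.m:
            raise ValueError("target counts must satisfy 1 <= lo <= hi <= m")
        gene_names = set(self.gene_names)
        for genes, shared in self.modules:
            if shared > self.m:
                raise ValueError("module shared-miRNA count exceeds m")
            if not set(genes) <= gene_names:
                raise ValueError("module genes must be among the simulated genes")

    @property
    def gene_names(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(self.n_genes)]


# ---------------------------------------------------------------------------
# seed plumbing

_STREAMS = {"genotypes": 0, "cohort": 1, "epistasis": 2, "targets": 3, "misc": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# generators


def _draw_dosages(rng: np.random.Generator, mafs: list[float], n: int) -> np.ndarray:
    out = np.empty((n, len(mafs)), dtype=float)
    for j, q in enumerate(mafs):
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
        out[:, j] = rng.choice(3, size=n, p=probs)
    return out


def simulate_genotypes(spec: CohortSimSpec, n_subjects: int | None = None) -> GenotypeMatrix:
    """Independent HWE genotypes at the spec's MAFs."""
    n = n_subjects if n_subjects is not None else spec.n_total
    rng = _rng(spec.seed, "genotypes")
    dosages = _draw_dosages(rng, spec.mafs, n)
    ids = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(ids, list(spec.snp_ids), dosages)


def _coded_treatment(dosage: np.ndarray, coding: str) -> np.ndarray:
    if coding == "dominant":
        return (dosage >= 1).astype(float)
    if coding == "recessive":
        return (dosage == 2).astype(float)
    if coding == "additive":
        return dosage.astype(float)
    raise ValueError(f"unknown coding {coding!r}")


def simulate_cohort(spec: CohortSimSpec, max_batches: int = 200,
                    ) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Retrospective case-control cohort with planted mediation pathways.

    Subjects are simulated prospectively (genotype -> mediators -> logistic
    outcome) and rejection-sampled until exactly n_case cases and n_control
    controls are collected, matching a case-control study design.
    Risk factors not on a planted pathway are independent draws from their
    clinical baselines.
    """
    rng = _rng(spec.seed, "cohort")
    batch = max(4 * spec.n_total, 500)
    kept_dos: list[np.ndarray] = []
    kept_fac: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    n_case = n_control = 0
    pathway_by_factor: dict[str, list[PlantedPathway]] = {}
    for pw in spec.pathways:
        pathway_by_factor.setdefault(pw.mediator, []).append(pw)

    snp_idx = {s: j for j, s in enumerate(spec.snp_ids)}
    for _ in range(max_batches):
        dos = _draw_dosages(rng, spec.mafs, batch)
        factors = np.empty((batch, len(RISK_FACTORS)))
        logit = np.full(batch, spec.baseline_logit)
        for fi, fac in enumerate(RISK_FACTORS):
            mean, nat_sd = FACTOR_BASELINES[fac]
            sd = spec.mediator_sd if (spec.mediator_sd is not None
                                      and fac in pathway_by_factor) else nat_sd
            m = mean + sd * rng.standard_normal(batch)
            for pw in pathway_by_factor.get(fac, []):
                t = _coded_treatment(dos[:, snp_idx[pw.snp]], pw.coding)
                m = m + pw.a * t
                logit = logit + pw.c_prime * t
            factors[:, fi] = m
            for pw in pathway_by_factor.get(fac, []):
                logit = logit + pw.b * (m - mean)
        if spec.penetrance is not None:
            cells = tuple(dos[:, snp_idx[s]].astype(int) for s in spec.penetrance.snps)
            prob = spec.penetrance.table[cells]
        else:
            prob = 1.0 / (1.0 + np.exp(-logit))
        status = (rng.random(batch) < prob).astype(int)
        need_case = spec.n_case - n_case
        need_control = spec.n_control - n_control
        take_case = np.flatnonzero(status == 1)[:need_case]
        take_control = np.flatnonzero(status == 0)[:need_control]
        take = np.sort(np.concatenate([take_case, take_control]))
        kept_dos.append(dos[take])
        kept_fac.append(factors[take])
        kept_status.append(status[take])
        n_case += len(take_case)
        n_control += len(take_control)
        if n_case >= spec.n_case and n_control >= spec.n_control:
            break
    else:
        raise SimulationError(
            f"could not reach {spec.n_case}/{spec.n_control} cases/controls in "
            f"{max_batches} batches; outcome probabilities may be degenerate")

    dosages = np.vstack(kept_dos)
    factors = np.vstack(kept_fac)
    status = np.concatenate(kept_status)
    n = len(status)
    ids = [f"S{i:05d}" for i in range(n)]
    g = GenotypeMatrix(ids, list(spec.snp_ids), dosages)

    subtype = np.where(status == 1,
                       rng.choice(SUBTYPES, size=n, p=spec.subtype_probs), "none")
    df = pd.DataFrame({"subject_id": ids,
                       "status": np.where(status == 1, "case", "control"),
                       "subtype": subtype})
    for fi, fac in enumerate(RISK_FACTORS):
        df[fac] = np.clip(factors[:, fi], 0.05, None)
    df["age"] = np.clip(62 + 10 * rng.standard_normal(n), 25, 95).round(1)
    df["sex"] = rng.integers(0, 2, size=n)
    df["smoking"] = (rng.random(n) < 0.30).astype(int)
    df["drinking"] = (rng.random(n) < 0.25).astype(int)
    return g, PhenotypeTable(df[PHENOTYPE_COLUMNS])


def simulate_epistasis(spec: CohortSimSpec, n_subjects: int | None = None,
                       ) -> tuple[GenotypeMatrix, np.ndarray]:
    """HWE genotypes with case status drawn from a k-locus penetrance table.

    Planted SNPs follow the table; all other SNPs are null decoys.  Status
    is a prospective Bernoulli draw from the per-cell penetrance, so a flat
    table yields a null dataset and a checkerboard yields pure epistasis.
    """
    if spec.penetrance is None:
        raise ValueError("spec.penetrance is required for simulate_epistasis")
    n = n_subjects if n_subjects is not None else spec.n_total
    rng = _rng(spec.seed, "epistasis")
    dosages = _draw_dosages(rng, spec.mafs, n)
    snp_idx = {s: j for j, s in enumerate(spec.snp_ids)}
    cells = tuple(dosages[:, snp_idx[s]].astype(int) for s in spec.penetrance.snps)
    prob = spec.penetrance.table[cells]
    status = (rng.random(n) < prob).astype(int)
    ids = [f"S{i:05d}" for i in range(n)]
    return GenotypeMatrix(ids, list(spec.snp_ids), dosages), status


def simulate_target_map(spec: TargetMapSimSpec) -> TargetMap:
    """Random bipartite miRNA -> gene map with optional planted modules.

    Null genes draw their miRNA targets uniformly at random; each planted
    module's genes all share the module's dedicated miRNAs (plus random
    extras up to their drawn target count).
    """
    rng = _rng(spec.seed, "targets")
    mirnas = [f"miR-{i:03d}" for i in range(spec.m)]
    lo, hi = spec.target_count_range
    module_of: dict[str, frozenset[str]] = {}
    used = 0
    for genes, shared in spec.modules:
        chosen = frozenset(mirnas[used:used + shared])
        if len(chosen) < shared:
            raise SimulationError("not enough miRNAs to give modules disjoint cores")
        used += shared
        for gene in genes:
            module_of[gene] = chosen
    rows: list[tuple[str, str]] = []
    for gene in spec.gene_names:
        t = int(rng.integers(lo, hi + 1))
        core = module_of.get(gene, frozenset())
        t = max(t, len(core))
        pool = [mi for mi in mirnas if mi not in core]
        extra = rng.choice(len(pool), size=t - len(core), replace=False)
        targets = sorted(core) + [pool[i] for i in extra]
        rows.extend((mi, gene) for mi in targets)
    df = pd.DataFrame(rows, columns=["miRNA", "gene"])
    if spec.with_energy:
        df["energy"] = np.round(rng.uniform(-34.0, -21.0, size=len(df)), 2)
    return TargetMap(df)
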