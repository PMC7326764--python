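"""End-to-end pipeline: QC -> association -> mediation -> MDR -> network -> ORA.

One YAML config drives the whole analysis; every stage writes a TSV, every
number any stage produces is collected into a machine-readable
``summary.json`` (deterministic given config + seed), and ``run.log``
records seeds, exclusion counts and package versions.
"""

from __future__ import annotations

import itertools
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator

from . import __version__
from .cerna import build_network, centralities, load_target_map, ora, powerlaw_fit, read_gmt
from .io_cohort import RISK_FACTORS, SUBTYPES, load_cohort, recode
from .mdr import entropy_graph, mdr_permutation_test, mdr_search
from .mediation import mediation_scan
from .qc import DegenerateInputError, assoc_scan, hwe_scan, subtype_scan

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """All config validation problems, reported together."""


class PipelineConfig(BaseModel):
    """Validated pipeline configuration (YAML-backed)."""

    genotypes: str
    phenotypes: str
    out_dir: str
    seed: int
    targets: Optional[str] = None       # miRNA target TSV
    gene_sets: Optional[str] = None     # GMT
    seed_genes: Optional[list[str]] = None
    subtype: str = "all"                # all | atherothrombosis | lacunar | combination
    codings: list[str] = Field(default_factory=lambda: ["dominant", "genotypic"])
    mediators: list[str] = Field(default_factory=lambda: list(RISK_FACTORS))
    mediation_nsim: int = 1000
    mdr_k_min: int = 1
    mdr_k_max: int = 3
    mdr_folds: int = 10
    mdr_permutations: int = 0           # 0 disables the substitution test
    hwe_alpha: float = 0.05
    edge_alpha: float = 0.05
    ora_alpha: float = 0.05
    energy_cutoff: float = -20.0

    @field_validator("hwe_alpha", "edge_alpha", "ora_alpha")
    @classmethod
    def _alpha_open_unit(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("alpha must lie in (0, 1)")
        return v

    @field_validator("subtype")
    @classmethod
    def _subtype_known(cls, v: str) -> str:
        if v not in ["all"] + SUBTYPES:
            raise ValueError(f"subtype must be 'all' or one of {SUBTYPES}")
        return v


def load_config(path) -> PipelineConfig:
    """Load + validate a YAML config; all problems are reported together."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems: list[str] = []
    try:
        cfg = PipelineConfig(**raw)
    except ValidationError as exc:
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"]) or "(root)"
            problems.append(f"{loc}: {err['msg']}")
        raise PipelineConfigError("invalid pipeline config:\n  " + "\n  ".join(problems))
    for name in ("genotypes", "phenotypes", "targets", "gene_sets"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name}: file not found: {p}")
    if problems:
        raise PipelineConfigError("invalid pipeline config:\n  " + "\n  ".join(problems))
    return cfg


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage in order; returns the summary dict.

    Writes per-stage TSVs, ``summary.json`` and ``run.log`` to
    ``cfg.out_dir``.  Any stage failure halts with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("strokenet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"config": json.loads(cfg.model_dump_json()), "version": __version__}
    stage = "load"
    try:
        logger.info("strokenet %s, seed %d", __version__, cfg.seed)
        g, pheno = load_cohort(cfg.genotypes, cfg.phenotypes)
        status = (pheno.status_vector() if cfg.subtype == "all"
                  else pheno.subtype_indicator(cfg.subtype))
        summary["cohort"] = {"n_subjects": g.n_subjects, "n_snps": g.n_snps,
                             "n_case": int(status.sum()),
                             "n_control": int(len(status) - status.sum())}

        stage = "hwe"
        hwe = hwe_scan(g)
        hwe.to_csv(out / "hwe.tsv", sep="\t", index=False)
        summary["hwe"] = hwe.to_dict(orient="records")

        stage = "association"
        rows = []
        binary_factors = ["smoking", "drinking", "sex"]
        for snp, coding in itertools.product(g.snp_ids, cfg.codings):
            coded = recode(g, snp, coding)
            for fac in cfg.mediators + ["age"]:
                try:
                    r = assoc_scan(coded, pheno.factor(fac), factor_name=fac)
                    rows.append(vars(r))
                except DegenerateInputError as exc:
                    rows.append({"snp_id": snp, "coding": coding, "factor": fac,
                                 "test": "skipped", "statistic": np.nan,
                                 "p_value": np.nan, "n": 0, "note": str(exc)})
            for fac in binary_factors:
                try:
                    r = assoc_scan(coded, pheno.factor(fac), factor_name=fac,
                                   factor_binary=True)
                    rows.append(vars(r))
                except DegenerateInputError as exc:
                    rows.append({"snp_id": snp, "coding": coding, "factor": fac,
                                 "test": "skipped", "statistic": np.nan,
                                 "p_value": np.nan, "n": 0, "note": str(exc)})
        if cfg.subtype == "all":
            for snp in g.snp_ids:
                coded = recode(g, snp, "dominant")
                for st in SUBTYPES:
                    try:
                        r = subtype_scan(coded, pheno.subtype_indicator(st),
                                         subtype_name=st)
                        rows.append(vars(r))
                    except DegenerateInputError as exc:
                        rows.append({"snp_id": snp, "coding": "dominant", "factor": st,
                                     "test": "skipped", "statistic": np.nan,
                                     "p_value": np.nan, "n": 0, "note": str(exc)})
        assoc = pd.DataFrame(rows)
        assoc.to_csv(out / "assoc.tsv", sep="\t", index=False)
        summary["association"] = assoc.to_dict(orient="records")

        stage = "mediation"
        outcomes = ["IS"] if cfg.subtype == "all" else [cfg.subtype]
        med = mediation_scan(g, pheno, g.snp_ids, cfg.mediators, outcomes,
                             nsim=cfg.mediation_nsim, seed=cfg.seed)
        med.to_csv(out / "mediation.tsv", sep="\t", index=False)
        summary["mediation"] = med.to_dict(orient="records")

        stage = "mdr"
        models = mdr_search(g, status, k_min=cfg.mdr_k_min, k_max=cfg.mdr_k_max,
                            n_folds=cfg.mdr_folds, seed=cfg.seed)
        mdr_rows = []
        for m in models:
            row = {"attributes": ",".join(m.attributes), "k": len(m.attributes),
                   "training_accuracy": m.training_accuracy,
                   "testing_accuracy": m.testing_accuracy, "cvc": m.cvc,
                   "odds_ratio": m.odds_ratio, "or_lo": m.or_ci[0],
                   "or_hi": m.or_ci[1], "chi2_p": m.chi2_p}
            if cfg.mdr_permutations:
                row["permutation_p"] = mdr_permutation_test(
                    g, status, m, n_perm=cfg.mdr_permutations, seed=cfg.seed,
                    n_folds=cfg.mdr_folds)
            mdr_rows.append(row)
        mdr_df = pd.DataFrame(mdr_rows)
        mdr_df.to_csv(out / "mdr_models.tsv", sep="\t", index=False)
        summary["mdr"] = mdr_df.to_dict(orient="records")

        stage = "entropy"
        eg = entropy_graph(g, status)
        edges = pd.DataFrame(
            [{"snp_a": a, "snp_b": b, "gain_bits": v,
              "gain_pct": eg.pairwise_gain_pct[(a, b)]}
             for (a, b), v in eg.pairwise_gain.items()])
        edges.to_csv(out / "entropy_edges.tsv", sep="\t", index=False)
        (out / "mdr_dendrogram.nwk").write_text(eg.to_newick() + "\n")
        summary["entropy"] = {
            "class_entropy_bits": eg.class_entropy,
            "info_gain_pct": eg.info_gain_pct,
            "pairwise_gain_pct": {f"{a}|{b}": v
                                  for (a, b), v in eg.pairwise_gain_pct.items()},
        }

        if cfg.targets:
            stage = "network"
            tmap = load_target_map(cfg.targets, energy_cutoff=cfg.energy_cutoff)
            net = build_network(tmap, seed_genes=cfg.seed_genes, alpha=cfg.edge_alpha)
            net.edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
            cent, top5 = centralities(net)
            cent.to_csv(out / "centrality.tsv", sep="\t", index=False)
            summary["network"] = {
                "m": tmap.m, "n_genes": len(tmap.genes),
                "n_candidate_pairs": len(net.edges),
                "n_edges": int(net.graph.number_of_edges()),
                "n_nodes": int(net.graph.number_of_nodes()),
                "top5_intersection": sorted(top5),
            }
            try:
                slope, r2 = powerlaw_fit(net)
                summary["network"]["powerlaw_slope"] = slope
                summary["network"]["powerlaw_r2"] = r2
            except Exception as exc:  # degenerate degree distribution
                summary["network"]["powerlaw_error"] = str(exc)
            if cfg.gene_sets:
                stage = "enrichment"
                sets = read_gmt(cfg.gene_sets)
                nodes = sorted(net.graph.nodes())
                if nodes:
                    enr = ora(nodes, sets, universe=tmap.genes, alpha=cfg.ora_alpha)
                    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                    summary["enrichment"] = enr.to_dict(orient="records")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable,
                  allow_nan=True)
        fh.write("\n")
    return summary
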