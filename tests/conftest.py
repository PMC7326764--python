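import numpy as np
import pytest

from strokenet import (CohortSimSpec, GenotypeMatrix, PlantedPathway,
                       simulate_cohort)


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    dosages = np.array([
        [0, 1],
        [1, 2],
        [2, 0],
        [1, 1],
    ], dtype=float)
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], ["rs1", "rs2"], dosages)


@pytest.fixture
def cohort_files(tmp_path):
    """A small simulated cohort written in the pipeline's file dialects."""
    from strokenet import write_genotypes_tsv, write_phenotypes_csv

    spec = CohortSimSpec(seed=42, n_case=60, n_control=60,
                         mafs=[0.3, 0.4, 0.25],
                         pathways=[PlantedPathway(snp="rs9000000",
                                                  mediator="systolic_BP",
                                                  a=6.0, b=0.04)])
    g, pheno = simulate_cohort(spec)
    gpath = tmp_path / "genotypes.tsv"
    ppath = tmp_path / "phenotypes.csv"
    write_genotypes_tsv(g, gpath)
    write_phenotypes_csv(pheno, ppath)
    return gpath, ppath, g, pheno
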