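import numpy as np
import pandas as pd
import pytest

from comorbnet.datatypes import DifferentialProfile, SampleTable
from comorbnet.synthetic import (
    CohortConfig,
    DiseaseSpec,
    GeneModule,
    planted_pair_config,
    simulate_cohort,
)


def make_profile(
    phenotype: str,
    logfc,
    sdeg=None,
    genes=None,
    kind: str = "disease",
    family: str | None = None,
) -> DifferentialProfile:
    """Hand-built profile for toy network tests."""
    logfc = np.asarray(logfc, dtype=float)
    n = len(logfc)
    genes = list(genes) if genes is not None else [f"g{i:03d}" for i in range(n)]
    sdeg = np.asarray(sdeg, dtype=bool) if sdeg is not None else np.ones(n, dtype=bool)
    tab = pd.DataFrame(
        {
            "logFC": logfc,
            "t": logfc,
            "pvalue": np.where(sdeg, 0.001, 0.5),
            "fdr": np.where(sdeg, 0.01, 0.8),
            "sdeg": sdeg,
        },
        index=pd.Index(genes, name="gene"),
    )
    return DifferentialProfile(
        phenotype=phenotype, table=tab, d0=4.0, s02=1.0, df_residual=10.0,
        kind=kind, family=family,
    )


def small_table(
    n_genes: int = 40,
    cases: int = 4,
    controls: int = 4,
    n_studies: int = 1,
    seed: int = 0,
    **disease_kw,
) -> SampleTable:
    cfg = CohortConfig(
        n_genes=n_genes,
        diseases=[
            DiseaseSpec(
                name="dx", icd9="001", n_studies=n_studies,
                cases_per_study=cases, controls_per_study=controls, **disease_kw,
            )
        ],
        seed=seed,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_cohort():
    """One positive and one negative planted pair, small: 4 diseases."""
    cfg = planted_pair_config(
        n_pos_pairs=1, n_neg_pairs=1, n_genes=800, module_size=120, seed=7,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort_small():
    from comorbnet.synthetic import null_cohort_config

    cfg = null_cohort_config(n_diseases=5, n_genes=500, cases=8, controls=8, seed=13)
    return cfg, simulate_cohort(cfg)
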