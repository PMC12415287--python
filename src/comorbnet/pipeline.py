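"""End-to-end drivers: cohort -> profiles -> networks.

Thin orchestration over the per-stage modules so the analysis scripts,
tests and acceptance checks all run the exact same path.
"""

from __future__ import annotations

import logging

import pandas as pd

from .datatypes import (
    AnalysisError,
    DifferentialProfile,
    ExpressionMatrix,
    SampleTable,
    SimilarityNetwork,
)
from .dsn import MIN_UNION, build_network
from .expression import fit_de, normalize, qc_filter, remove_batch
from .metapatients import build_ssn, correlation_distance, meta_patient_de, select_k

log = logging.getLogger(__name__)

__all__ = [
    "disease_expression",
    "disease_profiles",
    "build_dsn",
    "stratify_disease",
    "stratified_network",
]


def disease_expression(
    table: SampleTable,
    min_aligned: float = 70.0,
    min_cases: int = 3,
) -> dict[str, ExpressionMatrix]:
    """QC the cohort, then normalize each disease separately."""
    clean = qc_filter(table, min_aligned=min_aligned, min_cases=min_cases)
    out: dict[str, ExpressionMatrix] = {}
    for disease in clean.diseases:
        try:
            out[disease] = normalize(clean.subset_disease(disease))
        except AnalysisError as err:
            log.warning("disease %s dropped: %s", disease, err)
    if not out:
        raise AnalysisError("no disease survived normalization")
    return out


def disease_profiles(
    expr_by_disease: dict[str, ExpressionMatrix],
    sdeg_threshold: float = 0.05,
) -> list[DifferentialProfile]:
    """Study-adjusted case-vs-control profile per disease."""
    profiles = []
    for disease, expr in expr_by_disease.items():
        profiles.append(fit_de(expr, phenotype=disease, sdeg_threshold=sdeg_threshold))
    return profiles


def build_dsn(
    table: SampleTable,
    metric: str = "spearman",
    fdr_threshold: float = 0.05,
    min_union: int = MIN_UNION,
    icd9_map: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[SimilarityNetwork, list[DifferentialProfile]]:
    """Full cohort -> disease similarity network."""
    expr = disease_expression(table)
    profiles = disease_profiles(expr)
    net = build_network(
        profiles, metric=metric, fdr_threshold=fdr_threshold,
        min_union=min_union, icd9_map=icd9_map, seed=seed,
    )
    return net, profiles


def stratify_disease(
    expr: ExpressionMatrix,
    disease: str,
    method: str = "pam",
    k_max: int = 15,
    min_cluster_size: int = 3,
):
    """Batch-correct, compute case distances and pick the cluster number."""
    corrected = remove_batch(expr, batch="study")
    n_cases = int((expr.metadata["condition"] == "case").sum())
    if n_cases < 2 * min_cluster_size:
        return _unstratified(expr, disease, method)
    dist = correlation_distance(corrected, cases_only=True)
    return select_k(
        dist, method=method, k_max=k_max,
        min_cluster_size=min_cluster_size, disease=disease,
    )


def _unstratified(expr: ExpressionMatrix, disease: str, method: str):
    from .datatypes import MetaPatientAssignment

    md = expr.metadata
    cases = list(md.loc[md["condition"] == "case", "sample_id"])
    return MetaPatientAssignment(
        disease=disease, method=method, chosen_k=1,
        labels=pd.Series(1, index=cases, name="cluster"),
        unstratified=True,
    )


def stratified_network(
    expr_by_disease: dict[str, ExpressionMatrix],
    profiles: list[DifferentialProfile],
    method: str = "pam",
    metric: str = "spearman",
    fdr_threshold: float = 0.05,
    min_union: int = MIN_UNION,
    icd9_map: pd.DataFrame | None = None,
    k_max: int = 15,
    min_cluster_size: int = 3,
):
    """Stratify every disease, fit meta-patient profiles, build the SSN.

    Returns (ssn, assignments, metapatient_profiles). Unstratified
    diseases contribute no extra nodes.
    """
    assignments = {}
    mp_profiles: list[DifferentialProfile] = []
    for disease, expr in expr_by_disease.items():
        a = stratify_disease(
            expr, disease, method=method, k_max=k_max,
            min_cluster_size=min_cluster_size,
        )
        assignments[disease] = a
        if not a.unstratified:
            mp_profiles.extend(meta_patient_de(expr, a))
    ssn = build_ssn(
        profiles, mp_profiles, metric=metric,
        fdr_threshold=fdr_threshold, min_union=min_union, icd9_map=icd9_map,
    )
    return ssn, assignments, mp_profiles
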