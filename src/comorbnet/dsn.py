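"""Disease Similarity Network construction.

Each disease pair is scored by the Spearman correlation of their log2 fold
changes over the union of their significantly differentially expressed
genes (sDEGs), restricted to genes measured in both. Edges significant
after a single Benjamini-Hochberg correction across all tested pairs
(FDR <= 0.05) are kept, signed by the correlation. A cosine-similarity
variant with a gene-permutation p-value is provided as a robustness check,
and an ICD9-grouped run pools diseases sharing a 3-digit code before the
whole pipeline.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AnalysisError,
    DifferentialProfile,
    SampleTable,
    SimilarityEdge,
    SimilarityNetwork,
)
from .expression import bh_fdr

log = logging.getLogger(__name__)

#: smallest sDEG union on which an edge is attempted
MIN_UNION = 10

__all__ = [
    "MIN_UNION",
    "union_sdegs",
    "edge_test_spearman",
    "edge_test_cosine",
    "build_network",
    "group_by_icd9",
]


def union_sdegs(a: DifferentialProfile, b: DifferentialProfile) -> list[str]:
    """(sDEG(a) | sDEG(b)) restricted to genes measured in both, sorted."""
    measured = set(a.genes) & set(b.genes)
    return sorted((set(a.sdegs) | set(b.sdegs)) & measured)


def _union_vectors(a: DifferentialProfile, b: DifferentialProfile) -> tuple[list[str], np.ndarray, np.ndarray]:
    genes = union_sdegs(a, b)
    return genes, a.logfc.loc[genes].to_numpy(), b.logfc.loc[genes].to_numpy()


def edge_test_spearman(a: DifferentialProfile, b: DifferentialProfile,
                       min_union: int = MIN_UNION) -> SimilarityEdge | None:
    """Spearman edge over the sDEG union; None when skipped (logged)."""
    genes, x, y = _union_vectors(a, b)
    if len(genes) < min_union:
        log.info("edge %s-%s skipped: union %d < %d", a.phenotype, b.phenotype, len(genes), min_union)
        return None
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.warning("edge %s-%s skipped: zero-variance logFC vector", a.phenotype, b.phenotype)
        return None
    rho, p = stats.spearmanr(x, y)
    if not np.isfinite(rho):
        log.warning("edge %s-%s skipped: undefined correlation", a.phenotype, b.phenotype)
        return None
    # rho exactly +-1 has p 0 from the t-approximation; keep as is
    return SimilarityEdge(
        node_a=a.phenotype, node_b=b.phenotype, metric="spearman",
        weight=float(np.clip(rho, -1.0, 1.0)), pvalue=float(p), n_genes=len(genes),
    )


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    nx_, ny_ = np.linalg.norm(x), np.linalg.norm(y)
    if nx_ == 0 or ny_ == 0:
        raise AnalysisError("zero vector in cosine similarity")
    return float(np.dot(x, y) / (nx_ * ny_))


def edge_test_cosine(
    a: DifferentialProfile,
    b: DifferentialProfile,
    n_perm: int = 1000,
    seed: int = 0,
    min_union: int = MIN_UNION,
) -> SimilarityEdge | None:
    """Cosine edge with a two-sided gene-permutation p-value (add-one)."""
    genes, x, y = _union_vectors(a, b)
    if len(genes) < min_union:
        log.info("edge %s-%s skipped: union %d < %d", a.phenotype, b.phenotype, len(genes), min_union)
        return None
    if np.linalg.norm(x) == 0 or np.linalg.norm(y) == 0:
        log.warning("edge %s-%s skipped: zero logFC vector", a.phenotype, b.phenotype)
        return None
    obs = cosine_similarity(x, y)
    rng = np.random.default_rng(seed)
    xn = x / np.linalg.norm(x)
    yn = y / np.linalg.norm(y)
    perms = np.array([np.dot(xn, yn[rng.permutation(len(yn))]) for _ in range(n_perm)])
    p = (1.0 + np.sum(np.abs(perms) >= abs(obs) - 1e-12)) / (1.0 + n_perm)
    return SimilarityEdge(
        node_a=a.phenotype, node_b=b.phenotype, metric="cosine",
        weight=float(np.clip(obs, -1.0, 1.0)), pvalue=float(p), n_genes=len(genes),
    )


def _node_table(profiles: list[DifferentialProfile],
                icd9_map: pd.DataFrame | None) -> pd.DataFrame:
    lookup = {}
    if icd9_map is not None:
        lookup = icd9_map.set_index("disease")[["icd9", "category"]].to_dict("index")
    rows = []
    for pr in profiles:
        key = pr.family if pr.family is not None else pr.phenotype
        info = lookup.get(key, {})
        rows.append(
            dict(
                id=pr.phenotype,
                kind=pr.kind,
                icd9=info.get("icd9", pr.phenotype if icd9_map is None else None),
                category=info.get("category"),
                family=pr.family,
            )
        )
    return pd.DataFrame(rows)


def build_network(
    profiles: list[DifferentialProfile],
    metric: str = "spearman",
    fdr_threshold: float = 0.05,
    min_union: int = MIN_UNION,
    n_perm: int = 1000,
    seed: int = 0,
    icd9_map: pd.DataFrame | None = None,
    exclude_pairs: set[frozenset] | None = None,
) -> SimilarityNetwork:
    """All-pairs similarity edges with one joint BH correction.

    Phenotypes are ordered lexicographically so pair enumeration, the
    permutation stream of the cosine test and the BH ranking are all
    reproducible. ``exclude_pairs`` drops pairs before testing (used for
    self-family exclusions in the stratified network).
    """
    if len(profiles) < 2:
        raise AnalysisError("need at least 2 profiles to build a network")
    if metric not in {"spearman", "cosine"}:
        raise ValueError(f"unknown metric {metric!r}")
    profiles = sorted(profiles, key=lambda p: p.phenotype)
    ids = [p.phenotype for p in profiles]
    if len(set(ids)) != len(ids):
        raise AnalysisError("duplicate phenotype ids")
    exclude_pairs = exclude_pairs or set()

    edges: list[SimilarityEdge] = []
    skipped: list[dict] = []
    for idx, (a, b) in enumerate(itertools.combinations(profiles, 2)):
        pair = frozenset((a.phenotype, b.phenotype))
        if pair in exclude_pairs:
            continue
        if metric == "spearman":
            e = edge_test_spearman(a, b, min_union=min_union)
        else:
            e = edge_test_cosine(a, b, n_perm=n_perm, seed=seed + idx, min_union=min_union)
        if e is None:
            skipped.append(dict(node_a=a.phenotype, node_b=b.phenotype, reason="skipped"))
        else:
            edges.append(e)

    cols = list(SimilarityNetwork.EDGE_COLUMNS)
    if edges:
        df = pd.DataFrame(
            [
                (e.node_a, e.node_b, e.metric, e.weight, e.pvalue, np.nan, e.n_genes)
                for e in edges
            ],
            columns=cols,
        )
        df["fdr"] = bh_fdr(df["pvalue"].to_numpy())
        df = df[df["fdr"] <= fdr_threshold].reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=cols)
    return SimilarityNetwork(
        nodes=_node_table(profiles, icd9_map),
        edges=df,
        metric=metric,
        fdr_threshold=fdr_threshold,
        skipped=pd.DataFrame(skipped) if skipped else None,
    )


def group_by_icd9(table: SampleTable, icd9_map: pd.DataFrame) -> SampleTable:
    """Pool diseases sharing a 3-digit ICD9 code into one phenotype.

    The phenotype label becomes the ICD9 code; samples are concatenated and
    studies preserved, so the downstream pipeline runs unchanged at the
    ICD9 level.
    """
    mapping = icd9_map.set_index("disease")["icd9"].to_dict()
    missing = sorted(set(table.metadata["disease"]) - set(mapping))
    if missing:
        raise AnalysisError(f"diseases without ICD9 mapping: {missing}")
    md = table.metadata.copy()
    md["source_disease"] = md["disease"]
    md["disease"] = md["disease"].map(mapping)
    return SampleTable(counts=table.counts, metadata=md, truth=table.truth)
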