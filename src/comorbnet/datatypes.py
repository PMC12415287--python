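"""Core containers shared across the pipeline.

The pipeline moves a cohort through four representations: raw counts with
sample metadata (:class:`SampleTable`), normalized log2CPM expression
(:class:`ExpressionMatrix`), per-phenotype differential-expression profiles
(:class:`DifferentialProfile`) and phenotype-phenotype graphs
(:class:`SimilarityNetwork`, :class:`EpidemiologicalNetwork`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

#: metadata columns every sample record must carry
METADATA_COLUMNS = (
    "sample_id",
    "disease",
    "study",
    "tissue",
    "condition",
    "percent_aligned",
)


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration."""


class AnalysisError(RuntimeError):
    """A pipeline stage cannot produce output (e.g. all samples removed)."""


@dataclass
class SampleTable:
    """Raw gene counts (genes x samples) plus per-sample metadata.

    ``truth`` optionally records planted simulation ground truth (subtype
    labels, per-gene log2 effects). It is carried for evaluation only and is
    never read by any analysis stage.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        md = self.metadata
        missing = [c for c in METADATA_COLUMNS if c not in md.columns]
        if missing:
            raise ConfigError(f"metadata missing columns: {missing}")
        if md["sample_id"].duplicated().any():
            dup = md.loc[md["sample_id"].duplicated(), "sample_id"].tolist()
            raise ConfigError(f"duplicate sample ids: {dup[:5]}")
        if list(self.counts.columns) != list(md["sample_id"]):
            raise ConfigError("counts columns must match metadata sample_id order")
        if (self.counts.to_numpy() < 0).any():
            raise ConfigError("negative counts")
        if md["percent_aligned"].isna().any():
            raise ConfigError("percent_aligned required for every sample")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def diseases(self) -> list[str]:
        return sorted(self.metadata["disease"].unique())

    def subset_samples(self, sample_ids: list[str]) -> "SampleTable":
        md = self.metadata[self.metadata["sample_id"].isin(set(sample_ids))]
        md = md.reset_index(drop=True)
        return SampleTable(
            counts=self.counts[list(md["sample_id"])],
            metadata=md,
            truth=self.truth,
        )

    def subset_disease(self, disease: str) -> "SampleTable":
        ids = self.metadata.loc[self.metadata["disease"] == disease, "sample_id"]
        if ids.empty:
            raise KeyError(f"no samples for disease {disease!r}")
        return self.subset_samples(list(ids))


@dataclass
class ExpressionMatrix:
    """Filtered log2CPM expression with the normalization bookkeeping.

    ``values`` is genes x samples on the log2CPM scale after TMM-effective
    library sizes; ``norm_factors`` are the TMM factors f_j (geometric mean
    1); ``lib_sizes`` the raw library sizes.
    """

    values: pd.DataFrame
    norm_factors: pd.Series
    lib_sizes: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.norm_factors <= 0).any():
            raise ConfigError("norm factors must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def cases_mask(self) -> np.ndarray:
        return (self.metadata["condition"] == "case").to_numpy()


@dataclass
class DifferentialProfile:
    """Per-gene differential expression for one phenotype.

    ``table`` is indexed by gene id with columns ``logFC`` (log2 case vs
    control), ``t`` (moderated t), ``pvalue``, ``fdr`` (BH q-value) and
    ``sdeg`` (bool, fdr <= threshold). ``d0``/``s02`` are the empirical-Bayes
    prior degrees of freedom and prior variance, ``df_residual`` the residual
    df of the linear model.
    """

    phenotype: str
    table: pd.DataFrame
    d0: float
    s02: float
    df_residual: float
    kind: str = "disease"  # or "meta-patient"
    family: str | None = None  # owning disease for meta-patients
    sdeg_threshold: float = 0.05

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def sdegs(self) -> pd.Index:
        return self.table.index[self.table["sdeg"]]

    @property
    def logfc(self) -> pd.Series:
        return self.table["logFC"]


@dataclass
class SimilarityEdge:
    node_a: str
    node_b: str
    metric: str
    weight: float
    pvalue: float
    n_genes: int
    fdr: float = np.nan

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise ConfigError("self-edge not allowed")
        if abs(self.weight) > 1 + 1e-12:
            raise ConfigError(f"|weight| > 1: {self.weight}")

    @property
    def sign(self) -> str:
        return "positive" if self.weight > 0 else "negative"


@dataclass
class SimilarityNetwork:
    """Signed phenotype-phenotype similarity graph (DSN or SSN)."""

    nodes: pd.DataFrame  # columns: id, kind, icd9, category, family
    edges: pd.DataFrame  # columns: node_a, node_b, metric, weight, pvalue, fdr, n_genes
    metric: str
    fdr_threshold: float
    skipped: pd.DataFrame | None = None  # pairs skipped before testing, with reason

    EDGE_COLUMNS = ("node_a", "node_b", "metric", "weight", "pvalue", "fdr", "n_genes")

    def sign_edges(self, sign: str | None) -> pd.DataFrame:
        if sign is None:
            return self.edges
        if sign == "positive":
            return self.edges[self.edges["weight"] > 0]
        if sign == "negative":
            return self.edges[self.edges["weight"] < 0]
        raise ValueError(f"unknown sign {sign!r}")

    def graph(self, sign: str | None = None) -> nx.Graph:
        """Unweighted undirected graph over all nodes, optionally one sign class."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes["id"])
        for row in self.sign_edges(sign).itertuples():
            g.add_edge(row.node_a, row.node_b, weight=row.weight)
        return g

    def edge_set(self, sign: str | None = None) -> set[frozenset]:
        return {
            frozenset((a, b))
            for a, b in self.sign_edges(sign)[["node_a", "node_b"]].itertuples(index=False)
        }


@dataclass
class EpidemiologicalNetwork:
    """Undirected ICD9-level comorbidity network with an RR or phi measure."""

    edges: pd.DataFrame  # columns: icd9_a, icd9_b, measure, value
    measure: str = "RR"

    def __post_init__(self) -> None:
        e = self.edges
        if (e["icd9_a"] == e["icd9_b"]).any():
            raise ConfigError("self-loop in epidemiological network")

    @property
    def nodes(self) -> set[str]:
        return set(self.edges["icd9_a"]) | set(self.edges["icd9_b"])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges[["icd9_a", "icd9_b"]].itertuples(index=False))
        return g

    def edge_set(self) -> set[frozenset]:
        return {
            frozenset((a, b))
            for a, b in self.edges[["icd9_a", "icd9_b"]].itertuples(index=False)
        }


@dataclass
class MetaPatientAssignment:
    """Clustering of one disease's cases into meta-patients."""

    disease: str
    method: str  # "pam" or "ward2"
    chosen_k: int
    labels: pd.Series  # case sample_id -> cluster int (1-based)
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    silhouette_samples: pd.Series | None = None
    unstratified: bool = False
    low_confidence: bool = False

    @property
    def cluster_sizes(self) -> dict[int, int]:
        return self.labels.value_counts().sort_index().to_dict()

    def cases_in(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])
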