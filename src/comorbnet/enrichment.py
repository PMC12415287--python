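"""Preranked gene-set enrichment and pathway-level edge explanation.

The enrichment score is the classic weighted Kolmogorov-Smirnov running
statistic over genes ranked by log2 fold change (descending): genes in the
set increment the running sum by |score|^p normalized over the set's
scores, genes outside decrement by 1/(N - N_hit); the ES is the signed
extremum. Significance comes from gene-label permutations; NES divides the
ES by the mean magnitude of same-sign null scores, and the permutation
p-value is sign-matched with add-one smoothing. FDR across sets is
Benjamini-Hochberg.

Downstream, diseases are clustered on their binarized NES signatures
(+1/-1/0 for significantly up/down/not), and the positive edges of a
similarity network are profiled for pathways significantly altered in the
same direction in both endpoints, contrasting epidemiological (EI) against
nonepidemiological (NEI) interactions per pathway category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .datatypes import AnalysisError, DifferentialProfile, EpidemiologicalNetwork, SimilarityNetwork
from .expression import bh_fdr

log = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "gsea_es",
    "gsea_preranked",
    "binarize_and_cluster",
    "shared_pathways_by_edge",
]


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    category: dict[str, str] = field(default_factory=dict)

    def category_of(self, name: str) -> str:
        return self.category.get(name, "uncategorized")


@dataclass
class EnrichmentResult:
    phenotype: str
    table: pd.DataFrame  # index set name; columns: size, es, nes, pvalue, fdr, direction
    n_perm: int
    seed: int

    def significant(self, fdr: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] <= fdr]


def _ranked_scores(profile: DifferentialProfile) -> pd.Series:
    """logFC descending, ties broken by gene id for a reproducible order."""
    tmp = pd.DataFrame(
        {"score": profile.table["logFC"].to_numpy(), "g": profile.table.index.to_numpy()}
    ).sort_values(["score", "g"], ascending=[False, True])
    return pd.Series(tmp["score"].to_numpy(), index=tmp["g"].to_numpy())


def _es_from_positions(w: np.ndarray, pos: np.ndarray, n_universe: int) -> np.ndarray:
    """Signed-extremum ES for each row of hit positions.

    ``w`` are the |score|^p weights over the ranked universe, ``pos`` is a
    (B, m) array of sorted 0-based hit positions. The running sum attains
    its maxima immediately after hits and its minima immediately before
    hits, so only those 2m candidates are scanned.
    """
    pos = np.atleast_2d(pos)
    B, m = pos.shape
    if not m or m >= n_universe:
        raise AnalysisError("gene set must be a nonempty proper subset of the universe")
    wpos = w[pos]
    cw = np.cumsum(wpos, axis=1)
    denom = cw[:, -1].copy()
    flat = denom <= 0
    if flat.any():  # all-zero scores in the set: fall back to equal hit steps
        cw[flat] = np.arange(1, m + 1)[None, :]
        denom[flat] = m
    p_hit = cw / denom[:, None]
    miss_before = (pos - np.arange(m)[None, :]) / (n_universe - m)
    up = p_hit - miss_before
    down = np.concatenate([np.zeros((B, 1)), p_hit[:, :-1]], axis=1) - miss_before
    es_max = up.max(axis=1)
    es_min = down.min(axis=1)
    return np.where(np.abs(es_max) >= np.abs(es_min), es_max, es_min)


def gsea_es(
    ranked: pd.Series,
    gene_set,
    weight: float = 1.0,
) -> tuple[float, int]:
    """ES of one gene set against a ranked score list (descending).

    Returns (ES, position of the running-sum extremum, 0-based in the
    ranked list). ``ranked`` must already be sorted descending.
    """
    scores = ranked.to_numpy(dtype=float)
    if np.any(np.diff(scores) > 1e-12):
        raise AnalysisError("ranked scores must be sorted descending")
    n = len(ranked)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.index), dtype=bool, count=n)
    m = int(hit.sum())
    if m == 0 or m == n:
        raise AnalysisError("gene set must be a nonempty proper subset of the universe")
    w = np.abs(scores) ** weight
    pos = np.flatnonzero(hit)
    es = float(_es_from_positions(w, pos[None, :], n)[0])

    # locate the extremum for reporting
    denom = w[pos].sum()
    step = np.where(hit, (w if denom > 0 else np.ones(n) / m) / (denom if denom > 0 else 1.0), -1.0 / (n - m))
    running = np.cumsum(step)
    argext = int(np.argmax(running)) if es >= 0 else int(np.argmin(running))
    return es, argext


def gsea_preranked(
    profile: DifferentialProfile,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    weight: float = 1.0,
    fdr_threshold: float = 0.05,
) -> EnrichmentResult:
    """ES/NES/p/FDR for every set in the collection against one profile."""
    ranked = _ranked_scores(profile)
    n = len(ranked)
    universe = set(ranked.index)
    w = np.abs(ranked.to_numpy()) ** weight
    gene_pos = {g: i for i, g in enumerate(ranked.index)}

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name in sorted(collection.sets):
        genes = sorted(set(collection.sets[name]) & universe)
        m = len(genes)
        if not (min_size <= m <= max_size) or m >= n:
            continue
        pos = np.sort(np.array([gene_pos[g] for g in genes]))
        es = float(_es_from_positions(w, pos[None, :], n)[0])
        if m not in null_cache:
            rng = np.random.default_rng([seed & 0x7FFFFFFF, m])
            keys = rng.random((n_perm, n))
            # uniform random m-subsets of gene positions per permutation
            perm_pos = np.sort(np.argpartition(keys, m, axis=1)[:, :m], axis=1)
            null_cache[m] = _es_from_positions(w, perm_pos, n)
        null = null_cache[m]
        if es >= 0:
            same = null[null > 0]
            nes = es / same.mean() if same.size else np.nan
            p = (1.0 + np.sum(same >= es - 1e-12)) / (1.0 + same.size)
        else:
            same = null[null < 0]
            nes = es / np.abs(same).mean() if same.size else np.nan
            p = (1.0 + np.sum(same <= es + 1e-12)) / (1.0 + same.size)
        rows.append(dict(set=name, size=m, es=es, nes=nes, pvalue=p))
    if not rows:
        log.warning("gsea_preranked(%s): no sets within size bounds", profile.phenotype)
        tab = pd.DataFrame(columns=["size", "es", "nes", "pvalue", "fdr", "direction"])
        return EnrichmentResult(profile.phenotype, tab, n_perm, seed)
    tab = pd.DataFrame(rows).set_index("set")
    tab["fdr"] = bh_fdr(tab["pvalue"].to_numpy())
    tab["direction"] = np.sign(tab["nes"]).astype(int)
    return EnrichmentResult(profile.phenotype, tab, n_perm, seed)


def binarize_and_cluster(
    results: dict[str, EnrichmentResult],
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Ward2 clustering of diseases on signed significant-pathway vectors.

    The matrix holds +1 (significantly up), -1 (significantly down) or 0
    per (pathway, disease); diseases with no significant pathway are
    excluded. Returns (matrix pathways x diseases, linkage over diseases,
    disease order).
    """
    if len(results) < 2:
        raise AnalysisError("need >= 2 phenotypes to cluster")
    cols = {}
    for name in sorted(results):
        tab = results[name].table
        sig = tab["fdr"] <= fdr_threshold
        cols[name] = (tab["direction"].where(sig, 0)).astype(int)
    mat = pd.DataFrame(cols).fillna(0).astype(int)
    keep = mat.columns[(mat != 0).any(axis=0)]
    mat = mat[keep]
    if mat.shape[1] == 0 or (mat.to_numpy() == 0).all():
        raise AnalysisError("no phenotype has a significant pathway")
    if mat.shape[1] < 2:
        raise AnalysisError("fewer than 2 phenotypes with significant pathways")
    z = linkage(mat.T.to_numpy(dtype=float), method="ward", metric="euclidean")
    return mat, z, list(mat.columns)


def shared_pathways_by_edge(
    network: SimilarityNetwork,
    epi: EpidemiologicalNetwork,
    results: dict[str, EnrichmentResult],
    collection: GeneSetCollection,
    direction: str = "up",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per pathway category, shared-alteration statistics for EIs vs NEIs.

    Each positive molecular edge is labeled EI when its ICD9 pair is in
    the epidemiological network, else NEI. Per edge and category the
    pathways significantly altered in the requested direction in BOTH
    endpoints are counted. Returns one row per category with the
    percentage of EIs/NEIs sharing >= 1 such pathway, the mean shared
    counts, and the EI/NEI ratio of those means.
    """
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    want = 1 if direction == "up" else -1
    icd9 = network.nodes.set_index("id")["icd9"]
    epi_edges = epi.edge_set()

    sig: dict[str, set[str]] = {}
    for pheno, res in results.items():
        t = res.table
        sig[pheno] = set(t.index[(t["fdr"] <= fdr_threshold) & (t["direction"] == want)])

    categories = sorted({collection.category_of(s) for s in collection.sets})
    counts: dict[str, dict[str, list[int]]] = {c: {"EI": [], "NEI": []} for c in categories}
    n_edges = {"EI": 0, "NEI": 0}
    for row in network.sign_edges("positive").itertuples():
        if row.node_a not in sig or row.node_b not in sig:
            log.info("edge %s-%s skipped: missing enrichment results", row.node_a, row.node_b)
            continue
        a9, b9 = icd9[row.node_a], icd9[row.node_b]
        label = "EI" if frozenset((a9, b9)) in epi_edges else "NEI"
        n_edges[label] += 1
        shared = sig[row.node_a] & sig[row.node_b]
        per_cat: dict[str, int] = {c: 0 for c in categories}
        for s in shared:
            per_cat[collection.category_of(s)] += 1
        for c in categories:
            counts[c][label].append(per_cat[c])

    rows = []
    for c in categories:
        ei, nei = counts[c]["EI"], counts[c]["NEI"]
        mean_ei = float(np.mean(ei)) if ei else np.nan
        mean_nei = float(np.mean(nei)) if nei else np.nan
        rows.append(
            dict(
                category=c,
                direction=direction,
                n_ei=len(ei),
                n_nei=len(nei),
                pct_ei_sharing=100.0 * np.mean([x > 0 for x in ei]) if ei else np.nan,
                pct_nei_sharing=100.0 * np.mean([x > 0 for x in nei]) if nei else np.nan,
                mean_shared_ei=mean_ei,
                mean_shared_nei=mean_nei,
                ei_nei_ratio=(mean_ei / mean_nei) if nei and mean_nei > 0 else np.inf,
            )
        )
    return pd.DataFrame(rows).set_index("category")
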