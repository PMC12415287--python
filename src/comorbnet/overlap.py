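"""Agreement between a molecular similarity network and epidemiology.

Recall is the percentage of epidemiological comorbidity edges (restricted
to the diseases present in both networks) found among the molecular edges
of the requested sign; precision is the percentage of molecular edges that
are epidemiological. Significance comes from a degree-preserving null:
the molecular sign-subnetwork is rewired by double-edge swaps, keeping
every node's degree, and the overlap is recomputed per replicate; p-values
use add-one smoothing, so they can never be below 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .datatypes import AnalysisError, EpidemiologicalNetwork, SimilarityNetwork

__all__ = ["OverlapResult", "recall_precision", "degree_preserving_null", "compare_networks"]


@dataclass
class OverlapResult:
    n_common_nodes: int
    n_epi_edges: int
    n_mol_edges: int
    n_shared_edges: int
    recall: float  # percent, nan when undefined
    precision: float  # percent, nan when undefined
    p_recall: float = np.nan
    p_precision: float = np.nan
    n_perm: int = 0
    seed: int | None = None
    replicate_overlaps: np.ndarray | None = None  # shared-edge count per rewired replicate


def _mol_icd9_edges(mol: SimilarityNetwork, sign: str) -> tuple[set[str], set[frozenset]]:
    """Molecular nodes and sign-class edges mapped to ICD9 labels."""
    icd9 = mol.nodes.set_index("id")["icd9"]
    if icd9.isna().any():
        missing = list(mol.nodes.loc[mol.nodes["icd9"].isna(), "id"])
        raise AnalysisError(f"molecular nodes without ICD9 label: {missing[:5]}")
    nodes = set(icd9)
    edges = set()
    for row in mol.sign_edges(sign).itertuples():
        a, b = icd9[row.node_a], icd9[row.node_b]
        if a != b:
            edges.add(frozenset((a, b)))
    return nodes, edges


def _restrict(edges: set[frozenset], nodes: set[str]) -> set[frozenset]:
    return {e for e in edges if set(e) <= nodes}


def recall_precision(
    mol: SimilarityNetwork,
    epi: EpidemiologicalNetwork,
    sign: str = "positive",
) -> OverlapResult:
    """Overlap of the molecular sign class with the epidemiology (no p-values)."""
    mol_nodes, mol_edges = _mol_icd9_edges(mol, sign)
    common = mol_nodes & epi.nodes
    if len(common) < 2:
        raise AnalysisError(f"fewer than 2 common nodes ({len(common)})")
    e_epi = _restrict(epi.edge_set(), common)
    e_mol = _restrict(mol_edges, common)
    shared = e_epi & e_mol
    recall = 100.0 * len(shared) / len(e_epi) if e_epi else np.nan
    precision = 100.0 * len(shared) / len(e_mol) if e_mol else np.nan
    return OverlapResult(
        n_common_nodes=len(common),
        n_epi_edges=len(e_epi),
        n_mol_edges=len(e_mol),
        n_shared_edges=len(shared),
        recall=recall,
        precision=precision,
    )


def _rewire(g: nx.Graph, rng: np.random.Generator, swap_multiplier: int = 10) -> nx.Graph:
    """Degree-preserving double-edge-swap replicate of ``g``."""
    h = g.copy()
    m = h.number_of_edges()
    nswap = swap_multiplier * m
    try:
        nx.double_edge_swap(h, nswap=nswap, max_tries=100 * nswap,
                            seed=int(rng.integers(0, 2**31 - 1)))
    except nx.NetworkXAlgorithmError as err:
        raise AnalysisError(
            "subnetwork cannot be rewired (too dense or too small); "
            "consider an exhaustive null"
        ) from err
    return h


def degree_preserving_null(
    mol: SimilarityNetwork,
    epi: EpidemiologicalNetwork,
    sign: str = "positive",
    n_perm: int = 1000,
    seed: int = 0,
    swap_multiplier: int = 10,
) -> OverlapResult:
    """Rewiring-null p-values for the recall and precision of one sign class."""
    obs = recall_precision(mol, epi, sign)
    mol_nodes, mol_edges = _mol_icd9_edges(mol, sign)
    common = mol_nodes & epi.nodes
    e_epi = _restrict(epi.edge_set(), common)
    e_mol = _restrict(mol_edges, common)
    if len(e_mol) < 2:
        raise AnalysisError("need >= 2 molecular edges of the requested sign to rewire")

    g = nx.Graph()
    g.add_nodes_from(common)
    g.add_edges_from(map(tuple, e_mol))
    degrees = sorted(d for _, d in g.degree())
    rng = np.random.default_rng(seed)
    shared_counts = np.empty(n_perm, dtype=int)
    for r in range(n_perm):
        h = _rewire(g, rng, swap_multiplier)
        assert sorted(d for _, d in h.degree()) == degrees
        shared_counts[r] = sum(1 for a, b in h.edges() if frozenset((a, b)) in e_epi)
    p = (1.0 + int(np.sum(shared_counts >= obs.n_shared_edges))) / (1.0 + n_perm)
    # edge count of the sign class is fixed under rewiring, so the same
    # exceedance drives recall and precision
    obs.p_recall = p
    obs.p_precision = p
    obs.n_perm = n_perm
    obs.seed = seed
    obs.replicate_overlaps = shared_counts
    return obs


def compare_networks(
    a: SimilarityNetwork,
    b: SimilarityNetwork,
    sign: str = "positive",
) -> tuple[float, float]:
    """Fisher's exact association between two molecular networks.

    Builds the 2x2 table of all common-node pairs classified by presence of
    an edge (of the requested sign) in each network. Returns (odds ratio,
    two-sided p); the odds ratio is inf/0 on a degenerate margin.
    """
    nodes_a = set(a.nodes["id"])
    nodes_b = set(b.nodes["id"])
    common = sorted(nodes_a & nodes_b)
    if len(common) < 3:
        raise AnalysisError("need >= 3 common nodes")
    cset = set(common)
    ea = {e for e in a.edge_set(sign) if set(e) <= cset}
    eb = {e for e in b.edge_set(sign) if set(e) <= cset}
    n_pairs = len(common) * (len(common) - 1) // 2
    both = len(ea & eb)
    only_a = len(ea - eb)
    only_b = len(eb - ea)
    neither = n_pairs - both - only_a - only_b
    table = np.array([[both, only_a], [only_b, neither]])
    oddsratio, p = stats.fisher_exact(table, alternative="two-sided")
    return float(oddsratio), float(p)
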