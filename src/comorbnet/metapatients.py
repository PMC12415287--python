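"""Patient stratification into meta-patients and the stratified network.

Cases of a disease are clustered on the batch-corrected log2CPM matrix
using the 1 - Spearman correlation distance. PAM (k-medoids, deterministic
BUILD + SWAP) is scanned over k = 2..15 and the k with the highest average
silhouette is kept (ties to the smaller k); Ward2 agglomeration is the
alternative method. Each meta-patient (cluster of cases) is contrasted
against all the disease's controls with the same DE model as diseases, and
the Stratified Similarity Network treats meta-patients and diseases
equally as phenotypes, excluding a disease's own family from pairing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples

from .datatypes import (
    AnalysisError,
    DifferentialProfile,
    ExpressionMatrix,
    MetaPatientAssignment,
    SimilarityNetwork,
)
from .dsn import MIN_UNION, build_network
from .expression import fit_de, subset_expression

log = logging.getLogger(__name__)

#: smallest admissible meta-patient
MIN_CLUSTER_SIZE = 3
K_MAX = 15

__all__ = [
    "correlation_distance",
    "pam_cluster",
    "ward2_cluster",
    "select_k",
    "meta_patient_de",
    "build_ssn",
    "random_metapatient_null",
]


def correlation_distance(corrected: ExpressionMatrix, cases_only: bool = True) -> pd.DataFrame:
    """Pairwise 1 - Spearman distance between samples (cases by default)."""
    md = corrected.metadata
    ids = list(md.loc[md["condition"] == "case", "sample_id"]) if cases_only else list(md["sample_id"])
    if len(ids) < 4:
        raise AnalysisError(f"need >= 4 samples for a distance matrix, have {len(ids)}")
    x = corrected.values[ids].to_numpy()
    for j, sid in enumerate(ids):
        if np.ptp(x[:, j]) == 0:
            raise AnalysisError(f"constant expression vector for sample {sid}")
    rho = stats.spearmanr(x, axis=0).statistic
    rho = np.atleast_2d(rho)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# PAM (k-medoids): deterministic BUILD + SWAP
# ---------------------------------------------------------------------------

def _pam_cost(d: np.ndarray, medoids: list[int]) -> float:
    return float(d[:, medoids].min(axis=1).sum())


def pam_cluster(distance: pd.DataFrame, k: int) -> tuple[pd.Series, list[str]]:
    """Partition Around Medoids on a precomputed distance matrix.

    BUILD seeds medoids greedily (first the point minimizing total
    distance, then the point yielding the largest cost decrease); SWAP
    repeatedly applies the single best improving (medoid, non-medoid)
    exchange. All ties break to the lowest index, so the outcome is a
    deterministic local optimum of the total distance to medoids.
    Returns (labels indexed by sample, medoid ids ordered by cluster).
    """
    n = distance.shape[0]
    if not 1 <= k <= n:
        raise AnalysisError(f"k must be in [1, n], got k={k}, n={n}")
    d = distance.to_numpy()
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, None
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(cur - d[:, j], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)

    current = _pam_cost(d, medoids)
    while True:
        best_cost, best_swap = current, None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = _pam_cost(d, trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        current = best_cost

    medoids = sorted(medoids)
    assign = np.argmin(d[:, medoids], axis=1)
    labels = pd.Series(assign + 1, index=distance.index, name="cluster")
    return labels, [distance.index[m] for m in medoids]


def ward2_cluster(distance: pd.DataFrame, k: int) -> pd.Series:
    """Ward2 agglomeration (Lance-Williams on squared distances), cut at k."""
    n = distance.shape[0]
    if not 1 <= k <= n:
        raise AnalysisError(f"k must be in [1, n], got k={k}, n={n}")
    z = ward2_linkage(distance)
    raw = fcluster(z, t=k, criterion="maxclust")
    # renumber clusters by first appearance for determinism
    seen: dict[int, int] = {}
    out = []
    for c in raw:
        if c not in seen:
            seen[c] = len(seen) + 1
        out.append(seen[c])
    return pd.Series(out, index=distance.index, name="cluster")


def ward2_linkage(distance: pd.DataFrame) -> np.ndarray:
    """Ward2 linkage matrix for a precomputed distance (ward.D2 convention)."""
    return linkage(squareform(distance.to_numpy(), checks=False), method="ward")


def _avg_silhouette(d: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    s = silhouette_samples(d, labels, metric="precomputed")
    return float(s.mean()), s


def select_k(
    distance: pd.DataFrame,
    method: str = "pam",
    k_max: int = K_MAX,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    disease: str = "disease",
) -> MetaPatientAssignment:
    """Scan k = 2..k_max, keep the highest average silhouette.

    Only k with all clusters >= ``min_cluster_size`` are admissible; ties
    break to the smaller k. Diseases with fewer than 2 * min_cluster_size
    cases, or with no admissible k, are left unstratified (one
    meta-patient). A best silhouette below 0.25 flags low confidence.
    """
    n = distance.shape[0]
    ids = distance.index
    if method not in {"pam", "ward2"}:
        raise ValueError(f"unknown method {method!r}")
    one = MetaPatientAssignment(
        disease=disease, method=method, chosen_k=1,
        labels=pd.Series(1, index=ids, name="cluster"),
        unstratified=True,
    )
    if n < 2 * min_cluster_size:
        log.info("select_k(%s): %d cases < %d; unstratified", disease, n, 2 * min_cluster_size)
        return one

    d = distance.to_numpy()
    sil_by_k: dict[int, float] = {}
    per_k: dict[int, tuple[pd.Series, np.ndarray]] = {}
    for k in range(2, min(k_max, n - 1) + 1):
        if method == "pam":
            labels, _ = pam_cluster(distance, k)
        else:
            labels = ward2_cluster(distance, k)
        if labels.value_counts().min() < min_cluster_size:
            continue
        avg, s = _avg_silhouette(d, labels.to_numpy())
        sil_by_k[k] = avg
        per_k[k] = (labels, s)
    if not sil_by_k:
        log.info("select_k(%s): no admissible k; unstratified", disease)
        return one
    best_k = min(sil_by_k, key=lambda k: (-sil_by_k[k], k))
    labels, s = per_k[best_k]
    return MetaPatientAssignment(
        disease=disease,
        method=method,
        chosen_k=best_k,
        labels=labels,
        silhouette_by_k=sil_by_k,
        silhouette_samples=pd.Series(s, index=ids, name="silhouette"),
        unstratified=False,
        low_confidence=sil_by_k[best_k] < 0.25,
    )


# ---------------------------------------------------------------------------
# meta-patient differential expression and the stratified network
# ---------------------------------------------------------------------------

def meta_patient_de(
    expr: ExpressionMatrix,
    assignment: MetaPatientAssignment,
    sdeg_threshold: float = 0.05,
) -> list[DifferentialProfile]:
    """One profile per meta-patient: cluster cases vs ALL disease controls.

    Runs on the disease-level normalized matrix (same genes, same TMM
    factors), so the unstratified (k = 1) profile coincides exactly with
    the disease-level profile.
    """
    md = expr.metadata
    controls = list(md.loc[md["condition"] == "control", "sample_id"])
    if not controls:
        raise AnalysisError(f"{assignment.disease}: no controls")
    profiles = []
    for cluster in sorted(assignment.labels.unique()):
        cases = assignment.cases_in(cluster)
        sub = subset_expression(expr, cases + controls)
        name = (
            assignment.disease
            if assignment.unstratified
            else f"{assignment.disease}::mp{cluster}"
        )
        profiles.append(
            fit_de(
                sub,
                phenotype=name,
                sdeg_threshold=sdeg_threshold,
                kind="disease" if assignment.unstratified else "meta-patient",
                family=assignment.disease,
            )
        )
    return profiles


def _family(profile: DifferentialProfile) -> str:
    return profile.family if profile.family is not None else profile.phenotype


def build_ssn(
    disease_profiles: list[DifferentialProfile],
    metapatient_profiles: list[DifferentialProfile],
    metric: str = "spearman",
    fdr_threshold: float = 0.05,
    min_union: int = MIN_UNION,
    icd9_map: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> SimilarityNetwork:
    """DSN over diseases plus meta-patients, excluding within-family pairs.

    A disease and its own meta-patients (and meta-patients of the same
    disease among themselves) share samples and controls, so those pairs
    are never tested.
    """
    profiles = list(disease_profiles) + [
        p for p in metapatient_profiles if p.kind == "meta-patient"
    ]
    exclude = set()
    for i, a in enumerate(profiles):
        for b in profiles[i + 1:]:
            if _family(a) == _family(b):
                exclude.add(frozenset((a.phenotype, b.phenotype)))
    return build_network(
        profiles,
        metric=metric,
        fdr_threshold=fdr_threshold,
        min_union=min_union,
        icd9_map=icd9_map,
        n_perm=n_perm,
        seed=seed,
        exclude_pairs=exclude,
    )


def _metapatient_edge_counts(net: SimilarityNetwork) -> tuple[int, int]:
    """(positive, negative) meta-patient-to-disease edge counts."""
    kinds = net.nodes.set_index("id")["kind"]
    pos = neg = 0
    for row in net.edges.itertuples():
        if {kinds[row.node_a], kinds[row.node_b]} == {"meta-patient", "disease"}:
            if row.weight > 0:
                pos += 1
            else:
                neg += 1
    return pos, neg


def random_metapatient_null(
    expr_by_disease: dict[str, ExpressionMatrix],
    assignments: dict[str, MetaPatientAssignment],
    disease_profiles: list[DifferentialProfile],
    n_reps: int = 1000,
    seed: int = 0,
    metric: str = "spearman",
    fdr_threshold: float = 0.05,
    min_union: int = MIN_UNION,
    observed_ssn: SimilarityNetwork | None = None,
) -> dict:
    """Shuffle cases into clusters of the original sizes; rebuild the SSN.

    Per replicate each stratified disease's cases are randomly permuted
    into clusters with the original size multiset, meta-patient profiles
    refit, the SSN rebuilt, and the positive/negative meta-patient edge
    counts recorded. p = (1 + #{replicate >= observed}) / (1 + n_reps).
    """
    if n_reps < 1:
        raise AnalysisError("n_reps must be >= 1")
    stratified = {d: a for d, a in assignments.items() if not a.unstratified}
    if observed_ssn is None:
        mp_profiles = []
        for disease, a in stratified.items():
            mp_profiles.extend(meta_patient_de(expr_by_disease[disease], a))
        observed_ssn = build_ssn(
            disease_profiles, mp_profiles, metric=metric,
            fdr_threshold=fdr_threshold, min_union=min_union,
        )
    obs_pos, obs_neg = _metapatient_edge_counts(observed_ssn)

    rng = np.random.default_rng(seed)
    pos_counts = np.zeros(n_reps, dtype=int)
    neg_counts = np.zeros(n_reps, dtype=int)
    for r in range(n_reps):
        rep_profiles = []
        for disease, a in stratified.items():
            cases = list(a.labels.index)
            perm = rng.permutation(len(cases))
            shuffled = pd.Series(
                a.labels.to_numpy(), index=[cases[i] for i in perm], name="cluster"
            )
            rep_assign = MetaPatientAssignment(
                disease=disease, method=a.method, chosen_k=a.chosen_k, labels=shuffled
            )
            assert sorted(rep_assign.cluster_sizes.values()) == sorted(a.cluster_sizes.values())
            rep_profiles.extend(meta_patient_de(expr_by_disease[disease], rep_assign))
        net = build_ssn(
            disease_profiles, rep_profiles, metric=metric,
            fdr_threshold=fdr_threshold, min_union=min_union,
        )
        pos_counts[r], neg_counts[r] = _metapatient_edge_counts(net)

    return {
        "observed_positive": obs_pos,
        "observed_negative": obs_neg,
        "p_positive": (1.0 + np.sum(pos_counts >= obs_pos)) / (1.0 + n_reps),
        "p_negative": (1.0 + np.sum(neg_counts >= obs_neg)) / (1.0 + n_reps),
        "replicate_positive": pos_counts,
        "replicate_negative": neg_counts,
        "n_reps": n_reps,
        "seed": seed,
    }
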