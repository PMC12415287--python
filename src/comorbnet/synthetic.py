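"""Synthetic multi-study RNA-seq cohorts with planted comorbidity structure.

Emulates the kind of data the pipeline targets: per-disease case/control
count matrices pooled over several studies, with study batch effects,
planted gene-module disease signatures, optional case subtypes, and a toy
epidemiological comorbidity network that agrees with the planted molecular
similarities to a configurable degree.

Counts follow a negative-binomial model: gene baseline means are drawn
log-normally, each study multiplies every gene by a log-normal batch factor
(sd ``batch_sd`` on the log2 scale), each sample carries a log-normal
library-depth factor, and case samples multiply the genes of their
disease's (or subtype's) modules by ``2**effect``. The planted log2 effects
are recorded in a ``truth`` block that no analysis stage reads.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ConfigError, EpidemiologicalNetwork, SampleTable

__all__ = [
    "GeneModule",
    "DiseaseSpec",
    "CohortConfig",
    "simulate_cohort",
    "simulate_epi_network",
    "null_cohort_config",
    "planted_pair_config",
    "subtype_config",
    "module_gene_sets",
    "icd9_map_from_config",
]


@dataclass
class GeneModule:
    """A coherent set of genes dysregulated together.

    ``effect`` is the baseline log2 fold change applied to module genes in a
    disease carrying the module (scaled per disease by its own effect size).
    ``heterogeneity`` spreads per-gene effect magnitudes as multipliers drawn
    uniformly from [1-h, 1+h]; ``frac_down`` flips the sign of that fraction
    of module genes. Both default to 0, i.e. a uniform single-sign effect.
    The per-gene pattern is intrinsic to the module (deterministic given the
    cohort seed), so two diseases sharing a module share the same pattern —
    which is what makes their differential profiles rank-correlated.
    """

    module_id: str
    genes: np.ndarray  # 0-based indices into the gene universe
    effect: float = 1.0
    heterogeneity: float = 0.0
    frac_down: float = 0.0

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=int)
        if not 0 <= self.frac_down <= 1:
            raise ConfigError("frac_down must be in [0,1]")
        if not 0 <= self.heterogeneity < 1:
            raise ConfigError("heterogeneity must be in [0,1)")

    def pattern(self, cohort_seed: int) -> np.ndarray:
        """Signed per-gene multipliers, deterministic given the cohort seed."""
        tag = zlib.crc32(self.module_id.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng([cohort_seed & 0x7FFFFFFF, tag])
        m = np.ones(len(self.genes))
        if self.heterogeneity > 0:
            m *= rng.uniform(1 - self.heterogeneity, 1 + self.heterogeneity, len(self.genes))
        if self.frac_down > 0:
            n_down = int(round(self.frac_down * len(self.genes)))
            down = rng.choice(len(self.genes), size=n_down, replace=False)
            m[down] *= -1
        return m


@dataclass
class DiseaseSpec:
    """One disease: design (studies, group sizes) plus planted biology.

    ``module_effects`` maps module id -> disease-level multiplier of the
    module's baseline effect (1.0 keeps it, -1.0 inverts it). ``subtypes``
    optionally overrides the effect map per planted case subtype; cases are
    assigned subtypes by ``subtype_proportions`` (default equal).
    """

    name: str
    icd9: str
    category: str = "other"
    n_studies: int = 1
    cases_per_study: int = 20
    controls_per_study: int = 20
    tissue: str = "blood"
    module_effects: dict[str, float] = field(default_factory=dict)
    subtypes: dict[str, dict[str, float]] | None = None
    subtype_proportions: dict[str, float] | None = None


@dataclass
class CohortConfig:
    n_genes: int
    diseases: list[DiseaseSpec]
    modules: list[GeneModule] = field(default_factory=list)
    similarity_plan: list[tuple[str, str, str, float]] = field(default_factory=list)
    batch_sd: float = 0.5
    dispersion: float = 0.1
    lib_sd: float = 0.3
    base_log2_mean: float = 4.0
    base_log2_sd: float = 1.5
    aligned_beta: tuple[float, float] = (2.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if not self.diseases:
            raise ConfigError("at least one disease required")
        if self.batch_sd < 0:
            raise ConfigError("batch_sd must be nonnegative")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be nonnegative")
        names = [d.name for d in self.diseases]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate disease names")
        known = {m.module_id for m in self.modules}
        for d in self.diseases:
            maps = [d.module_effects] + (list(d.subtypes.values()) if d.subtypes else [])
            for eff in maps:
                unknown = set(eff) - known
                if unknown:
                    raise ConfigError(f"disease {d.name}: unknown modules {sorted(unknown)}")
        for m in self.modules:
            if len(m.genes) and (m.genes.min() < 0 or m.genes.max() >= self.n_genes):
                raise ConfigError(f"module {m.module_id}: gene index out of range")
        for a, b, sign, frac in self.similarity_plan:
            if sign not in {"+", "-", "0"}:
                raise ConfigError(f"plan sign must be +, - or 0, got {sign!r}")
            if not 0 <= frac <= 1:
                raise ConfigError("plan overlap fraction must be in [0,1]")
            if a not in names or b not in names:
                raise ConfigError(f"plan pair ({a},{b}) references unknown disease")

    @property
    def gene_ids(self) -> pd.Index:
        width = max(4, len(str(self.n_genes)))
        return pd.Index([f"g{i:0{width}d}" for i in range(self.n_genes)], name="gene")

    def module(self, module_id: str) -> GeneModule:
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)


def _effect_vector(config: CohortConfig, effects: dict[str, float]) -> np.ndarray:
    """Per-gene planted log2 fold change from a module-effect map."""
    vec = np.zeros(config.n_genes)
    for module_id, scale in effects.items():
        m = config.module(module_id)
        vec[m.genes] += scale * m.effect * m.pattern(config.seed)
    return vec


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.maximum(mu, 1e-8)
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_cohort(config: CohortConfig) -> SampleTable:
    """Draw a full multi-disease, multi-study cohort. Deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    base_mean = 2.0 ** rng.normal(config.base_log2_mean, config.base_log2_sd, config.n_genes)

    count_blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    subtype_truth: dict[str, str] = {}
    effect_truth: dict[str, np.ndarray] = {}

    for disease in config.diseases:
        effect_truth[disease.name] = _effect_vector(config, disease.module_effects)
        sub_labels, sub_probs, sub_effects = None, None, None
        if disease.subtypes:
            sub_labels = sorted(disease.subtypes)
            props = disease.subtype_proportions or {s: 1.0 for s in sub_labels}
            total = sum(props[s] for s in sub_labels)
            sub_probs = [props[s] / total for s in sub_labels]
            sub_effects = {
                s: _effect_vector(config, disease.subtypes[s]) for s in sub_labels
            }
            for s in sub_labels:
                effect_truth[f"{disease.name}::{s}"] = sub_effects[s]

        for j in range(disease.n_studies):
            study = f"{disease.name}_st{j + 1}"
            batch = 2.0 ** rng.normal(0.0, config.batch_sd, config.n_genes)
            n_cases, n_ctrl = disease.cases_per_study, disease.controls_per_study
            n = n_cases + n_ctrl
            lib = 2.0 ** rng.normal(0.0, config.lib_sd, n)
            aligned = 60.0 + 40.0 * rng.beta(*config.aligned_beta, n)

            fc = np.ones((config.n_genes, n))
            labels: list[str | None] = []
            if sub_labels is not None:
                # exact largest-remainder allocation so realized subtype
                # proportions match the requested ones, then a random order
                quota = np.array(sub_probs) * n_cases
                alloc = np.floor(quota).astype(int)
                rem = np.argsort(-(quota - alloc), kind="stable")
                for r in rem[: n_cases - alloc.sum()]:
                    alloc[r] += 1
                case_labels = [s for s, c in zip(sub_labels, alloc) for _ in range(c)]
                rng.shuffle(case_labels)
                for i, s in enumerate(case_labels):
                    fc[:, i] = 2.0 ** sub_effects[s]
                    labels.append(s)
            else:
                for i in range(n_cases):
                    fc[:, i] = 2.0 ** effect_truth[disease.name]
                    labels.append(None)
            labels.extend([None] * n_ctrl)

            mu = base_mean[:, None] * batch[:, None] * fc * lib[None, :]
            count_blocks.append(_draw_counts(rng, mu, config.dispersion))

            for i in range(n):
                sid = f"{disease.name}_{study}_s{i + 1:03d}"
                cond = "case" if i < n_cases else "control"
                meta_rows.append(
                    dict(
                        sample_id=sid,
                        disease=disease.name,
                        study=study,
                        tissue=disease.tissue,
                        condition=cond,
                        percent_aligned=round(float(aligned[i]), 2),
                    )
                )
                if labels[i] is not None:
                    subtype_truth[sid] = labels[i]

    metadata = pd.DataFrame(meta_rows)
    counts = pd.DataFrame(
        np.hstack(count_blocks),
        index=config.gene_ids,
        columns=metadata["sample_id"].to_list(),
    )
    truth = {
        "effects": pd.DataFrame(effect_truth, index=config.gene_ids),
        "subtype": pd.Series(subtype_truth, name="subtype", dtype=object),
        "modules": {m.module_id: config.gene_ids[m.genes].to_list() for m in config.modules},
        "config": config,
    }
    return SampleTable(counts=counts, metadata=metadata, truth=truth)


def simulate_epi_network(
    config: CohortConfig,
    agreement: float = 1.0,
    n_noise_edges: int = 0,
    seed: int = 0,
    rr_value: float = 2.0,
) -> EpidemiologicalNetwork:
    """Toy ICD9 comorbidity network matching the planted positive pairs.

    Each planted positive-sign pair enters with probability ``agreement``;
    ``n_noise_edges`` extra edges are drawn uniformly among unplanted ICD9
    pairs. Stands in for a claims-derived relative-risk network.
    """
    if not 0 <= agreement <= 1:
        raise ConfigError("agreement must be in [0,1]")
    rng = np.random.default_rng(seed)
    icd9 = {d.name: d.icd9 for d in config.diseases}
    planted = []
    for a, b, sign, _frac in config.similarity_plan:
        if sign == "+" and icd9[a] != icd9[b]:
            planted.append(frozenset((icd9[a], icd9[b])))
    planted = sorted(set(planted), key=sorted)

    kept = [pair for pair in planted if rng.random() < agreement]

    codes = sorted(set(icd9.values()))
    candidates = [
        frozenset(p)
        for p in itertools.combinations(codes, 2)
        if frozenset(p) not in set(planted)
    ]
    if n_noise_edges > len(candidates):
        raise ConfigError(
            f"n_noise_edges={n_noise_edges} exceeds {len(candidates)} available pairs"
        )
    if n_noise_edges:
        idx = rng.choice(len(candidates), size=n_noise_edges, replace=False)
        kept.extend(candidates[i] for i in sorted(idx))

    rows = [sorted(pair) for pair in kept]
    edges = pd.DataFrame(rows, columns=["icd9_a", "icd9_b"])
    edges["measure"] = "RR"
    edges["value"] = rr_value
    return EpidemiologicalNetwork(edges=edges, measure="RR")


def module_gene_sets(config: CohortConfig) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Gene-set collection derived from the planted modules.

    Emits each full module plus, for bidirectional modules, the
    directionally coherent ``_up`` / ``_dn`` subsets (genes whose intrinsic
    pattern is positive / negative). Real pathway collections are
    directionally coherent, so enrichment fixtures should be too.
    Returns (sets, category labels).
    """
    ids = config.gene_ids
    sets: dict[str, list[str]] = {}
    cats: dict[str, str] = {}
    for m in config.modules:
        pattern = m.pattern(config.seed)
        sets[m.module_id] = ids[m.genes].to_list()
        cats[m.module_id] = "planted-module"
        if (pattern > 0).any() and (pattern < 0).any():
            sets[f"{m.module_id}_up"] = ids[m.genes[pattern > 0]].to_list()
            sets[f"{m.module_id}_dn"] = ids[m.genes[pattern < 0]].to_list()
            cats[f"{m.module_id}_up"] = "planted-module-directional"
            cats[f"{m.module_id}_dn"] = "planted-module-directional"
    return sets, cats


def icd9_map_from_config(config: CohortConfig) -> pd.DataFrame:
    """disease -> 3-digit ICD9 code and category, as the mapping table."""
    return pd.DataFrame(
        [(d.name, d.icd9, d.category) for d in config.diseases],
        columns=["disease", "icd9", "category"],
    )


# ---------------------------------------------------------------------------
# Canned study designs used by the analysis drivers and the test-bench.
# Module sizes, effect spreads and group sizes are the package's standing
# simulation conditions (see docs/methods.md).
# ---------------------------------------------------------------------------

_CATEGORIES = (
    "infectious",
    "neoplasms",
    "endocrine",
    "mental",
    "nervous",
    "circulatory",
    "respiratory",
    "digestive",
)


def _mk_disease(i: int, **kw) -> DiseaseSpec:
    return DiseaseSpec(
        name=f"D{i:02d}",
        icd9=f"{i + 1:03d}",
        category=_CATEGORIES[i % len(_CATEGORIES)],
        **kw,
    )


def null_cohort_config(
    n_diseases: int = 20,
    n_genes: int = 2000,
    cases: int = 10,
    controls: int = 10,
    n_studies: int = 1,
    batch_sd: float = 0.5,
    seed: int = 0,
) -> CohortConfig:
    """No planted effects anywhere: cases and controls are exchangeable."""
    diseases = [
        _mk_disease(i, n_studies=n_studies, cases_per_study=cases, controls_per_study=controls)
        for i in range(n_diseases)
    ]
    return CohortConfig(n_genes=n_genes, diseases=diseases, seed=seed)


def planted_pair_config(
    n_pos_pairs: int = 10,
    n_neg_pairs: int = 5,
    n_genes: int = 2000,
    module_size: int = 120,
    effect: float = 2.0,
    cases: int = 20,
    controls: int = 20,
    seed: int = 0,
) -> CohortConfig:
    """Disjoint disease pairs sharing one heterogeneous module each.

    Positive pairs carry the module with the same sign, negative pairs with
    opposite signs; per-gene magnitudes spread over [0.5, 1.5]x with 30% of
    genes down-regulated so paired differential profiles are rank-correlated.
    """
    n_diseases = 2 * (n_pos_pairs + n_neg_pairs)
    needed = (n_pos_pairs + n_neg_pairs) * module_size
    if needed > n_genes:
        raise ConfigError("not enough genes for the requested modules")
    modules, diseases, plan = [], [], []
    gene_cursor = 0
    for p in range(n_pos_pairs + n_neg_pairs):
        mid = f"M{p + 1:02d}"
        genes = np.arange(gene_cursor, gene_cursor + module_size)
        gene_cursor += module_size
        modules.append(
            GeneModule(mid, genes, effect=effect, heterogeneity=0.5, frac_down=0.5)
        )
        i, j = 2 * p, 2 * p + 1
        sign = "+" if p < n_pos_pairs else "-"
        da = _mk_disease(i, cases_per_study=cases, controls_per_study=controls,
                         module_effects={mid: 1.0})
        db = _mk_disease(j, cases_per_study=cases, controls_per_study=controls,
                         module_effects={mid: 1.0 if sign == "+" else -1.0})
        diseases.extend([da, db])
        plan.append((da.name, db.name, sign, 1.0))
    assert len(diseases) == n_diseases
    return CohortConfig(
        n_genes=n_genes, diseases=diseases, modules=modules,
        similarity_plan=plan, seed=seed,
    )


def subtype_config(
    n_genes: int = 1200,
    module_size: int = 200,
    effect: float = 2.0,
    cases_per_subtype: int = 15,
    controls: int = 20,
    partner_cases: int = 20,
    seed: int = 0,
    proportions: tuple[float, float] = (0.5, 0.5),
    n_partners: int = 1,
) -> CohortConfig:
    """A two-subtype disease whose subtypes have opposite module effects.

    Disease ``D00`` has two planted subtypes: subtype ``s1`` carries the
    shared module with effect +1x, ``s2`` with -1x, so at the pooled
    disease level the signal cancels (exactly so with equal proportions).
    Partner disease ``D01`` (and, with ``n_partners`` > 1, additional
    partners ``D04``, ``D05``, ...) carries the module with +1x and
    therefore correlates with the ``s1`` meta-patient only. Two decoy
    diseases ``D02``/``D03`` carry an unrelated module and nothing,
    respectively. Total cases for ``D00`` stay at 2 * cases_per_subtype;
    ``proportions`` splits them between s1 and s2.
    """
    m_shared = GeneModule("Mshared", np.arange(module_size), effect=effect,
                          heterogeneity=0.5, frac_down=0.5)
    m_decoy = GeneModule("Mdecoy", np.arange(module_size, 2 * module_size),
                         effect=effect, heterogeneity=0.5, frac_down=0.5)
    if 2 * module_size > n_genes:
        raise ConfigError("not enough genes for the modules")
    target = DiseaseSpec(
        name="D00", icd9="001", category=_CATEGORIES[0],
        cases_per_study=2 * cases_per_subtype, controls_per_study=controls,
        subtypes={"s1": {"Mshared": 1.0}, "s2": {"Mshared": -1.0}},
        subtype_proportions={"s1": proportions[0], "s2": proportions[1]},
    )
    partner = DiseaseSpec(
        name="D01", icd9="002", category=_CATEGORIES[1],
        cases_per_study=partner_cases, controls_per_study=controls,
        module_effects={"Mshared": 1.0},
    )
    decoy1 = DiseaseSpec(
        name="D02", icd9="003", category=_CATEGORIES[2],
        cases_per_study=partner_cases, controls_per_study=controls,
        module_effects={"Mdecoy": 1.0},
    )
    decoy2 = DiseaseSpec(
        name="D03", icd9="004", category=_CATEGORIES[3],
        cases_per_study=partner_cases, controls_per_study=controls,
    )
    extra_partners = [
        DiseaseSpec(
            name=f"D{3 + j:02d}", icd9=f"{4 + j:03d}",
            category=_CATEGORIES[(3 + j) % len(_CATEGORIES)],
            cases_per_study=partner_cases, controls_per_study=controls,
            module_effects={"Mshared": 1.0},
        )
        for j in range(1, n_partners)
    ]
    plan = [("D00", "D01", "0", 1.0)]
    return CohortConfig(
        n_genes=n_genes,
        diseases=[target, partner, decoy1, decoy2, *extra_partners],
        modules=[m_shared, m_decoy],
        similarity_plan=plan,
        seed=seed,
    )
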