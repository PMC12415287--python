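#!/usr/bin/env python
"""Pathway-level characterization of diseases and network edges.

Runs preranked GSEA (logFC ranking, gene-label permutations) for every
disease against the module gene sets plus random decoy sets, clusters
diseases on their binarized NES signatures (Ward2 on Euclidean distance),
and profiles the DSN's positive edges for pathways shared in the same
direction by both endpoints, split into epidemiological (EI) and
nonepidemiological (NEI) interactions. Writes results/enrichment/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from comorbnet.enrichment import (
    GeneSetCollection,
    binarize_and_cluster,
    gsea_preranked,
    shared_pathways_by_edge,
)
from comorbnet.io import read_epi_network, read_gmt, read_icd9_map, read_sample_table
from comorbnet.pipeline import build_dsn, disease_expression, disease_profiles

SEED = 42


def build_collection(modules: dict[str, list[str]], all_genes: list[str]) -> GeneSetCollection:
    """Fixture modules (full + directional subsets) plus random decoys."""
    sets = dict(modules)
    category = {
        name: ("planted-module-directional" if name.endswith(("_up", "_dn"))
               else "planted-module")
        for name in modules
    }
    rng = np.random.default_rng(SEED + 7)
    for j in range(10):
        name = f"decoy{j:02d}"
        sets[name] = list(rng.choice(all_genes, size=60, replace=False))
        category[name] = "decoy"
    return GeneSetCollection(sets=sets, category=category)


def main() -> None:
    fixtures = ROOT / "results" / "fixtures"
    table = read_sample_table(fixtures / "counts.tsv", fixtures / "metadata.tsv")
    icd9 = read_icd9_map(fixtures / "icd9_map.tsv")
    epi = read_epi_network(fixtures / "epidemiology.tsv")
    modules = read_gmt(fixtures / "modules.gmt")
    collection = build_collection(modules, list(table.counts.index))

    expr = disease_expression(table)
    profiles = disease_profiles(expr)
    results = {}
    for prof in profiles:
        results[prof.phenotype] = gsea_preranked(
            prof, collection, n_perm=2000, seed=SEED, min_size=5,
        )

    outdir = ROOT / "results" / "enrichment"
    outdir.mkdir(parents=True, exist_ok=True)
    long = pd.concat(
        {k: v.table for k, v in results.items()}, names=["disease", "set"]
    ).reset_index()
    long.to_csv(outdir / "gsea_results.tsv", sep="\t", index=False)
    n_sig = long[long["fdr"] <= 0.05].groupby("disease").size()
    print("significant pathway counts per disease (nonzero):")
    print(n_sig.to_string())

    mat, z, order = binarize_and_cluster(results)
    mat.to_csv(outdir / "binarized_nes.tsv", sep="\t")
    print(f"binarized NES matrix: {mat.shape[0]} pathways x {mat.shape[1]} diseases")

    dsn, _ = build_dsn(table, icd9_map=icd9, seed=SEED)
    for direction in ("up", "down"):
        tab = shared_pathways_by_edge(dsn, epi, results, collection, direction=direction)
        tab.to_csv(outdir / f"shared_pathways_{direction}.tsv", sep="\t")
        print(f"\nshared {direction}-regulated pathways by edge class:")
        print(tab[["n_ei", "n_nei", "pct_ei_sharing", "pct_nei_sharing",
                   "mean_shared_ei", "mean_shared_nei"]].round(2).to_string())


if __name__ == "__main__":
    main()
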