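#!/usr/bin/env python
"""Build the Disease Similarity Network.

Edges are Spearman correlations of logFC over each pair's sDEG union,
kept at joint BH FDR <= 0.05. Also builds the cosine-similarity variant,
tests whether the two agree (Fisher), and summarizes the topology of the
positive and negative subnetworks. Writes edge lists and a topology table
under results/dsn/.
"""

import json
import sys
from dataclasses import asdict
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from comorbnet.io import read_icd9_map, read_sample_table
from comorbnet.overlap import compare_networks
from comorbnet.pipeline import build_dsn
from comorbnet.topology import summarize

SEED = 42


def main() -> None:
    fixtures = ROOT / "results" / "fixtures"
    table = read_sample_table(fixtures / "counts.tsv", fixtures / "metadata.tsv")
    icd9 = read_icd9_map(fixtures / "icd9_map.tsv")

    dsn, _ = build_dsn(table, metric="spearman", icd9_map=icd9, seed=SEED)
    cosine, _ = build_dsn(table, metric="cosine", icd9_map=icd9, seed=SEED)

    outdir = ROOT / "results" / "dsn"
    outdir.mkdir(parents=True, exist_ok=True)
    dsn.edges.to_csv(outdir / "dsn_edges.tsv", sep="\t", index=False)
    cosine.edges.to_csv(outdir / "dsn_cosine_edges.tsv", sep="\t", index=False)

    n_pos = int((dsn.edges["weight"] > 0).sum())
    n_neg = int((dsn.edges["weight"] < 0).sum())
    print(f"DSN: {len(dsn.edges)} edges ({n_pos} positive, {n_neg} negative)")
    print(f"cosine DSN: {len(cosine.edges)} edges")

    for sign, net_name in [("positive", "dsn"), ("negative", "dsn")]:
        cats = dict(zip(dsn.nodes["id"], dsn.nodes["category"]))
        s = summarize(dsn, sign=sign, categories=cats)
        with open(outdir / f"topology_{sign}.json", "w") as fh:
            json.dump(asdict(s), fh, indent=2, default=float)
        print(f"topology ({sign}): components={s.n_components} "
              f"mean_degree={s.mean_degree:.2f} density={s.density:.3f} "
              f"transitivity={s.mean_transitivity:.3f}")

    for sign in ("positive", "negative"):
        orr, p = compare_networks(cosine, dsn, sign=sign)
        print(f"cosine vs spearman enrichment ({sign}): OR={orr:.2f}, Fisher p={p:.2e}")


if __name__ == "__main__":
    main()
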