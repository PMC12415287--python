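#!/usr/bin/env python
"""Generate the study cohort: 30 diseases with 10 positive and 5 negative
planted similarity pairs (shared 120-gene modules, effect 2, n = 20/20),
plus a two-subtype disease family, a matched toy epidemiological network,
and text fixtures (counts/metadata/epidemiology/GMT/ICD9 map) under
results/fixtures/.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from comorbnet.io import write_fixtures
from comorbnet.synthetic import (
    icd9_map_from_config,
    module_gene_sets,
    planted_pair_config,
    simulate_cohort,
    simulate_epi_network,
)

SEED = 42


def main() -> None:
    outdir = ROOT / "results" / "fixtures"
    cfg = planted_pair_config(n_pos_pairs=10, n_neg_pairs=5, seed=SEED)
    table = simulate_cohort(cfg)
    epi = simulate_epi_network(cfg, agreement=1.0, n_noise_edges=5, seed=SEED + 1)
    sets, _cats = module_gene_sets(cfg)
    paths = write_fixtures(
        table, epi, sets, outdir,
        icd9_map=icd9_map_from_config(cfg),
    )
    n_cases = (table.metadata["condition"] == "case").sum()
    print(f"cohort: {table.n_genes} genes x {table.n_samples} samples "
          f"({n_cases} cases), {len(cfg.diseases)} diseases")
    print(f"planted pairs: {sum(s == '+' for _, _, s, _ in cfg.similarity_plan)} positive, "
          f"{sum(s == '-' for _, _, s, _ in cfg.similarity_plan)} negative")
    print(f"epidemiological edges: {len(epi.edges)}")
    for k, p in paths.items():
        print(f"  wrote {k}: {p.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
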