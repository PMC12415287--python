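#!/usr/bin/env python
"""Per-disease differential-expression fingerprints.

Reads the fixture cohort, applies QC (>= 70% aligned reads, >= 3 cases per
study), normalizes each disease (log2CPM, low-expression filter, TMM) and
fits the study-adjusted moderated-t model. Writes one profile TSV per
disease plus a summary table of sDEG counts under results/profiles/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from comorbnet.io import read_sample_table
from comorbnet.pipeline import disease_expression, disease_profiles


def main() -> None:
    fixtures = ROOT / "results" / "fixtures"
    table = read_sample_table(fixtures / "counts.tsv", fixtures / "metadata.tsv")
    expr = disease_expression(table)
    profiles = disease_profiles(expr)

    outdir = ROOT / "results" / "profiles"
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for prof in profiles:
        out = outdir / f"{prof.phenotype}.tsv"
        prof.table.to_csv(out, sep="\t")
        rows.append(
            dict(
                disease=prof.phenotype,
                n_genes=len(prof.genes),
                n_sdegs=len(prof.sdegs),
                d0=round(prof.d0, 3),
                s02=round(prof.s02, 4),
            )
        )
    summary = pd.DataFrame(rows).sort_values("disease")
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\n{len(profiles)} disease profiles written to {outdir.relative_to(ROOT)}/")


if __name__ == "__main__":
    main()
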