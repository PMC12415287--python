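"""Plain-text readers/writers for the pipeline's exchange formats.

Counts and metadata travel as TSV, gene sets as GMT (name, description,
then tab-separated genes), the comorbidity network as an ICD9 edge-list TSV
and the disease -> ICD9 mapping as a two-column TSV. Everything round-trips
bit-identically through pandas.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .datatypes import ConfigError, EpidemiologicalNetwork, SampleTable


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "disease": str, "study": str})


def read_sample_table(counts_path: str | Path, metadata_path: str | Path) -> SampleTable:
    return SampleTable(counts=read_counts(counts_path), metadata=read_metadata(metadata_path))


def write_epi_network(epi: EpidemiologicalNetwork, path: str | Path) -> None:
    epi.edges.to_csv(path, sep="\t", index=False)


def read_epi_network(path: str | Path, measure: str | None = None) -> EpidemiologicalNetwork:
    edges = pd.read_csv(path, sep="\t", dtype={"icd9_a": str, "icd9_b": str})
    if measure is None:
        measure = str(edges["measure"].iloc[0]) if len(edges) else "RR"
    return EpidemiologicalNetwork(edges=edges, measure=measure)


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sets:
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *map(str, sets[name])]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ConfigError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = parts[2:]
    return sets


def write_icd9_map(icd9_map: pd.DataFrame, path: str | Path) -> None:
    icd9_map.to_csv(path, sep="\t", index=False)


def read_icd9_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"disease": str, "icd9": str, "category": str})


def write_fixtures(
    table: SampleTable,
    epi: EpidemiologicalNetwork,
    gene_modules: dict[str, list[str]],
    outdir: str | Path,
    icd9_map: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Emit a complete text fixture set for one cohort under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "epi": outdir / "epidemiology.tsv",
        "gmt": outdir / "modules.gmt",
    }
    write_counts(table.counts, paths["counts"])
    write_metadata(table.metadata, paths["metadata"])
    write_epi_network(epi, paths["epi"])
    write_gmt(gene_modules, paths["gmt"])
    if icd9_map is not None:
        paths["icd9_map"] = outdir / "icd9_map.tsv"
        write_icd9_map(icd9_map, paths["icd9_map"])
    return paths
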