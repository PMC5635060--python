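"""Readers and writers for the plain-text interchange formats.

Matrices travel as TSV with genes as rows (first column ``gene``), samples
as columns.  Clinical tables are CSV, mutations a MAF-like TSV
(gene, sample, class), gene sets GMT, configs YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .matrix import OmicsMatrix, Platform, ProbeAnnotation, Scale

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_gmt",
    "write_gmt",
    "read_mutations_maf",
    "write_mutations_maf",
    "read_probe_annotation",
    "write_probe_annotation",
    "load_config",
    "dump_config",
]


def write_matrix_tsv(m: OmicsMatrix, path) -> None:
    df = m.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path, platform: Platform | str, scale: Scale | str) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return OmicsMatrix(platform=Platform(platform), values=df, scale=Scale(scale))


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "cnvmet") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *map(str, genes)]) + "\n")


_MAF_COLS = ["gene", "sample", "variant_class"]


def write_mutations_maf(mut: pd.DataFrame, path, variant_class: str = "Missense_Mutation") -> None:
    """Write a binary gene x tumor mutation matrix as a MAF-like long table.

    A cohort with zero mutations still yields a valid, header-only file.
    """
    rows = []
    for gene in mut.index:
        hit = mut.columns[mut.loc[gene].astype(bool)]
        rows.extend((gene, s, variant_class) for s in hit)
    pd.DataFrame(rows, columns=_MAF_COLS).to_csv(path, sep="\t", index=False)


def read_mutations_maf(path, genes=None, samples=None) -> pd.DataFrame:
    """Read a MAF-like table back into a binary gene x sample matrix.

    ``genes``/``samples`` fix the full index (so unmutated rows/columns are
    preserved); by default the matrix spans only observed genes/samples.
    """
    long = pd.read_csv(path, sep="\t")
    missing = [c for c in _MAF_COLS[:2] if c not in long.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    genes = list(genes) if genes is not None else sorted(long["gene"].unique())
    samples = list(samples) if samples is not None else sorted(long["sample"].unique())
    mat = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=samples, dtype=int)
    for _, row in long.iterrows():
        if row["gene"] in mat.index and row["sample"] in mat.columns:
            mat.loc[row["gene"], row["sample"]] = 1
    return mat


def write_probe_annotation(ann: ProbeAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_probe_annotation(path) -> ProbeAnnotation:
    return ProbeAnnotation(pd.read_csv(path, sep="\t"))


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def dump_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2))
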