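"""Readers and writers for the pipeline's delimited-text table formats.

Everything is plain TSV (or GMT for gene sets, JSON for the manifest and
ground truth), so runs are diffable and reproducible byte-for-byte.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .preprocess import IntensityTable, MethylationMatrix


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "age", "cigarettes_total", "ic50"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table is missing columns {sorted(missing)}")
    return df


write_sample_table = write_tsv


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"gene": str, "chromosome": str})
    df["snp_overlap"] = df["snp_overlap"].astype(int).astype(bool)
    df["position"] = df["position"].astype(int)
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["snp_overlap"] = out["snp_overlap"].astype(int)
    write_tsv(out, path)


def read_intensities(path) -> IntensityTable:
    return IntensityTable.from_long(pd.read_csv(path, sep="\t"))


def write_intensities(table: IntensityTable, path) -> None:
    write_tsv(table.to_long(), path)


def read_matrix(path, scale: str) -> MethylationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return MethylationMatrix(df, scale)


def write_matrix(matrix: MethylationMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_gwas_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    df["position"] = df["position"].astype(int)
    return df


write_gwas_catalog = write_tsv


def read_gmt(path) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Parse a GMT file: one set per line, tab-separated
    ``id <TAB> description <TAB> gene1 <TAB> gene2 ...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
            descriptions[fields[0]] = fields[1]
    return sets, descriptions


def write_gmt(sets: Mapping[str, Sequence[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for set_id, genes in sets.items():
            desc = (descriptions or {}).get(set_id, set_id)
            fh.write("\t".join([set_id, desc, *genes]) + "\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Sequence[str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
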