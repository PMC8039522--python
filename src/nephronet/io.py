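"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV with one header row. Expression: rows = genes, first
column the gene ID. Metadata: sample_id, diagnosis, batch, study, numeric
covariates. Gene sets: standard GMT (name, description, members). Gene
annotations: TSV (1-based inclusive) or BED (0-based half-open, converted
on read). Floats are written with a fixed format so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.10g"


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("gene").to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene IDs in expression table")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample IDs in expression table")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample_id").to_csv(path, sep="\t",
                                             float_format=FLOAT_FMT)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    if "diagnosis" in df.columns:
        bad = set(df["diagnosis"].unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown diagnosis level(s): {sorted(bad)}")
    return df


def write_probe_map(probe_map: pd.DataFrame, path) -> None:
    probe_map.to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"probe_id", "gene_id"}.issubset(df.columns):
        raise ValueError("probe map needs columns probe_id, gene_id")
    return df


def write_snps(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_snps(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    """TSV gene annotation (gene, chr, start, stop; 1-based inclusive) or
    BED (chr, start, stop, gene; 0-based half-open, converted)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chr", "start", "stop", "gene"],
                         usecols=range(4))
        df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
        df = df[["gene", "chr", "start", "stop"]]
    else:
        df = pd.read_csv(path, sep="\t")
    if not {"gene", "chr", "start", "stop"}.issubset(df.columns):
        raise ValueError("annotation needs columns gene, chr, start, stop")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene IDs in annotation")
    return df


def write_gmt(collection: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = (descriptions or {}).get(name, "na")
            genes = "\t".join(collection[name])
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_gmt(path) -> dict:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_truth(truth, path) -> None:
    payload = {
        "module_assignment": truth.module_assignment.to_dict(),
        "hub_weights": truth.hub_weights.to_dict(),
        "disease_effects": truth.disease_effects,
        "batch_offsets": (truth.batch_offsets.to_dict()
                          if truth.batch_offsets is not None else None),
        "marker_map": truth.marker_map,
        "gwas_enriched_module": truth.gwas_enriched_module,
        "seed": truth.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def write_linkage(Z: np.ndarray, path) -> None:
    """Serialize a merge list: child_a, child_b, height, n_leaves per row."""
    df = pd.DataFrame(Z, columns=["child_a", "child_b", "height", "n_leaves"])
    df["child_a"] = df["child_a"].astype(int)
    df["child_b"] = df["child_b"].astype(int)
    df["n_leaves"] = df["n_leaves"].astype(int)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_linkage(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df[["child_a", "child_b", "height", "n_leaves"]].to_numpy(dtype=float)
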