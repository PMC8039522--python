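"""End-to-end orchestration: config validation, stage ordering, reporting.

Stage order: QC/normalization per dataset -> cross-study gene intersection
and DGE overlap -> network construction (datasets merged only when their
DGE overlap is significant, with dataset-as-batch empirical-Bayes
adjustment) -> module-trait association -> cell-type and gene-set
enrichment -> GWAS enrichment. One global seed deterministically derives
every stage seed through numpy's SeedSequence spawning, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .association import associate_covariates, associate_modules
from .dge import fit_dge, rank_overlap_pairs, severity_slope, transcriptome_overlap
from .enrichment import (celltype_specific_sets, collapse_reference,
                         fisher_enrichment, ora_genesets, psi_pvalue)
from .gwas import gene_level_p, load_gene_level_stats, map_snps_to_genes, \
    module_gwas_enrichment
from .network import (NetworkParams, bicor_matrix, detect_modules,
                      eigengene_matrix, hclust_average, kme,
                      robustness_consensus, signed_adjacency,
                      tom_dissimilarity)
from .preprocess import (adjust_batch_empirical_bayes, check_balance,
                         collapse_probes, intersect_genes, log2_transform,
                         quantile_normalize, remove_outliers)

KNOWN_TOP_KEYS = {
    "seed", "outdir", "datasets", "preprocess", "dge", "network",
    "enrichment", "gwas", "merge_overlap_p",
}
KNOWN_DATASET_KEYS = {"name", "expression", "metadata", "probe_map"}
KNOWN_PREPROCESS_KEYS = {"already_log2", "log2_offset", "z_threshold",
                         "max_iterations", "batch_col", "preserve"}
KNOWN_DGE_KEYS = {"covariates", "random_intercept", "n_permutations"}
KNOWN_NETWORK_KEYS = {"beta", "min_module_size", "deep_split",
                      "merge_cut_height", "n_resamples", "resample_fraction",
                      "kme_method", "pick_beta", "r2_target"}
KNOWN_ENRICHMENT_KEYS = {"reference", "gmt", "psi_threshold",
                         "n_permutations", "min_size", "max_size"}
KNOWN_GWAS_KEYS = {"snps", "annotation", "gene_stats", "window",
                   "alternative"}


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    datasets: list
    preprocess: dict = field(default_factory=dict)
    dge: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=dict)
    merge_overlap_p: float = 0.05

    def network_params(self, seed: int) -> NetworkParams:
        kw = {k: v for k, v in self.network.items()
              if k not in ("pick_beta", "r2_target")}
        return NetworkParams(seed=seed, **kw)


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config; collect all problems."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems = []
    for key in raw:
        if key not in KNOWN_TOP_KEYS:
            problems.append(f"unknown key {key!r}")
    if "seed" not in raw:
        problems.append("missing mandatory key 'seed'")
    if not raw.get("datasets"):
        problems.append("no datasets configured")
    base = Path(path).parent
    for i, ds in enumerate(raw.get("datasets") or []):
        for key in ds:
            if key not in KNOWN_DATASET_KEYS:
                problems.append(f"datasets[{i}]: unknown key {key!r}")
        for req in ("name", "expression", "metadata"):
            if req not in ds:
                problems.append(f"datasets[{i}]: missing {req!r}")
        for fkey in ("expression", "metadata", "probe_map"):
            if fkey in ds and not (base / ds[fkey]).exists():
                problems.append(f"datasets[{i}]: path {ds[fkey]!r} not found")
    for section, known in (("preprocess", KNOWN_PREPROCESS_KEYS),
                           ("dge", KNOWN_DGE_KEYS),
                           ("network", KNOWN_NETWORK_KEYS),
                           ("enrichment", KNOWN_ENRICHMENT_KEYS),
                           ("gwas", KNOWN_GWAS_KEYS)):
        for key in raw.get(section) or {}:
            if key not in known:
                problems.append(f"{section}: unknown key {key!r}")
    net = raw.get("network") or {}
    if net.get("min_module_size", 100) < 2:
        problems.append("network.min_module_size must be >= 2")
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    cfg = PipelineConfig(
        seed=int(raw["seed"]),
        outdir=str(raw.get("outdir", "nephronet_out")),
        datasets=[dict(ds, expression=str(base / ds["expression"]),
                       metadata=str(base / ds["metadata"]),
                       **({"probe_map": str(base / ds["probe_map"])}
                          if "probe_map" in ds else {}))
                  for ds in raw["datasets"]],
        preprocess=raw.get("preprocess") or {},
        dge=raw.get("dge") or {},
        network=raw.get("network") or {},
        enrichment=_resolve_paths(raw.get("enrichment") or {}, base,
                                  ("reference", "gmt")),
        gwas=_resolve_gwas_paths(raw.get("gwas") or {}, base),
        merge_overlap_p=float(raw.get("merge_overlap_p", 0.05)),
    )
    # surface NetworkParams validation errors at config time
    cfg.network_params(seed=0)
    return cfg


def _resolve_paths(section: dict, base: Path, keys) -> dict:
    out = dict(section)
    for k in keys:
        if out.get(k):
            out[k] = str((base / out[k]))
    return out


def _resolve_gwas_paths(section: dict, base: Path) -> dict:
    out = _resolve_paths(section, base, ("annotation",))
    for key in ("snps", "gene_stats"):
        if out.get(key):
            out[key] = [dict(e, path=str(base / e["path"])) for e in out[key]]
    return out


def _stage_seeds(seed: int, names) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(names, children)}


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_all(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the run report (also written
    to ``<outdir>/run_report.json``)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["dge", "network", "enrichment", "gwas"])
    report = {"seed": config.seed, "stage_seeds": seeds, "stages": {},
              "version": _version()}

    # ---- stage 1: preprocess each dataset -------------------------------
    pp = config.preprocess
    processed = {}
    for ds in config.datasets:
        name = ds["name"]
        _log("preprocess", f"dataset {name}")
        mat = io.read_expression(ds["expression"])
        meta = io.read_metadata(ds["metadata"])
        if "probe_map" in ds:
            mat = collapse_probes(mat, io.read_probe_map(ds["probe_map"]))
        mat = log2_transform(mat, offset=pp.get("log2_offset", 0.0),
                             already_log2=pp.get("already_log2", True))
        mat = quantile_normalize(mat)
        mat, meta, qc = remove_outliers(
            mat, meta.loc[mat.columns],
            z_threshold=pp.get("z_threshold", -2.0),
            max_iterations=pp.get("max_iterations", 10))
        qc.balance = check_balance(meta)
        if meta[pp.get("batch_col", "batch")].nunique() > 1:
            mat = adjust_batch_empirical_bayes(
                mat, meta, batch_col=pp.get("batch_col", "batch"),
                preserve=pp.get("preserve", ["diagnosis"]))
        io.write_expression(mat, out / f"{name}.preprocessed.tsv")
        io.write_json(qc.to_dict(), out / f"{name}.qc.json")
        processed[name] = (mat, meta)
    names = list(processed)
    report["stages"]["preprocess"] = {
        "datasets": names,
        "n_samples": {n: processed[n][0].shape[1] for n in names},
    }

    # ---- stage 2: DGE + overlap ----------------------------------------
    _, mats = intersect_genes([processed[n][0] for n in names]) \
        if len(names) > 1 else (list(processed[names[0]][0].index),
                                [processed[names[0]][0]])
    dge_tables = {}
    for n, mat in zip(names, mats):
        meta = processed[n][1]
        dge_tables[n] = fit_dge(
            mat, meta, covariates=config.dge.get("covariates", []),
            random_intercept=config.dge.get("random_intercept"),
            dataset_id=n)
        io.write_table(dge_tables[n].reset_index(), out / f"{n}.dge.tsv")
    overlaps, slopes = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            ov = transcriptome_overlap(
                dge_tables[a], dge_tables[b],
                n_permutations=config.dge.get("n_permutations", 1000),
                seed=seeds["dge"] + i * len(names) + j, pair=(a, b))
            overlaps.append(ov)
            slopes.append(severity_slope(dge_tables[a], dge_tables[b],
                                         reference=a, target=b))
    if overlaps:
        io.write_table(rank_overlap_pairs(overlaps), out / "overlap_pairs.tsv")
        io.write_json([o.to_dict() for o in overlaps], out / "overlaps.json")
        io.write_json([s.to_dict() for s in slopes], out / "slopes.json")
    report["stages"]["dge"] = {
        "n_genes": int(mats[0].shape[0]),
        "significant_pairs": [list(o.pair) for o in overlaps
                              if o.p < config.merge_overlap_p],
    }

    # ---- stage 3: network ----------------------------------------------
    # merge datasets connected through significant overlaps (union-find)
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for o in overlaps:
        if o.p < config.merge_overlap_p:
            a, b = o.pair
            parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for n in names:
        groups.setdefault(find(n), []).append(n)
    net_results = {}
    for root, members in sorted(groups.items()):
        label = "+".join(sorted(members))
        _log("network", f"group {label}")
        if len(members) > 1:
            _, sub = intersect_genes([processed[m][0] for m in members])
            merged = pd.concat(sub, axis=1)
            meta = pd.concat([processed[m][1] for m in members], axis=0)
            meta = meta.assign(dataset=np.repeat(
                members, [processed[m][0].shape[1] for m in members]))
            merged = adjust_batch_empirical_bayes(
                merged, meta, batch_col="dataset", preserve=["diagnosis"])
        else:
            merged, meta = processed[members[0]]
            meta = meta.assign(dataset=members[0])
        params = config.network_params(seed=seeds["network"])
        if config.network.get("pick_beta", False):
            from .network import pick_soft_threshold
            params.beta = pick_soft_threshold(
                merged.to_numpy(), r2_target=config.network.get("r2_target", 0.8))
        full = detect_modules(merged, params)
        if params.n_resamples > 0 and len(full.modules) > 0:
            stability, part = robustness_consensus(merged, params, full)
        else:
            stability = pd.Series(1.0, index=merged.index, name="stability")
            part = full
        ME = eigengene_matrix(merged, part)
        K = kme(merged, ME, method=params.kme_method)
        Z = hclust_average(tom_dissimilarity(signed_adjacency(
            bicor_matrix(merged.to_numpy()), params.beta)))
        io.write_linkage(Z, out / f"{label}.dendrogram.tsv")
        part_table = pd.DataFrame({
            "gene": part.labels.index, "module": part.labels.to_numpy(),
            "stability": stability.reindex(part.labels.index).to_numpy(),
            "kME_own": [K.loc[g, m] if m in K.columns else np.nan
                        for g, m in part.labels.items()],
        })
        io.write_table(part_table, out / f"{label}.modules.tsv")
        io.write_table(K.rename_axis("gene").reset_index(), out / f"{label}.kme.tsv")
        io.write_table(ME.rename_axis("module").reset_index(),
                       out / f"{label}.eigengenes.tsv")
        net_results[label] = (merged, meta, part, ME, K)
    report["stages"]["network"] = {
        label: {"n_modules": len(part.modules),
                "grey_fraction": part.grey_fraction(),
                "module_sizes": {m: int((part.labels == m).sum())
                                 for m in part.modules}}
        for label, (_, _, part, _, _) in net_results.items()
    }

    # ---- stage 4: module association ------------------------------------
    assoc_summary = {}
    for label, (merged, meta, part, ME, K) in net_results.items():
        if ME.shape[0] == 0:
            continue
        ri = "dataset" if meta["dataset"].nunique() > 1 else None
        table = associate_modules(ME, meta, traits=("diagnosis",),
                                  random_intercept=ri)
        io.write_table(table, out / f"{label}.module_trait.tsv")
        numeric = [c for c in ("rin", "bias_53") if c in meta.columns]
        if numeric:
            cov = associate_covariates(ME, meta, covariates=numeric)
            io.write_table(cov, out / f"{label}.module_covariates.tsv")
        assoc_summary[label] = int((table["q"] < 0.05).sum())
    report["stages"]["association"] = {"significant_modules": assoc_summary}

    # ---- stage 5: enrichment --------------------------------------------
    enr = config.enrichment
    enr_summary = {}
    for label, (merged, meta, part, ME, K) in net_results.items():
        background = list(merged.index)
        module_sets = {m: list(part.members(m)) for m in part.modules}
        if not module_sets:
            continue
        if enr.get("reference"):
            ref = collapse_reference(io.read_expression(enr["reference"]))
            p_tab = psi_pvalue(ref, n_permutations=enr.get("n_permutations", 1000),
                               seed=seeds["enrichment"])
            ct_sets = celltype_specific_sets(
                p_tab, psi_threshold=enr.get("psi_threshold", 0.05))
            fish = fisher_enrichment(module_sets, ct_sets, background)
            io.write_table(fish, out / f"{label}.celltype_enrichment.tsv")
            enr_summary.setdefault(label, {})["celltype_hits"] = \
                int((fish["q"] < 0.05).sum())
        if enr.get("gmt"):
            collection = io.read_gmt(enr["gmt"])
            frames = []
            for m, genes in module_sets.items():
                t = ora_genesets(genes, collection, background,
                                 min_size=enr.get("min_size", 10),
                                 max_size=enr.get("max_size", 2000))
                t.insert(0, "module", m)
                frames.append(t)
            ora = pd.concat(frames, ignore_index=True)
            io.write_table(ora, out / f"{label}.geneset_ora.tsv")
            enr_summary.setdefault(label, {})["geneset_hits"] = \
                int((ora["q"] < 0.05).sum())
    report["stages"]["enrichment"] = enr_summary

    # ---- stage 6: GWAS enrichment ---------------------------------------
    gw = config.gwas
    gwas_summary = {}
    if gw.get("snps") or gw.get("gene_stats"):
        stats_by_gwas = {}
        if gw.get("annotation"):
            annotation = io.read_annotation(gw["annotation"])
        for spec_entry in gw.get("snps", []):
            name, path = spec_entry["name"], spec_entry["path"]
            snps = io.read_snps(path)
            mapping = map_snps_to_genes(snps, annotation,
                                        window=gw.get("window", 0))
            stats_by_gwas[name] = gene_level_p(mapping)
        for spec_entry in gw.get("gene_stats", []):
            stats_by_gwas[spec_entry["name"]] = \
                load_gene_level_stats(spec_entry["path"])
        for label, (merged, meta, part, ME, K) in net_results.items():
            if K.shape[1] == 0:
                continue
            table = module_gwas_enrichment(
                K, stats_by_gwas, alternative=gw.get("alternative", "greater"))
            io.write_table(table, out / f"{label}.gwas_enrichment.tsv")
            gwas_summary[label] = int((table["q"] < 0.05).sum())
    report["stages"]["gwas"] = {"significant_cells": gwas_summary}

    io.write_json(report, out / "run_report.json")
    return report


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("nephronet")
    except Exception:
        return "unknown"
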