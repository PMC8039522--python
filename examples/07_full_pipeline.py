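"""Drive the whole analysis from a YAML config (what `nephronet run-all`
does).

Writes two synthetic studies plus reference/GWAS inputs to disk, builds a
config, and executes preprocessing, DGE overlap, the (merge-gated) network
stage, module association, enrichment and GWAS enrichment in order.
"""

import json
import tempfile
from pathlib import Path

import yaml

import nephronet as nn
from nephronet import io

tmp = Path(tempfile.mkdtemp(prefix="nephronet_example_"))
eff = {"turquoise": 1.2, "blue": -0.9}
for name, seed in (("glom", 41), ("tub", 42)):
    b = nn.simulate_expression_study(
        n_genes=300, n_samples=50, module_sizes=[90, 90],
        hub_weight_range=(0.7, 0.95), disease_effect=eff, seed=seed,
        study=name)
    io.write_expression(b.expression, tmp / f"{name}.expr.tsv")
    io.write_metadata(b.metadata, tmp / f"{name}.meta.tsv")
    ann = nn.make_gene_annotation(list(b.expression.index))
io.write_annotation(ann, tmp / "annotation.tsv")
io.write_snps(nn.simulate_gwas(ann, snps_per_gene=2, seed=44),
              tmp / "snps.tsv")
ref, _ = nn.simulate_cell_reference(n_genes=300, seed=43)
io.write_expression(ref, tmp / "reference.tsv")
io.write_gmt(nn.simulate_gene_sets([f"G{i:05d}" for i in range(300)],
                                   n_sets=10, seed=45), tmp / "sets.gmt")

config = {
    "seed": 5, "outdir": str(tmp / "run"),
    "datasets": [
        {"name": "glom", "expression": "glom.expr.tsv",
         "metadata": "glom.meta.tsv"},
        {"name": "tub", "expression": "tub.expr.tsv",
         "metadata": "tub.meta.tsv"},
    ],
    "preprocess": {"z_threshold": -3.0},
    "dge": {"n_permutations": 200},
    "network": {"min_module_size": 50, "n_resamples": 3},
    "enrichment": {"reference": "reference.tsv", "gmt": "sets.gmt",
                   "n_permutations": 200},
    "gwas": {"annotation": "annotation.tsv",
             "snps": [{"name": "igan", "path": "snps.tsv"}]},
}
cfg_path = tmp / "config.yaml"
cfg_path.write_text(yaml.safe_dump(config))

report = nn.run_all(nn.validate_config(cfg_path))
print(json.dumps(report["stages"], indent=1, default=str))
print(f"\nartifacts under {tmp/'run'}; identical config + seed reruns are "
      f"byte-identical")
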