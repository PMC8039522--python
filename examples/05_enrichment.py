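"""Cell-type specificity and gene-set over-representation for modules.

Builds a purified-cell reference with planted markers, computes the
specificity index and its permutation p-values, forms the cell-type
specific sets at pSI < 0.05, and tests a module against them with Fisher's
exact test; then runs hypergeometric over-representation against a toy GMT
collection containing a pathway planted inside the module.
"""

import nephronet as nn

genes = [f"G{i:05d}" for i in range(500)]
raw, markers = nn.simulate_cell_reference(n_genes=500, markers_per_type=25,
                                          fold_change=16.0, seed=6)
ref = nn.collapse_reference(raw)
p_tab = nn.psi_pvalue(ref, n_permutations=1000, seed=6)
ct_sets = nn.celltype_specific_sets(p_tab, psi_threshold=0.05)

# a module that contains all podocyte markers plus unrelated genes
module = markers["podocyte"] + genes[200:280]
fisher = nn.fisher_enrichment({"blue": module}, ct_sets, genes)
print("cell-type enrichment of the 'blue' module:")
print(fisher[["set", "overlap", "odds_ratio", "p", "q"]]
      .to_string(index=False))

collection = nn.simulate_gene_sets(genes, n_sets=15, size_range=(20, 150),
                                   planted_subset=module[:60], seed=7)
ora = nn.ora_genesets(module, collection, genes)
top = ora.iloc[0]
print(f"\ntop over-represented set: {top['set']} "
      f"(overlap {top['overlap']}/{top['set_size']}, q = {top['q']:.3g})")
# the planted pathway should dominate; its q-value reflects drawing 60 of
# the module's genes straight from that set
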