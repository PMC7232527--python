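"""The full allele comparison battery plus sample-level structure.

Runs hybrid-vs-parent and mitotype-vs-mitotype DE for every subgenome and
condition, calls within-hybrid allele preference, and summarizes sample
structure by PCA and a correlation dendrogram over subgenome columns.
"""

from _common import get_study, get_orthologs, outdir

from hybridase import alleles

out = outdir("05_panel")
pair, truth = get_study()
omap = get_orthologs(pair)

panel = alleles.run_contrast_panel(truth.counts, truth.samples, omap)
ct = panel.count_table()
ct.to_csv(out / "panel_counts.tsv", sep="\t", index=False)
mito = ct[ct.contrast == "HMtSc_vs_HMtSu"].pivot(
    index="condition", columns="subgenome", values="n_significant"
)
print("significant genes, mitotype vs mitotype:")
print(mito.to_string())

pref = alleles.allele_preference(truth.counts, truth.samples, omap)
pref.to_csv(out / "allele_preference.tsv", sep="\t")
both = pref.preferred_in_both.value_counts().to_dict()
print(f"allele preference consistent across mitotypes: {both}")

mat, cmeta = alleles.subgenome_matrix(truth.counts, truth.samples, omap)
clust = alleles.sample_clustering(mat)
clust["pca"].join(cmeta.set_index("column")).to_csv(out / "pca.tsv", sep="\t")
(out / "dendrogram.nwk").write_text(clust["newick"] + "\n")
ve = clust["variance_explained"]
pc1_by_medium = clust["pca"]["PC1"].groupby(cmeta.set_index("column").medium).mean()
print(f"PCA: PC1 {ve[0]:.1f}% / PC2 {ve[1]:.1f}% variance; "
      f"PC1 means by medium: {pc1_by_medium.round(1).to_dict()}")
print(f"outputs -> {out}")
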