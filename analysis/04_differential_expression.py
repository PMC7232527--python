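"""NB differential expression for two example contrasts.

Hybrid Sc subgenome vs the Sc parent in YPD at 28 C (trans effects plus any
hybridization shock) and the two mitotypes' Su subgenomes in YP-glycerol at
28 C (the condition where the retained mtDNA matters most).
"""

from _common import get_study, get_orthologs, outdir

from hybridase import destats

out = outdir("04_de")
pair, truth = get_study()
omap = get_orthologs(pair)
meta = truth.samples

contrasts = {
    "HMtSc_vs_ParentSc_YPD28_Sc": ("ParentSc", "HMtSc", "YPD28", "Sc"),
    "HMtSu_vs_HMtSc_Gly28_Su": ("HMtSc", "HMtSu", "Gly28", "Su"),
}
uni = omap.universe()
for name, (strain_a, strain_b, condition, subgenome) in contrasts.items():
    rows = list(uni.sc_gene if subgenome == "Sc" else uni.su_gene)
    ga = list(meta.loc[(meta.strain == strain_a) & (meta.condition == condition), "sample_id"])
    gb = list(meta.loc[(meta.strain == strain_b) & (meta.condition == condition), "sample_id"])
    res = destats.differential_expression(truth.counts.loc[rows], ga, gb)
    res.to_csv(out / f"{name}.tsv", sep="\t", index_label="gene_id")
    print(f"{name}: {int(res.significant.sum())} / {len(res)} significant "
          f"(p < 0.05 and |log2fc| > 1)")
print(f"outputs -> {out}")
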