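"""Generate the synthetic hybrid study and write its ground truth.

Produces the dual-parent genomes (FASTA + GFF3), the allele count matrix for
all 48 samples, the sample sheet, and the truth tables downstream stages are
scored against.
"""

from _common import STUDY_CFG, get_study, outdir

from hybridase import io

out = outdir("01_study")
pair, truth = get_study()
io.write_pair(pair, out)
io.write_counts(truth.counts, out / "counts.tsv")
truth.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
truth.true_means.to_csv(out / "true_means.tsv", sep="\t", index_label="allele_id")
truth.relations.to_csv(out / "true_orthologs.tsv", sep="\t", index=False)

n_su = len(pair.genes["Su"])
print(f"study: {STUDY_CFG.n_genes} Sc genes, {n_su} Su genes "
      f"({n_su - STUDY_CFG.n_genes} planted duplicates), "
      f"{len(truth.samples)} samples, "
      f"median library {int(truth.counts.sum().median())} counts")
print(f"planted effect genes: "
      + ", ".join(f"{k}={len(v)}" for k, v in truth.effects.items()))
print(f"outputs -> {out}")
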