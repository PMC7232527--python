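"""Infer the ortholog map and score it against the planted relations."""

from _common import get_study, outdir

from hybridase import orthology

out = outdir("03_orthologs")
pair, truth = get_study()
scores = orthology.similarity_matrix(pair, k=15)
omap = orthology.infer_orthologs(scores, pair)
omap.pairs.to_csv(out / "orthologs.tsv", sep="\t", index=False)

ev = orthology.evaluate_orthologs(omap, truth.relations)
rel = omap.pairs.relation.value_counts().to_dict()
print(f"ortholog universe: {len(omap.pairs)} pairs "
      f"({rel.get('one_to_one', 0)} one-to-one, {rel.get('one_to_many', 0)} one-to-many); "
      f"{len(omap.unpaired['Sc'])} Sc / {len(omap.unpaired['Su'])} Su unpaired")
print(f"vs truth: one-to-one recall {ev['one_to_one_recall']:.3f}, "
      f"classification accuracy {ev['su_gene_accuracy']:.3f}")
print(f"outputs -> {out}")
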