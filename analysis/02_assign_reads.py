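"""Simulate reads for two hybrid samples and competitively assign them.

Checks that unique assignments land on the true subgenome and that the
counted matrix tracks the simulator's true counts.
"""

from scipy import stats

from _common import STUDY_CFG, get_study, outdir

from hybridase import assign, io
from hybridase.simulate import simulate_reads

out = outdir("02_assignment")
pair, truth = get_study()
ref = assign.build_reference(pair, k=31)
samples = ["HMtSc_YPD28_r1", "HMtSu_Gly16_r2"]
fastq = simulate_reads(pair, truth, STUDY_CFG, samples=samples)

per_sample = {}
for s in samples:
    io.write_fastq(fastq[s], out / f"{s}.fastq")
    per_sample[s] = assign.assign_reads(fastq[s], ref, max_mismatch=2)

counts, summary = assign.count_matrix(per_sample, ref, STUDY_CFG.read_length)
io.write_counts(counts, out / "counts.tsv")
summary.to_csv(out / "assignment_summary.tsv", sep="\t")

for s in samples:
    uniq = [(a, rid) for a, (rid, _) in zip(per_sample[s], fastq[s]) if a.status == "unique"]
    prec = sum(a.species == rid.split("|")[1] for a, rid in uniq) / len(uniq)
    rho = stats.spearmanr(counts[s], truth.counts[s].reindex(counts.index)).statistic
    print(f"{s}: {len(fastq[s])} reads, "
          f"{summary.loc[s, 'unique']} counted unique "
          f"({summary.loc[s, 'multimapped']} multimapped, "
          f"{summary.loc[s, 'unmapped']} unmapped, "
          f"{summary.loc[s, 'ambiguous_feature']} ambiguous), "
          f"species precision {prec:.4f}, Spearman vs truth {rho:.4f}")
print(f"outputs -> {out}")
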