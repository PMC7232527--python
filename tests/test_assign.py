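"""Competitive read assignment: index counting, uniqueness rules, feature counts."""

import collections

import numpy as np
import pytest
from scipy import stats

from hybridase import assign
from hybridase.simulate import SimConfig, generate_parental_pair, simulate_counts, simulate_reads

from conftest import manual_pair


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestReference:
    def test_index_holds_every_kmer_occurrence(self):
        rng = np.random.default_rng(0)
        l1, l2 = 500, 700
        pair = manual_pair({"Sc": [("scg0000", _rand_seq(rng, l1))],
                            "Su": [("sug0000", _rand_seq(rng, l2))]}, spacer=0)
        k = 31
        ref = assign.build_reference(pair, k=k)
        assert ref.n_kmers == (l1 - k + 1) + (l2 - k + 1)

    def test_indexed_positions_decode_to_their_kmer(self):
        pair = generate_parental_pair(SimConfig(n_genes=10, seed=2))
        ref = assign.build_reference(pair)
        rng = np.random.default_rng(1)
        for i in rng.integers(0, ref.n_kmers, 20):
            code = int(ref.kmer_codes[i])
            pos = int(ref.kmer_pos[i])
            decoded = ref.kmer_at(pos)
            recoded = 0
            for ch in decoded:
                recoded = recoded * 4 + "ACGT".index(ch)
            assert recoded == code

    def test_zero_divergence_genic_kmers_occur_twice(self):
        cfg = SimConfig(n_genes=10, divergence=0.0, frac_one_to_many=0.0, seed=3)
        pair = generate_parental_pair(cfg)
        ref = assign.build_reference(pair)
        g = pair.genes["Sc"][0]
        for offset in (0, 50, len(g.sequence) - ref.k):
            code = 0
            for ch in g.sequence[offset : offset + ref.k]:
                code = code * 4 + "ACGT".index(ch)
            assert ref.lookup(code).size >= 2

    def test_duplicate_chromosome_ids_rejected(self):
        pair = manual_pair({"Sc": [("a", "A" * 400)], "Su": [("b", "C" * 400)]})
        pair.chromosomes["Su"] = {"Sc_chr01": pair.chromosomes["Su"].pop("Su_chr01")}
        with pytest.raises(ValueError, match="duplicate chromosome"):
            assign.build_reference(pair)


@pytest.fixture(scope="module")
def diverged():
    cfg = SimConfig(n_genes=60, divergence=0.05, seq_error_rate=0.0,
                    lib_size_mean=8000, seed=17)
    pair = generate_parental_pair(cfg)
    truth = simulate_counts(pair, cfg)
    ref = assign.build_reference(pair)
    return cfg, pair, truth, ref


class TestAssignment:

    def test_error_free_reads_assign_to_true_species(self, diverged):
        cfg, pair, truth, ref = diverged
        sample = "HMtSc_YPD28_r1"
        reads = simulate_reads(pair, truth, cfg, samples=[sample])[sample][:1000]
        res = assign.assign_reads(reads, ref)
        uniq = [(a, rid) for a, (rid, _) in zip(res, reads) if a.status == "unique"]
        assert len(uniq) > 0
        correct = sum(a.species == rid.split("|")[1] for a, rid in uniq)
        assert correct / len(uniq) > 0.99

    def test_statuses_partition_all_reads(self, diverged):
        cfg, pair, truth, ref = diverged
        sample = "ParentSu_Gly16_r1"
        reads = simulate_reads(pair, truth, cfg, samples=[sample])[sample][:500]
        res = assign.assign_reads(reads, ref)
        tally = collections.Counter(a.status for a in res)
        assert sum(tally.values()) == len(reads)
        assert set(tally) <= {"unique", "multimapped", "unmapped"}

    def test_twin_locus_read_is_multimapped(self):
        cfg = SimConfig(n_genes=10, divergence=0.0, frac_one_to_many=0.0, seed=4)
        pair = generate_parental_pair(cfg)
        ref = assign.build_reference(pair)
        g = pair.genes["Sc"][3]
        read = g.sequence[10 : 10 + 75]
        assert assign.assign_read(read, ref).status == "multimapped"

    def test_alien_read_is_unmapped(self, diverged):
        _, _, _, ref = diverged
        rng = np.random.default_rng(99)
        read = _rand_seq(rng, 75)
        assert assign.assign_read(read, ref).status == "unmapped"

    def test_reverse_complement_reads_are_found(self, diverged):
        cfg, pair, truth, ref = diverged
        g = pair.genes["Su"][5]
        fwd = g.sequence[20 : 20 + 75]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(fwd))
        a = assign.assign_read(rc, ref)
        assert a.status == "unique"
        assert a.species == "Su" and a.strand == "-"


class TestCountMatrix:
    def test_reads_inside_one_gene_are_counted(self):
        rng = np.random.default_rng(5)
        seq = _rand_seq(rng, 600)
        pair = manual_pair({"Sc": [("scg0000", seq)], "Su": [("sug0000", _rand_seq(rng, 600))]})
        ref = assign.build_reference(pair)
        reads = [(f"r{i}", seq[i * 40 : i * 40 + 75]) for i in range(3)]
        res = assign.assign_reads(reads, ref)
        counts, summary = assign.count_matrix({"s1": res}, ref, 75)
        assert counts.loc["scg0000", "s1"] == 3
        assert summary.loc["s1", "unique"] == 3

    def test_read_straddling_two_genes_is_ambiguous(self):
        rng = np.random.default_rng(6)
        a, b = _rand_seq(rng, 400), _rand_seq(rng, 400)
        pair = manual_pair(
            {"Sc": [("g1", a), ("g2", b)], "Su": [("x", _rand_seq(rng, 400))]}, spacer=10
        )
        ref = assign.build_reference(pair)
        # read covering the last 30 bases of g1, the 10-base gap, and g2
        chrom = pair.chromosomes["Sc"]["Sc_chr01"]
        g1 = pair.genes["Sc"][0]
        read = chrom[g1.end - 30 : g1.end - 30 + 75]
        res = assign.assign_reads([("r0", read)], ref)
        assert res[0].status == "unique"
        counts, summary = assign.count_matrix({"s1": res}, ref, 75)
        assert summary.loc["s1", "ambiguous_feature"] == 1
        assert counts["s1"].sum() == 0

    def test_unknown_chromosome_is_hard_error(self):
        rng = np.random.default_rng(7)
        pair = manual_pair({"Sc": [("g", _rand_seq(rng, 400))],
                            "Su": [("h", _rand_seq(rng, 400))]})
        ref = assign.build_reference(pair)
        bogus = assign.ReadAssignment("r", "unique", "Sc", "nope_chr", 5, "+", 0)
        with pytest.raises(KeyError):
            assign.count_matrix({"s": [bogus]}, ref, 75)

    def test_counted_matrix_tracks_truth(self):
        cfg = SimConfig(n_genes=80, divergence=0.05, seq_error_rate=0.005,
                        lib_size_mean=15_000, seed=23)
        pair = generate_parental_pair(cfg)
        truth = simulate_counts(pair, cfg)
        ref = assign.build_reference(pair)
        sample = "HMtSu_Gly28_r2"
        reads = simulate_reads(pair, truth, cfg, samples=[sample])[sample]
        res = assign.assign_reads(reads, ref)
        counts, _ = assign.count_matrix({sample: res}, ref, cfg.read_length)
        true_col = truth.counts[sample].reindex(counts.index)
        rho = stats.spearmanr(counts[sample], true_col).statistic
        assert rho >= 0.95
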