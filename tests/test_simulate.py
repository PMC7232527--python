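"""The synthetic study generator: determinism, divergence, NB noise, reads."""

import numpy as np
import pytest

from hybridase.mitotype import BUILTIN_ENZYMES, digest
from hybridase.simulate import (
    EffectModel,
    SimConfig,
    encode_seq,
    generate_parental_pair,
    simulate_counts,
    simulate_reads,
)


class TestParentalPair:
    def test_zero_divergence_copies_are_identical(self):
        cfg = SimConfig(n_genes=20, divergence=0.0, frac_one_to_many=0.0, seed=3)
        pair = generate_parental_pair(cfg)
        sc = {g.gene_id: g.sequence for g in pair.genes["Sc"]}
        for g in pair.genes["Su"]:
            assert g.sequence == sc[pair.su_source[g.gene_id]]

    def test_same_seed_reproduces_everything(self):
        cfg = SimConfig(n_genes=15, seed=42)
        a, b = generate_parental_pair(cfg), generate_parental_pair(cfg)
        assert a.chromosomes == b.chromosomes
        assert a.markers == b.markers
        assert [g.sequence for g in a.genes["Su"]] == [g.sequence for g in b.genes["Su"]]

    def test_realized_divergence_matches_configured_rate(self):
        cfg = SimConfig(n_genes=300, divergence=0.05, frac_one_to_many=0.0, seed=7)
        pair = generate_parental_pair(cfg)
        sc = {g.gene_id: g.sequence for g in pair.genes["Sc"]}
        mism = sites = 0
        for g in pair.genes["Su"]:
            src = sc[pair.su_source[g.gene_id]]
            a, b = encode_seq(src), encode_seq(g.sequence)
            mism += int((a != b).sum())
            sites += a.size
        assert abs(mism / sites - 0.05) < 0.01

    def test_gene_intervals_within_bounds_and_disjoint(self):
        pair = generate_parental_pair(SimConfig(n_genes=40, seed=1))
        for sp, genes in pair.genes.items():
            by_chrom = {}
            for g in genes:
                assert 0 <= g.start < g.end <= len(pair.chromosomes[sp][g.chrom])
                assert pair.chromosomes[sp][g.chrom][g.start : g.end] == g.sequence
                by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
            for iv in by_chrom.values():
                iv.sort()
                assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(iv, iv[1:]))

    def test_markers_are_rflp_discriminative(self):
        pair = generate_parental_pair(SimConfig(n_genes=10, seed=5))
        for marker, enz in (("COX2", "HinfI"), ("COX3", "HindIII")):
            pat_sc = digest(pair.markers["Sc"][marker], BUILTIN_ENZYMES[enz])
            pat_su = digest(pair.markers["Su"][marker], BUILTIN_ENZYMES[enz])
            assert pat_sc.fragments != pat_su.fragments

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"divergence": 0.6},
            {"n_genes": 1},
            {"read_length": 300, "gene_length_min": 300},
            {"seq_error_rate": -0.1},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestCounts:
    def test_interaction_ratio_forced_by_effect_model(self):
        eff = EffectModel(interaction_log2=2.0, interaction_frac=0.2)
        cfg = SimConfig(n_genes=50, effects=eff, seed=9)
        pair = generate_parental_pair(cfg)
        truth = simulate_counts(pair, cfg)
        cond = f"{eff.interaction_condition[0]}{eff.interaction_condition[1]}"
        m = truth.true_means
        targets = [
            a.allele_id
            for a in truth.alleles.itertuples()
            if a.pair in truth.effects["interaction"] and a.species == eff.interaction_species
        ]
        assert targets
        hi = m.loc[targets, f"HMtSc_{cond}_r1"]
        lo = m.loc[targets, f"HMtSu_{cond}_r1"]
        np.testing.assert_allclose(hi / lo, 4.0)

    def test_parents_only_express_own_alleles(self, study):
        _, truth = study
        species = dict(zip(truth.alleles.allele_id, truth.alleles.species))
        for s in truth.samples.itertuples():
            if not s.strain.startswith("Parent"):
                continue
            own = s.strain.removeprefix("Parent")
            col = truth.counts[s.sample_id]
            foreign = [a for a in col.index if species[a] != own]
            assert (col[foreign] == 0).all()

    @pytest.mark.parametrize("dispersion", [0.0, 0.1])
    def test_nb_noise_matches_moment_formula(self, dispersion):
        # standardized residuals (c - mu) / sqrt(mu + a*mu^2) pool to variance 1
        eff = EffectModel(0, 0, 0, 0, 0, 0, 0, 0)
        cfg = SimConfig(
            n_genes=200, dispersion=dispersion, effects=eff, lib_size_mean=100_000, seed=13
        )
        pair = generate_parental_pair(cfg)
        truth = simulate_counts(pair, cfg)
        mu = truth.true_means.to_numpy() * truth.lib_factors.to_numpy()[None, :]
        c = truth.counts.to_numpy().astype(float)
        mask = mu > 0
        resid = (c[mask] - mu[mask]) / np.sqrt(mu[mask] + dispersion * mu[mask] ** 2)
        assert abs(resid.var() - 1.0) < 0.1


class TestReads:
    def test_exact_reads_and_conservation_without_errors(self):
        cfg = SimConfig(n_genes=10, seq_error_rate=0.0, lib_size_mean=2000, seed=21)
        pair = generate_parental_pair(cfg)
        truth = simulate_counts(pair, cfg)
        sample = "HMtSu_YPD16_r2"
        reads = simulate_reads(pair, truth, cfg, samples=[sample])[sample]
        assert len(reads) == int(truth.counts[sample].sum())
        seqs = {
            (g.species, g.gene_id): g.sequence
            for sp in pair.genes for g in pair.genes[sp]
        }
        for rid, seq in reads[:200]:
            _, sp, gene, start, _ = rid.split("|")
            assert seqs[(sp, gene)][int(start) : int(start) + cfg.read_length] == seq

    def test_error_rate_binomially_calibrated(self):
        cfg = SimConfig(n_genes=10, seq_error_rate=0.01, lib_size_mean=2000, seed=22)
        pair = generate_parental_pair(cfg)
        truth = simulate_counts(pair, cfg)
        sample = "ParentSc_YPD28_r1"
        reads = simulate_reads(pair, truth, cfg, samples=[sample])[sample]
        seqs = {g.gene_id: encode_seq(g.sequence) for g in pair.genes["Sc"]}
        mism = bases = 0
        for rid, seq in reads:
            _, _, gene, start, _ = rid.split("|")
            ref = seqs[gene][int(start) : int(start) + cfg.read_length]
            mism += int((encode_seq(seq) != ref).sum())
            bases += cfg.read_length
            if bases >= 100_000:
                break
        expect = 0.01 * bases
        assert abs(mism - expect) < 3 * np.sqrt(expect * 0.99)

    def test_read_generation_is_deterministic(self):
        cfg = SimConfig(n_genes=5, lib_size_mean=500, seed=31)
        pair = generate_parental_pair(cfg)
        truth = simulate_counts(pair, cfg)
        s = "HMtSc_Gly28_r1"
        r1 = simulate_reads(pair, truth, cfg, samples=[s])[s]
        r2 = simulate_reads(pair, truth, cfg, samples=[s])[s]
        assert r1 == r2
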