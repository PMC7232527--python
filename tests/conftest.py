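import numpy as np
import pandas as pd
import pytest

from hybridase import orthology
from hybridase.simulate import (
    Gene,
    ParentalPair,
    SimConfig,
    generate_parental_pair,
    simulate_counts,
)


@pytest.fixture(scope="session")
def study_cfg() -> SimConfig:
    """A small study-shaped simulation shared across test modules."""
    return SimConfig(n_genes=300, lib_size_mean=60_000, seed=11)


@pytest.fixture(scope="session")
def study(study_cfg):
    pair = generate_parental_pair(study_cfg)
    truth = simulate_counts(pair, study_cfg)
    return pair, truth


@pytest.fixture(scope="session")
def study_orthologs(study):
    pair, _ = study
    scores = orthology.similarity_matrix(pair)
    return orthology.infer_orthologs(scores, pair)


def manual_pair(gene_specs, spacer=200, seed=0) -> ParentalPair:
    """Hand-built ParentalPair: gene_specs = {species: [(gene_id, seq), ...]}.

    Genes are laid head-to-tail on one chromosome per species with random
    spacers, mirroring the simulator's layout.
    """
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def rand(n):
        return bases[rng.integers(0, 4, n)].tobytes().decode()

    genes = {}
    chromosomes = {}
    for sp, specs in gene_specs.items():
        chrom = f"{sp}_chr01"
        parts = []
        pos = 0
        glist = []
        for gid, seq in specs:
            sp_seq = rand(spacer)
            parts.append(sp_seq)
            pos += spacer
            parts.append(seq)
            glist.append(Gene(gid, sp, chrom, pos, pos + len(seq), "+", seq))
            pos += len(seq)
        parts.append(rand(spacer))
        genes[sp] = glist
        chromosomes[sp] = {chrom: "".join(parts)}
    return ParentalPair(genes=genes, chromosomes=chromosomes, markers={}, su_source={})
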