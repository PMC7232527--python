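"""Shared configuration for the analysis drivers.

One desk-scale synthetic study is used throughout: 300 ortholog-paired genes
at 5% divergence, the study-shaped design (2 parents + 2 hybrid mitotypes x
4 conditions x 3 replicates), NB dispersion 0.1.  Every driver regenerates
the study deterministically from the same seed, so the scripts can be run in
any order.
"""

from pathlib import Path

from hybridase import orthology
from hybridase.simulate import SimConfig, generate_parental_pair, simulate_counts

RESULTS = Path(__file__).resolve().parent.parent / "results"
STUDY_CFG = SimConfig(n_genes=300, lib_size_mean=60_000, seed=2020)


def get_study():
    pair = generate_parental_pair(STUDY_CFG)
    truth = simulate_counts(pair, STUDY_CFG)
    return pair, truth


def get_orthologs(pair):
    return orthology.infer_orthologs(orthology.similarity_matrix(pair), pair)


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
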