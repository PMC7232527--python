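"""End-to-end benchmarks of the pipeline on synthetic data with known truth.

Each function runs one stage of the pipeline at a fixed, desk-scale problem
size and measures its headline quantity against the simulator's ground truth:
read-assignment species precision, ortholog recovery, DE calibration and
power, planted mitotype-interaction recovery, walktrap modularity quality
against an exhaustive oracle, power-law exponent recovery, and RFLP mitotype
call accuracy.  The analysis drivers and the reproduction script are thin
wrappers over these functions.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import alleles, assign, destats, mitotype, network, orthology
from .simulate import (
    EffectModel,
    SimConfig,
    generate_parental_pair,
    simulate_counts,
    simulate_reads,
)

__all__ = [
    "retention_summary",
    "assignment_benchmark",
    "orthology_benchmark",
    "de_calibration_benchmark",
    "interaction_benchmark",
    "walktrap_benchmark",
    "powerlaw_benchmark",
    "rflp_benchmark",
]


def retention_summary() -> dict:
    """Totals and retention tests for the packaged hybrid-cross table."""
    table = mitotype.load_retention_table()
    summary = mitotype.summarize_retention(table)
    per_row = summary["per_row"]
    extreme = per_row[(per_row.n_sc_mtdna == 19) & (per_row.n_su_mtdna == 0)]
    return {
        "total_crosses": summary["total_crosses"],
        "total_hybrids": summary["total_hybrids"],
        "p_19_0_two_sided": float(extreme.p_two_sided.iloc[0]),
        "per_row": per_row,
    }


def assignment_benchmark(
    seed: int = 0,
    n_genes: int = 1000,
    divergence: float = 0.05,
    lib_size: int = 40_000,
) -> dict:
    """Competitive assignment on error-free hybrid reads, plus the twin-locus limit.

    Returns the fraction of uniquely assigned reads placed on the true
    parental allele's subgenome at the configured divergence, the Spearman
    correlation of counted vs true per-allele counts, and the genic unique
    fraction at divergence zero (which must vanish: every read has an exact
    twin locus in the other subgenome).
    """
    cfg = SimConfig(
        n_genes=n_genes, divergence=divergence, seq_error_rate=0.0,
        lib_size_mean=lib_size, seed=seed,
    )
    pair = generate_parental_pair(cfg)
    truth = simulate_counts(pair, cfg)
    ref = assign.build_reference(pair)
    sample = "HMtSc_YPD28_r1"
    reads = simulate_reads(pair, truth, cfg, samples=[sample])[sample]
    res = assign.assign_reads(reads, ref)
    uniq = [(a, rid) for a, (rid, _) in zip(res, reads) if a.status == "unique"]
    correct = sum(a.species == rid.split("|")[1] for a, rid in uniq)
    counts, _ = assign.count_matrix({sample: res}, ref, cfg.read_length)
    rho = stats.spearmanr(
        counts[sample], truth.counts[sample].reindex(counts.index)
    ).statistic

    cfg0 = SimConfig(
        n_genes=n_genes, divergence=0.0, frac_one_to_many=0.0,
        seq_error_rate=0.0, lib_size_mean=5000, seed=seed,
    )
    pair0 = generate_parental_pair(cfg0)
    truth0 = simulate_counts(pair0, cfg0)
    ref0 = assign.build_reference(pair0)
    reads0 = simulate_reads(pair0, truth0, cfg0, samples=[sample])[sample]
    res0 = assign.assign_reads(reads0, ref0)
    unique0 = sum(a.status == "unique" for a in res0)
    return {
        "n_reads": len(reads),
        "species_precision_pct": 100.0 * correct / max(len(uniq), 1),
        "unique_fraction": len(uniq) / len(reads),
        "count_truth_spearman": float(rho),
        "zero_divergence_unique_fraction": unique0 / max(len(reads0), 1),
    }


def orthology_benchmark(
    seed: int = 0,
    n_genes: int = 1000,
    frac_one_to_many: float = 0.02,
    divergence: float = 0.05,
) -> dict:
    """RBH ortholog recovery against the planted relations."""
    cfg = SimConfig(
        n_genes=n_genes, frac_one_to_many=frac_one_to_many,
        divergence=divergence, seed=seed,
    )
    pair = generate_parental_pair(cfg)
    truth = simulate_counts(pair, cfg)
    scores = orthology.similarity_matrix(pair)
    omap = orthology.infer_orthologs(scores, pair)
    ev = orthology.evaluate_orthologs(omap, truth.relations)
    return {
        "one_to_one_recall_pct": 100.0 * ev["one_to_one_recall"],
        "classification_accuracy_pct": 100.0 * ev["su_gene_accuracy"],
        "n_one_to_one": int((omap.pairs.relation == "one_to_one").sum()),
        "n_one_to_many": int((omap.pairs.relation == "one_to_many").sum()),
    }


def de_calibration_benchmark(
    seed: int = 0, n_null: int = 2000, n_planted: int = 1000, alpha: float = 0.1
) -> dict:
    """Type-I error under a 3v3 NB null and power for 4-fold planted changes."""
    rng = np.random.default_rng(seed)
    cols = [f"s{i}" for i in range(6)]
    ga, gb = cols[:3], cols[3:]
    r = 1.0 / alpha
    sf_true = np.exp(rng.normal(0, 0.1, 6))

    null = rng.negative_binomial(r, r / (r + 100.0 * sf_true), size=(n_null, 6))
    res_null = destats.differential_expression(pd.DataFrame(null, columns=cols), ga, gb)
    null_fraction = float((res_null.p_value < 0.05).mean())

    r2 = 1.0 / 0.05
    up = np.hstack(
        [
            rng.negative_binomial(r2, r2 / (r2 + 100.0 * sf_true[:3]), size=(n_planted, 3)),
            rng.negative_binomial(r2, r2 / (r2 + 400.0 * sf_true[3:]), size=(n_planted, 3)),
        ]
    )
    background = rng.negative_binomial(r2, r2 / (r2 + 100.0 * sf_true), size=(n_null, 6))
    mix = pd.DataFrame(np.vstack([background, up]), columns=cols)
    res_mix = destats.differential_expression(mix, ga, gb)
    power = float(res_mix.iloc[n_null:].significant.mean())
    return {"null_fraction_p05": null_fraction, "power_4fold": power}


def interaction_benchmark(
    seed: int = 0, n_genes: int = 1000, interaction_frac: float = 0.1
) -> dict:
    """Recovery of planted mitotype-by-allele interactions by the contrast panel.

    100 Su alleles (by default) carry a mitotype-dependent shift only in
    YP-glycerol at 28 C.  The corresponding mitotype contrast at that
    condition must be enriched for the planted genes (Fisher exact) and its
    significant-gene count must exceed the same contrast at 16 C.
    """
    eff = EffectModel(interaction_frac=interaction_frac)
    cfg = SimConfig(n_genes=n_genes, effects=eff, seed=seed)
    pair = generate_parental_pair(cfg)
    truth = simulate_counts(pair, cfg)
    omap = orthology.infer_orthologs(orthology.similarity_matrix(pair), pair)
    panel = alleles.run_contrast_panel(truth.counts, truth.samples, omap)
    res28 = panel.results[("Su", "Gly28", "HMtSc_vs_HMtSu")]
    res16 = panel.results[("Su", "Gly16", "HMtSc_vs_HMtSu")]
    pair_of = dict(zip(omap.pairs.su_gene, omap.pairs.sc_gene))
    in_set = res28.index.map(lambda g: pair_of.get(g) in truth.effects["interaction"])
    table = pd.crosstab(pd.Series(in_set, index=res28.index), res28.significant)
    table = table.reindex(index=[False, True], columns=[False, True], fill_value=0)
    fisher_p = float(stats.fisher_exact(table.to_numpy())[1])
    return {
        "fisher_p": fisher_p,
        "n_sig_gly28": int(res28.significant.sum()),
        "n_sig_gly16": int(res16.significant.sum()),
        "asymmetric": bool(res28.significant.sum() > res16.significant.sum()),
    }


def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in _set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] | {first}] + partition[i + 1 :]
        yield partition + [{first}]


def walktrap_fixture_graphs() -> list[nx.Graph]:
    """Small benchmark graphs (<= 8 nodes) with community structure."""
    graphs = [
        nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]),
        nx.path_graph(7),
        nx.cycle_graph(8),
        nx.barbell_graph(3, 1),
        nx.star_graph(6),
        nx.complete_graph(5),
    ]
    return [nx.relabel_nodes(g, {v: f"v{v}" for v in g}) for g in graphs]


def walktrap_benchmark() -> dict:
    """Walktrap partitions vs exhaustive maximum-modularity enumeration."""
    ratios = []
    for g in walktrap_fixture_graphs():
        net = network.AlleleNetwork(graph=g, r_min=0.98, p_max=0.05)
        labels = network.walktrap(net)
        parts: dict[int, set] = {}
        for v, l in labels.items():
            parts.setdefault(l, set()).add(v)
        q = nx.algorithms.community.modularity(g, parts.values())
        q_best = max(
            nx.algorithms.community.modularity(g, p)
            for p in _set_partitions(list(g.nodes))
        )
        ratios.append(1.0 if q_best <= 0 else q / q_best)
    two = nx.relabel_nodes(
        nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]),
        {i: f"n{i}" for i in range(6)},
    )
    net = network.AlleleNetwork(graph=two, r_min=0.98, p_max=0.05)
    labels = network.walktrap(net)
    groups = {frozenset(v for v in labels if labels[v] == c) for c in set(labels.values())}
    triangles_exact = groups == {
        frozenset({"n0", "n1", "n2"}), frozenset({"n3", "n4", "n5"})
    }
    return {
        "min_modularity_ratio": float(min(ratios)),
        "two_triangles_exact": bool(triangles_exact),
    }


def powerlaw_benchmark(seed: int = 0, n: int = 2000, gamma: float = 2.43) -> dict:
    """Exponent recovery for the discrete power-law MLE."""
    draws = network.sample_power_law(n, gamma, x_min=1, seed=seed)
    fit = network.fit_power_law(draws, x_min=1, n_bootstrap=20, seed=seed)
    return {"gamma_true": gamma, "gamma_hat": float(fit["gamma"]),
            "ks_p": float(fit["p_value"])}


def rflp_benchmark(seed: int = 0, n_hybrids: int = 50) -> dict:
    """Mitotype-call accuracy on synthetic hybrids with discriminative markers."""
    pair = generate_parental_pair(SimConfig(n_genes=5, seed=seed))
    enzymes = {"COX2": mitotype.BUILTIN_ENZYMES["HinfI"],
               "COX3": mitotype.BUILTIN_ENZYMES["HindIII"]}
    rng = np.random.default_rng(seed)
    correct = 0
    for _ in range(n_hybrids):
        true = "Sc" if rng.random() < 0.5 else "Su"
        hybrid = dict(pair.markers[true])
        call = mitotype.call_mitotype(hybrid, pair.markers["Sc"], pair.markers["Su"], enzymes)
        correct += call == true
    mixed = {"COX2": pair.markers["Sc"]["COX2"], "COX3": pair.markers["Su"]["COX3"]}
    recomb = mitotype.call_mitotype(mixed, pair.markers["Sc"], pair.markers["Su"], enzymes)
    return {
        "call_accuracy_pct": 100.0 * correct / n_hybrids,
        "recombinant_detected": recomb == "recombinant",
    }
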