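"""Allele-level comparison battery for hybrid transcriptomes.

For each growth condition and each subgenome (the set of alleles a hybrid
inherited from one parent) this module runs:

* hybrid subgenome vs the same-species parent, separately per mitotype;
* mitotype vs mitotype on the same subgenome (how the retained mtDNA shifts
  nuclear allele expression);
* within-hybrid allele preference (Sc allele row vs Su allele row of the same
  samples, paired through the ortholog map);

and provides sample-level structure summaries (PCA on log-normalized counts,
average-linkage correlation dendrogram) plus the per-allele
relative-to-parent expression profiles that feed the co-expression network.

All contrasts are restricted to the ortholog-pair universe.  Diploid parents
and single hybrid subgenomes differ in gene dose; subgenome columns are
normalized as full samples and the dosage difference is deliberately not
corrected (documented caveat).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .destats import differential_expression, size_factors
from .orthology import OrthologMap
from .simulate import CONDITIONS

__all__ = [
    "ContrastPanel",
    "run_contrast_panel",
    "allele_preference",
    "sample_clustering",
    "subgenome_matrix",
    "expression_profiles",
]

CONTRAST_TYPES = (
    "hybrid_vs_parent_HMtSc",
    "hybrid_vs_parent_HMtSu",
    "HMtSc_vs_HMtSu",
)


@dataclass
class ContrastPanel:
    """DE results per (subgenome, condition, contrast type) plus count table."""

    results: dict[tuple[str, str, str], pd.DataFrame] = field(default_factory=dict)
    universe: list[str] = field(default_factory=list)

    def count_table(self) -> pd.DataFrame:
        """Fig-2-style table: number of significant genes per panel cell."""
        rows = []
        for (subgenome, condition, ctype), df in self.results.items():
            rows.append(
                {
                    "subgenome": subgenome,
                    "condition": condition,
                    "contrast": ctype,
                    "n_significant": int(df.significant.sum()) if df is not None else pd.NA,
                    "n_tested": len(df) if df is not None else 0,
                }
            )
        return pd.DataFrame(rows)


def _samples_of(meta: pd.DataFrame, strain: str, condition: str) -> list[str]:
    m = meta[(meta.strain == strain) & (meta.condition == condition)]
    return list(m.sample_id)


def _subgenome_rows(orthologs: OrthologMap, subgenome: str) -> list[str]:
    uni = orthologs.universe()
    return list(uni.sc_gene if subgenome == "Sc" else uni.su_gene)


def run_contrast_panel(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    orthologs: OrthologMap,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> ContrastPanel:
    """Run the full hybrid-vs-parent and mitotype-vs-mitotype DE battery.

    ``counts`` is the allele count matrix (species-tagged gene rows x
    samples); ``meta`` the sample table with strain / condition columns.  A
    missing cell (no samples for some strain x condition) is recorded as
    ``None`` — absent, not zero.
    """
    panel = ContrastPanel()
    uni = orthologs.universe()
    panel.universe = list(uni.sc_gene) + list(uni.su_gene)
    for medium, temp in CONDITIONS:
        condition = f"{medium}{temp}"
        if condition not in set(meta.condition):
            continue
        for subgenome in ("Sc", "Su"):
            rows = [r for r in _subgenome_rows(orthologs, subgenome) if r in counts.index]
            parent = f"Parent{subgenome}"
            specs = {
                "hybrid_vs_parent_HMtSc": (parent, "HMtSc"),
                "hybrid_vs_parent_HMtSu": (parent, "HMtSu"),
                "HMtSc_vs_HMtSu": ("HMtSc", "HMtSu"),
            }
            for ctype, (strain_a, strain_b) in specs.items():
                ga = _samples_of(meta, strain_a, condition)
                gb = _samples_of(meta, strain_b, condition)
                key = (subgenome, condition, ctype)
                if not ga or not gb:
                    panel.results[key] = None
                    continue
                panel.results[key] = differential_expression(
                    counts.loc[rows], ga, gb,
                    p_threshold=p_threshold, lfc_threshold=lfc_threshold,
                )
    return panel


def allele_preference(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    orthologs: OrthologMap,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Within-hybrid allele preference per ortholog pair and mitotype.

    For each mitotype, the Sc-allele rows and Su-allele rows of the same
    hybrid samples are treated as two sample groups (each subgenome column
    normalized as a full sample) and tested with the NB machinery.  The
    preferred allele is the significantly higher one under the usual rule,
    else ``none``.  The output marks pairs preferred consistently in both
    mitotypes.
    """
    uni = orthologs.universe()
    out = {}
    for mito in ("HMtSc", "HMtSu"):
        hyb = list(meta.loc[meta.strain == mito, "sample_id"])
        if not hyb:
            continue
        keep = [
            (sc, su) for sc, su in zip(uni.sc_gene, uni.su_gene)
            if sc in counts.index and su in counts.index
        ]
        sc_mat = counts.loc[[sc for sc, _ in keep], hyb]
        su_mat = counts.loc[[su for _, su in keep], hyb]
        # two pseudo-samples per hybrid sample: its Sc column and Su column
        sc_cols = {f"{s}__Sc": sc_mat[s].to_numpy() for s in hyb}
        su_cols = {f"{s}__Su": su_mat[s].to_numpy() for s in hyb}
        pair_ids = [f"{sc}|{su}" for sc, su in keep]
        stacked = pd.DataFrame({**sc_cols, **su_cols}, index=pair_ids)
        res = differential_expression(
            stacked, list(sc_cols), list(su_cols),
            p_threshold=p_threshold, lfc_threshold=lfc_threshold,
        )
        pref = np.where(
            res.significant & (res.log2fc > 0), "Su",
            np.where(res.significant & (res.log2fc < 0), "Sc", "none"),
        )
        out[mito] = pd.Series(pref, index=pair_ids)
    table = pd.DataFrame(out)
    table.index.name = "pair"
    both = (table.nunique(axis=1) == 1) & (table.iloc[:, 0] != "none")
    table["preferred_in_both"] = np.where(both, table.iloc[:, 0], "none")
    return table


def subgenome_matrix(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    orthologs: OrthologMap,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts with one column per (sample, subgenome), rows = ortholog pairs.

    Each hybrid sample contributes two columns (its Sc-allele and Su-allele
    counts); each parent contributes one.  Su rows are re-indexed to the Sc
    anchor of their pair, so both subgenomes share a common row space — the
    sample-level view used for PCA and dendrograms, where every subgenome is
    a point.  Returns (matrix, column metadata).
    """
    uni = orthologs.universe().drop_duplicates("sc_gene")
    sc_rows = [g for g in uni.sc_gene if g in counts.index]
    keep = uni[uni.sc_gene.isin(sc_rows) & uni.su_gene.isin(counts.index)]
    cols = {}
    col_meta = []
    for s in meta.itertuples():
        for subgenome, rows in (("Sc", list(keep.sc_gene)), ("Su", list(keep.su_gene))):
            if s.strain == "ParentSc" and subgenome != "Sc":
                continue
            if s.strain == "ParentSu" and subgenome != "Su":
                continue
            name = f"{s.sample_id}:{subgenome}"
            cols[name] = counts.loc[rows, s.sample_id].to_numpy()
            col_meta.append(
                {
                    "column": name,
                    "sample_id": s.sample_id,
                    "subgenome": subgenome,
                    "strain": s.strain,
                    "medium": s.medium,
                    "temperature": s.temperature,
                    "condition": s.condition,
                }
            )
    mat = pd.DataFrame(cols, index=list(keep.sc_gene))
    mat.index.name = "pair_anchor"
    return mat, pd.DataFrame(col_meta)


def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.left, labels)
    right = _newick(node.right, labels)
    dl = max(node.dist - node.left.dist, 0.0)
    dr = max(node.dist - node.right.dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def sample_clustering(counts: pd.DataFrame) -> dict:
    """PCA and correlation dendrogram over samples.

    PCA: SVD of the gene-centered log2(normalized + 1) matrix; returns sample
    coordinates and percent variance explained.  Dendrogram: average linkage
    on distance 1 - Pearson r between sample log-profiles, serialized as a
    Newick string.
    """
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sf = size_factors(counts)
    log = np.log2(counts / sf + 1.0)
    mat = log.to_numpy(dtype=float)
    centered = mat - mat.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        raise ValueError("constant expression matrix: PCA undefined")
    # samples as observations: rows = samples
    X = centered.T
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U * S
    var = S**2 / max(X.shape[0] - 1, 1)
    var_explained = 100.0 * var / var.sum()
    pca = pd.DataFrame(
        coords[:, : min(10, coords.shape[1])],
        index=counts.columns,
        columns=[f"PC{i+1}" for i in range(min(10, coords.shape[1]))],
    )

    corr = np.corrcoef(mat.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    tree = hierarchy.to_tree(linkage)
    newick = _newick(tree, list(counts.columns)) + ";"
    return {
        "pca": pca,
        "variance_explained": var_explained[: pca.shape[1]],
        "linkage": linkage,
        "newick": newick,
    }


def expression_profiles(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    orthologs: OrthologMap,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-allele log2(hybrid / parent) profiles over condition x mitotype cells.

    For each subgenome, the allele submatrix over all hybrid samples plus the
    same-species parent samples is normalized (median-of-ratios), replicates
    are averaged, and each allele's profile is the log2 ratio of the hybrid
    cell mean to the matching parent condition mean.  Columns are ordered
    (condition x mitotype); rows are allele ids of the ortholog universe.
    """
    uni = orthologs.universe()
    cols = [
        f"{medium}{temp}:{mito}"
        for medium, temp in CONDITIONS
        for mito in ("HMtSc", "HMtSu")
    ]
    blocks = []
    for subgenome in ("Sc", "Su"):
        rows = [
            g for g in (uni.sc_gene if subgenome == "Sc" else uni.su_gene)
            if g in counts.index
        ]
        parent = f"Parent{subgenome}"
        relevant = meta[meta.strain.isin([parent, "HMtSc", "HMtSu"])]
        sub = counts.loc[rows, list(relevant.sample_id)]
        sf = size_factors(sub)
        norm = sub / sf
        prof = pd.DataFrame(index=rows, columns=cols, dtype=float)
        for medium, temp in CONDITIONS:
            condition = f"{medium}{temp}"
            par_cols = _samples_of(relevant, parent, condition)
            if not par_cols:
                continue
            par_mean = norm[par_cols].mean(axis=1)
            for mito in ("HMtSc", "HMtSu"):
                hyb_cols = _samples_of(relevant, mito, condition)
                if not hyb_cols:
                    continue
                hyb_mean = norm[hyb_cols].mean(axis=1)
                prof[f"{condition}:{mito}"] = np.log2(
                    (hyb_mean + pseudocount) / (par_mean + pseudocount)
                )
        blocks.append(prof)
    out = pd.concat(blocks)
    out.index.name = "allele_id"
    return out.dropna(axis=1, how="all")
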