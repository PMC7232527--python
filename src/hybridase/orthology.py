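"""Ortholog inference between the two parental gene sets.

Alignment-free similarity: each gene is represented by its set of k-mers and
cross-species gene pairs are scored by the Jaccard index of those sets.
Pairing is reciprocal-best-hit (RBH): mutual best hits become one-to-one
orthologs; a leftover gene whose best partner is already paired, and whose
score clears a floor, is attached to that partner as a one-to-many ortholog.
Genes with tied best hits are left unpaired with a tie flag, and everything
else is reported unpaired.  Downstream allele analyses are restricted to the
paired universe (one-to-one plus one-to-many).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ParentalPair, encode_seq

__all__ = ["OrthologMap", "similarity_matrix", "infer_orthologs", "evaluate_orthologs"]

SCORE_FLOOR = 0.05


@dataclass
class OrthologMap:
    """Paired genes plus the unpaired remainder of each species."""

    pairs: pd.DataFrame          # sc_gene, su_gene, relation, score
    unpaired: dict[str, list[str]] = field(default_factory=dict)
    ties: list[str] = field(default_factory=list)

    def universe(self) -> pd.DataFrame:
        """The analysis gene universe: one_to_one and one_to_many pairs."""
        return self.pairs[self.pairs.relation.isin(["one_to_one", "one_to_many"])]


def _kmer_set(seq: str, k: int) -> frozenset[int]:
    codes = encode_seq(seq).astype(np.int64)
    n = codes.size - k + 1
    if n <= 0:
        raise ValueError("gene shorter than k")
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out = out * 4 + codes[j : j + n]
    return frozenset(out.tolist())


def similarity_matrix(pair: ParentalPair, k: int = 15) -> pd.DataFrame:
    """Sparse Jaccard similarity between Sc and Su genes sharing >= 1 k-mer.

    Returns a long-form DataFrame (sc_gene, su_gene, score).
    """
    sets: dict[tuple[str, str], frozenset[int]] = {}
    for sp in ("Sc", "Su"):
        for g in pair.genes[sp]:
            sets[(sp, g.gene_id)] = _kmer_set(g.sequence, k)
    index: dict[int, list[tuple[int, str]]] = defaultdict(list)  # kmer -> [(side, gene)]
    for (sp, gid), s in sets.items():
        side = 0 if sp == "Sc" else 1
        for km in s:
            index[km].append((side, gid))
    shared: dict[tuple[str, str], int] = defaultdict(int)
    for entries in index.values():
        sc = [g for side, g in entries if side == 0]
        su = [g for side, g in entries if side == 1]
        for a in sc:
            for b in su:
                shared[(a, b)] += 1
    rows = []
    for (a, b), inter in shared.items():
        union = len(sets[("Sc", a)]) + len(sets[("Su", b)]) - inter
        rows.append({"sc_gene": a, "su_gene": b, "score": inter / union})
    return pd.DataFrame(rows, columns=["sc_gene", "su_gene", "score"])


def _best_hits(scores: pd.DataFrame, by: str, other: str):
    """Per-gene best hit; ties (equal top score) are flagged."""
    best: dict[str, str] = {}
    tied: set[str] = set()
    for gid, grp in scores.groupby(by, sort=True):
        top = grp.score.max()
        winners = sorted(grp.loc[grp.score >= top - 1e-12, other])
        if len(winners) > 1:
            tied.add(str(gid))
        else:
            best[str(gid)] = winners[0]
    return best, tied


def infer_orthologs(
    scores: pd.DataFrame,
    pair: ParentalPair | None = None,
    score_floor: float = SCORE_FLOOR,
) -> OrthologMap:
    """RBH pairing with best-match attachment of leftover (duplicated) genes.

    Mutual best hits above ``score_floor`` -> one_to_one.  A Su gene whose
    best Sc hit is already one-to-one-paired is attached to that Sc gene as
    one_to_many if its score clears the floor (and symmetrically for Sc
    genes, so orientation does not matter).  Best-hit ties disqualify a gene
    from RBH; it is reported unpaired with a tie flag.
    """
    score_lookup = {(r.sc_gene, r.su_gene): r.score for r in scores.itertuples()}
    best_sc, tied_sc = _best_hits(scores, "sc_gene", "su_gene")
    best_su, tied_su = _best_hits(scores, "su_gene", "sc_gene")

    pairs = []
    paired_sc: set[str] = set()
    paired_su: set[str] = set()
    for sc, su in sorted(best_sc.items()):
        if best_su.get(su) == sc and score_lookup[(sc, su)] >= score_floor:
            pairs.append({"sc_gene": sc, "su_gene": su, "relation": "one_to_one",
                          "score": score_lookup[(sc, su)]})
            paired_sc.add(sc)
            paired_su.add(su)

    # attach leftovers to their best already-paired partner
    for su, sc in sorted(best_su.items()):
        if su in paired_su or su in tied_su:
            continue
        if sc in paired_sc and score_lookup[(sc, su)] >= score_floor:
            pairs.append({"sc_gene": sc, "su_gene": su, "relation": "one_to_many",
                          "score": score_lookup[(sc, su)]})
            paired_su.add(su)
    for sc, su in sorted(best_sc.items()):
        if sc in paired_sc or sc in tied_sc:
            continue
        if su in paired_su and score_lookup[(sc, su)] >= score_floor:
            pairs.append({"sc_gene": sc, "su_gene": su, "relation": "one_to_many",
                          "score": score_lookup[(sc, su)]})
            paired_sc.add(sc)

    pairs_df = pd.DataFrame(pairs, columns=["sc_gene", "su_gene", "relation", "score"])
    unpaired: dict[str, list[str]] = {"Sc": [], "Su": []}
    if pair is not None:
        all_sc = [g.gene_id for g in pair.genes["Sc"]]
        all_su = [g.gene_id for g in pair.genes["Su"]]
    else:
        all_sc = sorted(set(scores.sc_gene))
        all_su = sorted(set(scores.su_gene))
    unpaired["Sc"] = sorted(set(all_sc) - paired_sc)
    unpaired["Su"] = sorted(set(all_su) - paired_su)
    return OrthologMap(
        pairs=pairs_df, unpaired=unpaired, ties=sorted(tied_sc | tied_su)
    )


def evaluate_orthologs(omap: OrthologMap, truth: pd.DataFrame) -> dict[str, float]:
    """Accuracy of inferred pairs against the simulator's truth relations.

    A Su gene is correct if it is paired to its true Sc source gene and its
    relation class is consistent with the truth: a uniquely derived Su gene
    must be one_to_one; within a duplicated group, one copy must be
    one_to_one and the others one_to_many (either copy may win the RBH).
    """
    truth_src = dict(zip(truth.su_gene, truth.sc_source))
    inferred = {r.su_gene: (r.sc_gene, r.relation) for r in omap.pairs.itertuples()}
    groups: dict[str, list[str]] = defaultdict(list)
    for su, src in truth_src.items():
        groups[src].append(su)
    n_correct = 0
    one_to_one_recovered = 0
    n_one_to_one_truth = sum(1 for g in groups.values() if len(g) == 1)
    for src, members in groups.items():
        inf = {su: inferred.get(su) for su in members}
        right_partner = all(v is not None and v[0] == src for v in inf.values())
        labels = sorted(v[1] for v in inf.values() if v is not None)
        if len(members) == 1:
            ok = right_partner and labels == ["one_to_one"]
            if ok:
                one_to_one_recovered += 1
        else:
            ok = right_partner and labels == ["one_to_many"] * (len(members) - 1) + ["one_to_one"]
            ok = ok or (right_partner and labels.count("one_to_one") == 1)
        if ok:
            n_correct += len(members)
    return {
        "su_gene_accuracy": n_correct / max(len(truth_src), 1),
        "one_to_one_recall": one_to_one_recovered / max(n_one_to_one_truth, 1),
    }
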