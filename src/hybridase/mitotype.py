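"""In-silico RFLP mitotype determination and mtDNA inheritance statistics.

Interspecific yeast hybrids rapidly become homoplasmic: each hybrid keeps the
mitochondrial genome of only one parent (its *mitotype*).  Which parent's mtDNA
is retained is scored by digesting PCR products of mitochondrial marker genes
(COX2/COX3-like) with restriction enzymes whose recognition sites differ
between the parental species, and matching the fragment-length pattern of the
hybrid against the two parental patterns.  Hybrids whose markers disagree
(e.g. a COX2 pattern from one parent and a COX3 pattern from the other) carry
recombinant mtDNA.

Retention counts across cross conditions are tested against a 50:50 null with
the exact binomial goodness-of-fit test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "Enzyme",
    "RFLPPattern",
    "BUILTIN_ENZYMES",
    "digest",
    "call_mitotype",
    "retention_test",
    "summarize_retention",
    "load_retention_table",
]

# IUPAC nucleotide ambiguity codes
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition motif (IUPAC) and cut offset.

    The enzyme cuts ``offset`` bases after the start of each motif occurrence
    on the forward strand.
    """

    name: str
    motif: str
    offset: int

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError(f"{self.name}: motif shorter than 4 bases")
        if not 0 <= self.offset <= len(self.motif):
            raise ValueError(f"{self.name}: cut offset outside motif")
        if any(b not in _IUPAC for b in self.motif.upper()):
            raise ValueError(f"{self.name}: non-IUPAC character in motif")

    @property
    def regex(self) -> re.Pattern:
        # lookahead so overlapping sites are all found
        inner = "".join(_IUPAC[b] for b in self.motif.upper())
        return re.compile(f"(?={inner})")


#: HinfI (GANTC, cuts G^ANTC) and HindIII (AAGCTT, cuts A^AGCTT)
BUILTIN_ENZYMES: dict[str, Enzyme] = {
    "HinfI": Enzyme("HinfI", "GANTC", 1),
    "HindIII": Enzyme("HindIII", "AAGCTT", 1),
}


@dataclass(frozen=True)
class RFLPPattern:
    """Sorted restriction fragment lengths for one marker/enzyme digest."""

    marker_id: str
    enzyme: str
    fragments: tuple[int, ...]

    def matches(self, other: "RFLPPattern", tolerance: int = 0) -> bool:
        """Exact (or ±tolerance bases) fragment-pattern identity."""
        if len(self.fragments) != len(other.fragments):
            return False
        return all(
            abs(a - b) <= tolerance
            for a, b in zip(self.fragments, other.fragments)
        )


def digest(sequence: str, enzyme: Enzyme, marker_id: str = "") -> RFLPPattern:
    """Digest ``sequence`` with ``enzyme``, returning sorted fragment lengths.

    Sites are scanned on the forward strand with IUPAC expansion; a sequence
    with no site yields a single full-length fragment.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    if re.search("[^ACGT]", seq):
        raise ValueError("sequence contains non-ACGT characters")
    cuts = sorted(
        m.start() + enzyme.offset
        for m in enzyme.regex.finditer(seq)
        # a cut at 0 or len(seq) produces an empty fragment; skip it
        if 0 < m.start() + enzyme.offset < len(seq)
    )
    bounds = [0] + cuts + [len(seq)]
    fragments = tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))
    return RFLPPattern(marker_id, enzyme.name, fragments)


def call_mitotype(
    hybrid_markers: Mapping[str, str],
    parent_a_markers: Mapping[str, str],
    parent_b_markers: Mapping[str, str],
    enzymes: Mapping[str, Enzyme],
    labels: tuple[str, str] = ("Sc", "Su"),
    tolerance: int = 0,
) -> str:
    """Call the mitotype of a hybrid from its marker RFLP patterns.

    Each marker's hybrid pattern is matched against the two parental patterns.
    All informative markers agreeing on one parent -> that parent's label;
    disagreement between markers -> ``"recombinant"``; any marker matching
    neither parent -> ``"undetermined"``.  Markers whose parental patterns are
    indistinguishable are uninformative and excluded; if every marker is
    uninformative an error is raised.

    Parameters
    ----------
    hybrid_markers, parent_a_markers, parent_b_markers
        marker_id -> sequence.  Marker ids must be shared.
    enzymes
        marker_id -> enzyme used for that marker.
    labels
        Labels returned for a parent-A or parent-B call.
    """
    shared = sorted(set(hybrid_markers) & set(parent_a_markers)
                    & set(parent_b_markers) & set(enzymes))
    if len(shared) < 2:
        raise ValueError("need at least two shared marker genes")

    calls: list[str] = []
    for marker in shared:
        enz = enzymes[marker]
        pat_a = digest(parent_a_markers[marker], enz, marker)
        pat_b = digest(parent_b_markers[marker], enz, marker)
        if pat_a.matches(pat_b, tolerance):
            continue  # uninformative marker
        pat_h = digest(hybrid_markers[marker], enz, marker)
        hit_a = pat_h.matches(pat_a, tolerance)
        hit_b = pat_h.matches(pat_b, tolerance)
        if hit_a and not hit_b:
            calls.append(labels[0])
        elif hit_b and not hit_a:
            calls.append(labels[1])
        else:
            return "undetermined"
    if not calls:
        raise ValueError("all markers uninformative (identical parental patterns)")
    if len(set(calls)) > 1:
        return "recombinant"
    return calls[0]


def retention_test(n_a: int, n_b: int) -> dict[str, float]:
    """Exact binomial goodness-of-fit test of an a:b retention split vs 50:50.

    Two-sided p follows the minlike ("method of small p-values") convention:
    the sum of point probabilities no larger than that of the observed count.
    The one-sided tail p is reported alongside.
    """
    if n_a < 0 or n_b < 0 or n_a + n_b < 1:
        raise ValueError("need non-negative counts with n_a + n_b >= 1")
    n = n_a + n_b
    two_sided = stats.binomtest(n_a, n, 0.5, alternative="two-sided").pvalue
    one_sided = stats.binom.cdf(min(n_a, n_b), n, 0.5)
    return {"p_two_sided": float(two_sided), "p_one_sided": float(one_sided)}


_RETENTION_COLS = ["temperature", "medium", "crosses", "hybrids", "n_sc_mtdna", "n_su_mtdna"]


def summarize_retention(table: pd.DataFrame) -> dict:
    """Totals, per-row hybridisation success, and retention tests for a cross table.

    ``table`` rows are (temperature, medium) cross conditions with the number
    of crosses attempted, viable hybrids obtained, and hybrids retaining each
    parental mtDNA.  Recombinant/unscored hybrids may leave
    ``n_sc + n_su < hybrids``.  Significance stars: * p<=0.05, ** p<=0.01
    (two-sided exact binomial).
    """
    missing = [c for c in _RETENTION_COLS if c not in table.columns]
    if missing:
        raise ValueError(f"retention table missing columns: {missing}")
    rows = []
    for idx, row in table.iterrows():
        n_sc, n_su = int(row.n_sc_mtdna), int(row.n_su_mtdna)
        hybrids, crosses = int(row.hybrids), int(row.crosses)
        if not (n_sc + n_su <= hybrids <= crosses):
            raise ValueError(
                f"row {idx} ({row.temperature}, {row.medium}): "
                f"requires n_sc + n_su <= hybrids <= crosses"
            )
        if n_sc + n_su >= 1:
            p = retention_test(n_sc, n_su)
        else:
            p = {"p_two_sided": float("nan"), "p_one_sided": float("nan")}
        star = ""
        if p["p_two_sided"] <= 0.01:
            star = "**"
        elif p["p_two_sided"] <= 0.05:
            star = "*"
        rows.append({
            "temperature": row.temperature,
            "medium": row.medium,
            "crosses": crosses,
            "hybrids": hybrids,
            "n_sc_mtdna": n_sc,
            "n_su_mtdna": n_su,
            "success_rate": hybrids / crosses if crosses else float("nan"),
            "p_two_sided": p["p_two_sided"],
            "p_one_sided": p["p_one_sided"],
            "stars": star,
        })
    per_row = pd.DataFrame(
        rows,
        columns=_RETENTION_COLS[:2]
        + ["crosses", "hybrids", "n_sc_mtdna", "n_su_mtdna", "success_rate",
           "p_two_sided", "p_one_sided", "stars"],
    )
    return {
        "per_row": per_row,
        "total_crosses": int(per_row.crosses.sum()),
        "total_hybrids": int(per_row.hybrids.sum()),
        "total_sc_mtdna": int(per_row.n_sc_mtdna.sum()),
        "total_su_mtdna": int(per_row.n_su_mtdna.sum()),
    }


def load_retention_table() -> pd.DataFrame:
    """The packaged hybrid-cross retention table (2 media x 3 temperatures)."""
    with resources.files("hybridase.data").joinpath("retention_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
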