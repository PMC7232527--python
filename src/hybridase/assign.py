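"""Competitive read assignment against a concatenated two-species reference.

Reads from a hybrid cannot be attributed to a subgenome by mapping to either
parent alone: a read matching both parents equally well is uninformative.  The
competitive strategy concatenates both parental genomes into one reference and
keeps only reads that place *uniquely* — strictly fewer mismatches at one
locus than at every other candidate locus, on either strand.  Ties (including
the exact twin locus in the other subgenome) are discarded as multimapped.

Matching is exact-seed / full-read-verify: candidate loci come from k-mer
seeds, then the whole read is compared allowing up to ``max_mismatch``
substitutions (no indels).  Unique assignments are converted to per-gene
counts with a union-style rule: a read overlapping exactly one annotated gene
increments that gene; reads overlapping none or more than one are flagged
``ambiguous_feature`` and not counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import ParentalPair, encode_seq

__all__ = [
    "CombinedReference",
    "ReadAssignment",
    "build_reference",
    "assign_read",
    "assign_reads",
    "count_matrix",
    "STATUSES",
]

STATUSES = ("unique", "multimapped", "unmapped", "ambiguous_feature")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str          # unique | multimapped | unmapped
    species: str = ""
    chrom: str = ""
    position: int = -1   # 0-based start on the chromosome, forward strand
    strand: str = ""
    mismatches: int = -1


class CombinedReference:
    """Concatenated dual-parent genome with a sorted k-mer index.

    Chromosome ids are species-namespaced (the simulator already prefixes
    them); duplicate ids across species are rejected.  Coordinates are
    0-based half-open internally; the genome is held as one uint8 code array
    with per-chromosome offsets.
    """

    def __init__(self, pair: ParentalPair, k: int):
        if not 11 <= k:
            raise ValueError("k must be >= 11")
        self.k = k
        names: list[str] = []
        species: list[str] = []
        offsets: list[int] = [0]
        chunks: list[np.ndarray] = []
        seen: set[str] = set()
        for sp in sorted(pair.chromosomes):
            for chrom in sorted(pair.chromosomes[sp]):
                if chrom in seen:
                    raise ValueError(f"duplicate chromosome id {chrom!r} across species")
                seen.add(chrom)
                codes = encode_seq(pair.chromosomes[sp][chrom])
                names.append(chrom)
                species.append(sp)
                chunks.append(codes)
                offsets.append(offsets[-1] + codes.size)
        self.chrom_names = names
        self.chrom_species = species
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.genome = np.concatenate(chunks)

        # k-mer codes per chromosome (no k-mer spans a boundary)
        code_list: list[np.ndarray] = []
        pos_list: list[np.ndarray] = []
        for ci, chunk in enumerate(chunks):
            if chunk.size < k:
                continue
            codes = _kmer_codes(chunk, k)
            code_list.append(codes)
            pos_list.append(np.arange(chunk.size - k + 1, dtype=np.int64) + self.offsets[ci])
        allcodes = np.concatenate(code_list)
        allpos = np.concatenate(pos_list)
        order = np.argsort(allcodes, kind="stable")
        self.kmer_codes = allcodes[order]
        self.kmer_pos = allpos[order]

        # gene annotation in global coordinates, sorted per chromosome
        gene_rows = []
        chrom_off = {c: int(self.offsets[i]) for i, c in enumerate(names)}
        for sp in pair.genes:
            for g in pair.genes[sp]:
                off = chrom_off[g.chrom]
                gene_rows.append((sp, g.gene_id, g.chrom, off + g.start, off + g.end))
        gene_rows.sort(key=lambda r: r[3])
        self.gene_species = [r[0] for r in gene_rows]
        self.gene_ids = [r[1] for r in gene_rows]
        self.gene_starts = np.asarray([r[3] for r in gene_rows], dtype=np.int64)
        self.gene_ends = np.asarray([r[4] for r in gene_rows], dtype=np.int64)

    @property
    def n_kmers(self) -> int:
        """Number of indexed k-mer occurrences (with multiplicity)."""
        return int(self.kmer_codes.size)

    def locate(self, global_pos: int) -> tuple[str, str, int]:
        """(species, chrom, chromosome-local position) for a global offset."""
        ci = int(np.searchsorted(self.offsets, global_pos, side="right")) - 1
        return self.chrom_species[ci], self.chrom_names[ci], int(global_pos - self.offsets[ci])

    def kmer_at(self, global_pos: int) -> str:
        from .simulate import decode_seq

        return decode_seq(self.genome[global_pos : global_pos + self.k])

    def lookup(self, code: int) -> np.ndarray:
        """All global positions of one k-mer code."""
        lo = np.searchsorted(self.kmer_codes, code, side="left")
        hi = np.searchsorted(self.kmer_codes, code, side="right")
        return self.kmer_pos[lo:hi]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack each k-mer into an int64 (2 bits per base); requires k <= 31."""
    if k > 31:
        raise ValueError("k must be <= 31 to pack into int64")
    n = codes.size - k + 1
    out = np.zeros(n, dtype=np.int64)
    c64 = codes.astype(np.int64)
    for j in range(k):
        out = out * 4 + c64[j : j + n]
    return out


_RC = np.array([3, 2, 1, 0], dtype=np.uint8)


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return _RC[codes[::-1]]


def build_reference(pair: ParentalPair, k: int = 31) -> CombinedReference:
    """Build the concatenated dual-parent reference with its k-mer index."""
    return CombinedReference(pair, k)


def _candidates(ref: CombinedReference, read_codes: np.ndarray, seed_offsets: Sequence[int]):
    """Candidate alignment start positions from exact k-mer seed hits."""
    k, L = ref.k, read_codes.size
    starts: set[int] = set()
    c64 = read_codes.astype(np.int64)
    for off in seed_offsets:
        code = 0
        for j in range(k):
            code = code * 4 + int(c64[off + j])
        for p in ref.lookup(code):
            s = int(p) - off
            if s < 0 or s + L > ref.genome.size:
                continue
            starts.add(s)
    return starts


def _verify(ref: CombinedReference, read_codes: np.ndarray, start: int) -> int:
    seg = ref.genome[start : start + read_codes.size]
    return int(np.count_nonzero(seg != read_codes))


def assign_read(
    read_seq: str,
    ref: CombinedReference,
    max_mismatch: int = 2,
    read_id: str = "",
) -> ReadAssignment:
    """Assign one read: unique best locus, tied loci -> multimapped, none -> unmapped."""
    codes = encode_seq(read_seq)
    return _assign_codes(codes, ref, max_mismatch, read_id)


def _assign_codes(
    codes: np.ndarray, ref: CombinedReference, max_mismatch: int, read_id: str
) -> ReadAssignment:
    L = codes.size
    k = ref.k
    if L < k:
        raise ValueError("read shorter than k")
    seed_offsets = sorted({0, (L - k) // 2, L - k})
    best_mm = max_mismatch + 1
    best: list[tuple[int, str]] = []  # (start, strand)
    for strand, rc in (("+", codes), ("-", _revcomp(codes))):
        for start in _candidates(ref, rc, seed_offsets):
            # a candidate must not span a chromosome boundary
            ci = int(np.searchsorted(ref.offsets, start, side="right")) - 1
            if start + L > ref.offsets[ci + 1]:
                continue
            mm = _verify(ref, rc, start)
            if mm < best_mm:
                best_mm = mm
                best = [(start, strand)]
            elif mm == best_mm:
                if (start, strand) not in best:
                    best.append((start, strand))
    if best_mm > max_mismatch or not best:
        return ReadAssignment(read_id, "unmapped")
    # the same locus can be reached from both strands only for palindromes;
    # distinct (start, strand) entries with equal mismatches are genuine ties
    uniq = {s for s, _ in best}
    if len(best) > 1 and len(uniq) > 1:
        return ReadAssignment(read_id, "multimapped")
    if len(best) > 1:
        # same start on both strands: still one place in the genome
        best = [best[0]]
    start, strand = best[0]
    sp, chrom, local = ref.locate(start)
    return ReadAssignment(read_id, "unique", sp, chrom, local, strand, best_mm)


def assign_reads(
    reads: Iterable[tuple[str, str]],
    ref: CombinedReference,
    max_mismatch: int = 2,
) -> list[ReadAssignment]:
    """Assign a batch of (read_id, sequence) pairs."""
    return [assign_read(seq, ref, max_mismatch, rid) for rid, seq in reads]


def count_matrix(
    assignments_by_sample: dict[str, list[ReadAssignment]],
    ref: CombinedReference,
    read_length: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene counts from unique assignments, union-style feature overlap.

    A unique read is counted for a gene iff its interval overlaps exactly one
    annotated gene; otherwise it becomes ``ambiguous_feature``.  Returns
    (counts genes x samples, per-sample status summary).  Assignments naming
    an unknown chromosome raise.
    """
    chrom_off = {c: int(ref.offsets[i]) for i, c in enumerate(ref.chrom_names)}
    gene_order = list(ref.gene_ids)
    counts = pd.DataFrame(
        0, index=pd.Index(gene_order, name="gene_id"),
        columns=list(assignments_by_sample), dtype=np.int64,
    )
    summary_rows = []
    for sample, assignments in assignments_by_sample.items():
        tally = {s: 0 for s in STATUSES}
        for a in assignments:
            if a.status != "unique":
                tally[a.status] += 1
                continue
            if a.chrom not in chrom_off:
                raise KeyError(f"assignment references unknown chromosome {a.chrom!r}")
            gstart = chrom_off[a.chrom] + a.position
            gend = gstart + read_length
            # genes sorted by start; overlap iff gene.start < gend and gene.end > gstart
            i = int(np.searchsorted(ref.gene_starts, gend, side="left"))
            hits = [
                j for j in range(max(0, i - 3), i)
                if ref.gene_ends[j] > gstart and ref.gene_starts[j] < gend
            ]
            if len(hits) == 1:
                counts.iloc[hits[0], counts.columns.get_loc(sample)] += 1
                tally["unique"] += 1
            else:
                tally["ambiguous_feature"] += 1
        summary_rows.append({"sample": sample, **tally})
    summary = pd.DataFrame(summary_rows).set_index("sample")
    return counts, summary
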