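"""Synthetic interspecific-hybrid transcriptomics with known ground truth.

Emulates the study system: two diverged budding-yeast-like parents (tagged
``Sc`` and ``Su``), diploid parental cultures, and hybrid strains carrying one
or the other parental mitochondrial genome (mitotype ``HMtSc`` / ``HMtSu``),
grown in four conditions (2 media x 2 temperatures) with replication.

The generator produces, deterministically from a seed:

* a :class:`ParentalPair` — random coding-like genes laid out on chromosomes
  for the Sc parent, with each Su ortholog derived by i.i.d. per-site
  substitution at a configured divergence; a small fraction of Sc genes get a
  second diverged Su copy (planted one-to-many orthologs); mitochondrial
  marker genes (COX2/COX3 analogues) engineered so a restriction site is
  present in one parent and ablated in the other;
* a :class:`TruthTable` — negative-binomial counts per (allele, sample) whose
  log2 means carry medium, temperature, subgenome and mitotype-by-allele
  interaction effects on designated gene subsets, plus the true means, true
  effect-gene sets, true ortholog relations and true mitotypes;
* single-end FASTQ reads drawn uniformly within genes with i.i.d. substitution
  errors, headers encoding the true origin for evaluation only.

Every random choice flows from ``SimConfig.seed`` through spawned
`numpy` generators, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "EffectModel",
    "Gene",
    "ParentalPair",
    "TruthTable",
    "CONDITIONS",
    "generate_parental_pair",
    "simulate_counts",
    "simulate_reads",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i

#: the four growth conditions: (medium, temperature in Celsius)
CONDITIONS: tuple[tuple[str, int], ...] = (("YPD", 28), ("YPD", 16), ("Gly", 28), ("Gly", 16))


def encode_seq(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("non-ACGT character in sequence")
    return arr


def decode_seq(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


@dataclass(frozen=True)
class EffectModel:
    """Per-factor log2 expression shifts and the gene fractions they touch.

    Each affected gene receives the stated |log2| shift with a random sign.
    The mitotype-by-allele interaction applies only to ``interaction_species``
    alleles of the designated gene fraction, in hybrid samples of
    ``interaction_mitotype``, at the single ``interaction_condition``.
    """

    medium_log2: float = 2.0
    medium_frac: float = 0.30
    temperature_log2: float = 1.5
    temperature_frac: float = 0.20
    subgenome_log2: float = 1.0
    subgenome_frac: float = 0.10
    interaction_log2: float = 2.0
    interaction_frac: float = 0.05
    interaction_condition: tuple[str, int] = ("Gly", 28)
    interaction_species: str = "Su"
    interaction_mitotype: str = "Sc"


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with study-shaped defaults."""

    n_genes: int = 200
    frac_one_to_many: float = 0.02
    divergence: float = 0.05
    gene_length_mean: int = 900
    gene_length_min: int = 300
    read_length: int = 75
    seq_error_rate: float = 0.005
    dispersion: float = 0.1
    lib_size_mean: int = 200_000
    base_mean_log2: float = 7.0   # log2 of typical per-allele mean count
    base_sd_log2: float = 1.0
    n_replicates: int = 3
    n_chromosomes: int = 2
    spacer_length: int = 300
    marker_length: int = 600
    effects: EffectModel = field(default_factory=EffectModel)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_one_to_many", "divergence", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.divergence > 0.5:
            raise ValueError("divergence > 0.5: gene identity would be lost")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.read_length >= self.gene_length_min:
            raise ValueError("read_length must be shorter than the minimum gene length")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    species: str
    chrom: str
    start: int   # 0-based, half-open
    end: int
    strand: str
    sequence: str


@dataclass
class ParentalPair:
    """Two annotated parental gene sets plus mitochondrial markers.

    ``su_source`` records, for every Su gene, the Sc gene it was derived
    from — the ground truth for orthology evaluation.
    """

    genes: dict[str, list[Gene]]                    # species -> genes
    chromosomes: dict[str, dict[str, str]]          # species -> chrom -> sequence
    markers: dict[str, dict[str, str]]              # species -> marker_id -> sequence
    su_source: dict[str, str]

    def gene_seq(self, species: str, gene_id: str) -> str:
        for g in self.genes[species]:
            if g.gene_id == gene_id:
                return g.sequence
        raise KeyError(gene_id)

    def gene_index(self) -> pd.DataFrame:
        rows = [
            (g.species, g.gene_id, g.chrom, g.start, g.end, g.strand, len(g.sequence))
            for sp in sorted(self.genes)
            for g in self.genes[sp]
        ]
        return pd.DataFrame(
            rows, columns=["species", "gene_id", "chrom", "start", "end", "strand", "length"]
        )


@dataclass
class TruthTable:
    """Ground truth of one simulated study.

    ``true_means`` are expression levels free of library-depth noise; counts
    are drawn as NB(mean = true_mean x lib_factor), so the per-sample
    ``lib_factors`` are exactly what size-factor normalization should recover.
    """

    samples: pd.DataFrame          # sample_id, strain, mitotype, medium, temperature, replicate
    true_means: pd.DataFrame       # alleles x samples (0 where allele absent)
    lib_factors: pd.Series         # per-sample library depth factor
    counts: pd.DataFrame           # alleles x samples, NB draws
    alleles: pd.DataFrame          # allele_id, species, gene_id, pair (sc anchor or NA)
    effects: dict[str, set[str]]   # factor -> set of affected Sc anchor gene ids
    effect_signs: dict[str, dict[str, int]]
    relations: pd.DataFrame        # su_gene, sc_source, relation (one_to_one / one_to_many)
    mitotypes: dict[str, str]      # hybrid sample -> "Sc" | "Su"

    def hybrid_samples(self) -> list[str]:
        return list(self.samples.loc[self.samples.strain.str.startswith("HMt"), "sample_id"])


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """i.i.d. per-site substitution to a uniformly chosen *different* base."""
    out = codes.copy()
    if rate <= 0:
        return out
    hit = rng.random(codes.size) < rate
    n = int(hit.sum())
    if n:
        # shift by 1..3 mod 4 guarantees a change
        out[hit] = (out[hit] + rng.integers(1, 4, size=n)) % 4
    return out


def _random_coding_like(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random gene body with start/stop codon trimmings."""
    codes = rng.integers(0, 4, size=length).astype(np.uint8)
    codes[:3] = encode_seq("ATG")
    codes[-3:] = encode_seq("TAA")
    return codes


def _scrub_motif(rng: np.random.Generator, seq: np.ndarray, motif_regex: re.Pattern) -> np.ndarray:
    """Resample bases until the motif no longer occurs anywhere."""
    s = seq.copy()
    for _ in range(100):
        text = decode_seq(s)
        hits = [m.start() for m in motif_regex.finditer(text)]
        if not hits:
            return s
        for h in hits:
            s[h] = (s[h] + rng.integers(1, 4)) % 4
    raise RuntimeError("failed to scrub restriction motif")


def _make_markers(rng: np.random.Generator, config: SimConfig) -> dict[str, dict[str, str]]:
    """COX2/COX3-like markers with an engineered restriction-site difference.

    COX2 carries a HinfI site (GANTC) in the Sc version only; COX3 carries a
    HindIII site (AAGCTT) in the Su version only.  The shared backbone is
    scrubbed of both motifs first, so the engineered site is the single
    discriminative cut.
    """
    hinf = re.compile("(?=GA[ACGT]TC)")
    hind = re.compile("(?=AAGCTT)")
    out: dict[str, dict[str, str]] = {"Sc": {}, "Su": {}}
    for marker, motif, carrier in (("COX2", "GACTC", "Sc"), ("COX3", "AAGCTT", "Su")):
        backbone = rng.integers(0, 4, size=config.marker_length).astype(np.uint8)
        backbone = _scrub_motif(rng, backbone, hinf)
        backbone = _scrub_motif(rng, backbone, hind)
        site = encode_seq(motif)
        pos = config.marker_length // 3
        with_site = backbone.copy()
        with_site[pos : pos + site.size] = site
        # a few neutral SNPs so the two parental markers also differ off-site
        without_site = _mutate(rng, backbone, 0.01)
        without_site = _scrub_motif(rng, without_site, hinf)
        without_site = _scrub_motif(rng, without_site, hind)
        other = "Su" if carrier == "Sc" else "Sc"
        out[carrier][marker] = decode_seq(with_site)
        out[other][marker] = decode_seq(without_site)
    return out


def generate_parental_pair(config: SimConfig) -> ParentalPair:
    """Generate the two parental gene sets, genomes and mitochondrial markers."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = config.n_genes
    # log-normal lengths with a floor, rounded to whole codons
    mu = math.log(max(config.gene_length_mean - config.gene_length_min, 1))
    lengths = (
        config.gene_length_min
        + np.exp(rng.normal(mu, 0.4, size=n)).astype(int)
    )
    lengths = (lengths // 3) * 3

    sc_seqs = [_random_coding_like(rng, int(L)) for L in lengths]
    sc_ids = [f"scg{i:04d}" for i in range(n)]

    n_dup = int(round(config.frac_one_to_many * n))
    dup_idx = set(rng.choice(n, size=n_dup, replace=False).tolist()) if n_dup else set()

    su_entries: list[tuple[str, str, np.ndarray]] = []  # (su_id, sc_source, codes)
    for i, sc_id in enumerate(sc_ids):
        su_entries.append((f"sug{i:04d}", sc_id, _mutate(rng, sc_seqs[i], config.divergence)))
        if i in dup_idx:
            su_entries.append(
                (f"sug{i:04d}b", sc_id, _mutate(rng, sc_seqs[i], config.divergence))
            )

    genes: dict[str, list[Gene]] = {"Sc": [], "Su": []}
    chromosomes: dict[str, dict[str, str]] = {"Sc": {}, "Su": {}}
    su_source: dict[str, str] = {}

    def layout(species: str, entries: list[tuple[str, np.ndarray]]) -> None:
        n_chr = config.n_chromosomes
        per = math.ceil(len(entries) / n_chr)
        for c in range(n_chr):
            chunk = entries[c * per : (c + 1) * per]
            if not chunk:
                continue
            chrom = f"{species}_chr{c + 1:02d}"
            parts: list[np.ndarray] = []
            pos = 0
            for gid, codes in chunk:
                spacer = rng.integers(0, 4, size=config.spacer_length).astype(np.uint8)
                parts.append(spacer)
                pos += config.spacer_length
                parts.append(codes)
                genes[species].append(
                    Gene(gid, species, chrom, pos, pos + codes.size, "+", decode_seq(codes))
                )
                pos += codes.size
            parts.append(rng.integers(0, 4, size=config.spacer_length).astype(np.uint8))
            chromosomes[species][chrom] = decode_seq(np.concatenate(parts))

    layout("Sc", list(zip(sc_ids, sc_seqs)))
    layout("Su", [(gid, codes) for gid, _, codes in su_entries])
    for gid, src, _ in su_entries:
        su_source[gid] = src

    markers = _make_markers(rng, config)
    return ParentalPair(genes=genes, chromosomes=chromosomes, markers=markers, su_source=su_source)


def _sample_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for medium, temp in CONDITIONS:
        cond = f"{medium}{temp}"
        for strain, mito in (
            ("ParentSc", ""), ("ParentSu", ""), ("HMtSc", "Sc"), ("HMtSu", "Su"),
        ):
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{strain}_{cond}_r{rep}",
                        "strain": strain,
                        "mitotype": mito,
                        "medium": medium,
                        "temperature": temp,
                        "replicate": rep,
                        "condition": cond,
                    }
                )
    return pd.DataFrame(rows)


def _truth_relations(pair: ParentalPair) -> pd.DataFrame:
    counts: dict[str, int] = {}
    for src in pair.su_source.values():
        counts[src] = counts.get(src, 0) + 1
    rows = [
        {
            "su_gene": su,
            "sc_source": src,
            "relation": "one_to_one" if counts[src] == 1 else "one_to_many",
        }
        for su, src in sorted(pair.su_source.items())
    ]
    return pd.DataFrame(rows)


def simulate_counts(pair: ParentalPair, config: SimConfig) -> TruthTable:
    """Draw NB counts for every (allele, sample) under the planted effect model.

    Parents contribute only their own species' allele rows; hybrids contribute
    both.  Per-sample library-size factors are log-normal around 1 and are
    part of the truth (they are what median-of-ratios normalization should
    recover).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    eff = config.effects
    samples = _sample_table(config)

    sc_ids = [g.gene_id for g in pair.genes["Sc"]]
    su_genes = [g.gene_id for g in pair.genes["Su"]]
    allele_rows = []
    for gid in sc_ids:
        allele_rows.append({"allele_id": gid, "species": "Sc", "gene_id": gid, "pair": gid})
    for gid in su_genes:
        allele_rows.append(
            {"allele_id": gid, "species": "Su", "gene_id": gid, "pair": pair.su_source[gid]}
        )
    alleles = pd.DataFrame(allele_rows).set_index("allele_id", drop=False)

    n = len(sc_ids)
    b0 = rng.normal(config.base_mean_log2, config.base_sd_log2, size=n)
    b0_map = dict(zip(sc_ids, b0))

    def pick(frac: float) -> set[str]:
        k = int(round(frac * n))
        return set(rng.choice(sc_ids, size=k, replace=False).tolist()) if k else set()

    effects = {
        "medium": pick(eff.medium_frac),
        "temperature": pick(eff.temperature_frac),
        "subgenome": pick(eff.subgenome_frac),
        "interaction": pick(eff.interaction_frac),
    }
    effect_signs = {
        factor: {g: int(s) for g, s in zip(sorted(genes), rng.choice([-1, 1], size=len(genes)))}
        for factor, genes in effects.items()
    }

    lib_factor = np.exp(rng.normal(0.0, 0.15, size=len(samples)))

    mean_cols = {}
    for j, s in samples.iterrows():
        col = np.zeros(len(alleles))
        for i, al in enumerate(alleles.itertuples()):
            if s.strain == "ParentSc" and al.species != "Sc":
                continue
            if s.strain == "ParentSu" and al.species != "Su":
                continue
            anchor = al.pair
            log2m = b0_map[anchor]
            if anchor in effects["medium"] and s.medium == "Gly":
                log2m += effect_signs["medium"][anchor] * eff.medium_log2
            if anchor in effects["temperature"] and s.temperature == 16:
                log2m += effect_signs["temperature"][anchor] * eff.temperature_log2
            if anchor in effects["subgenome"] and al.species == "Su":
                log2m += effect_signs["subgenome"][anchor] * eff.subgenome_log2
            if (
                anchor in effects["interaction"]
                and al.species == eff.interaction_species
                and s.strain.startswith("HMt")
                and s.mitotype == eff.interaction_mitotype
                and (s.medium, s.temperature) == eff.interaction_condition
            ):
                log2m += eff.interaction_log2
            col[i] = 2.0**log2m
        mean_cols[s.sample_id] = col
    true_means = pd.DataFrame(mean_cols, index=alleles.index)
    # calibrate expression so the average expected library is lib_size_mean
    depth_scale = config.lib_size_mean / true_means.sum(axis=0).mean()
    true_means *= depth_scale
    lib_factors = pd.Series(lib_factor, index=true_means.columns, name="lib_factor")

    mu = true_means.to_numpy() * lib_factor[None, :]
    if config.dispersion > 1e-12:
        size = 1.0 / config.dispersion
        p = size / (size + np.maximum(mu, 1e-12))
        draws = np.where(mu > 0, rng.negative_binomial(size, p), 0)
    else:
        draws = np.where(mu > 0, rng.poisson(np.maximum(mu, 0)), 0)
    counts = pd.DataFrame(draws.astype(np.int64), index=alleles.index, columns=true_means.columns)

    mitotypes = {
        s.sample_id: s.mitotype for s in samples.itertuples() if s.strain.startswith("HMt")
    }
    return TruthTable(
        samples=samples,
        true_means=true_means,
        lib_factors=lib_factors,
        counts=counts,
        alleles=alleles.reset_index(drop=True),
        effects=effects,
        effect_signs=effect_signs,
        relations=_truth_relations(pair),
        mitotypes=mitotypes,
    )


def simulate_reads(
    pair: ParentalPair,
    truth: TruthTable,
    config: SimConfig,
    samples: Iterable[str] | None = None,
) -> dict[str, list[tuple[str, str]]]:
    """Single-end reads for each requested sample: one read per counted copy.

    Read starts are uniform within the gene; substitution errors are i.i.d. at
    ``seq_error_rate``.  Read ids encode ``sample|species|gene|start|serial``
    (truth for evaluation only).  Returns sample -> list of (read_id, seq).
    """
    if samples is None:
        samples = list(truth.counts.columns)
    species_of = dict(zip(truth.alleles.allele_id, truth.alleles.species))
    seq_cache = {
        (g.species, g.gene_id): encode_seq(g.sequence)
        for sp in pair.genes
        for g in pair.genes[sp]
    }
    L = config.read_length
    out: dict[str, list[tuple[str, str]]] = {}
    for sample in samples:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 3, _stable_hash(sample)])
        )
        reads: list[tuple[str, str]] = []
        col = truth.counts[sample]
        for allele_id, c in col.items():
            c = int(c)
            if c == 0:
                continue
            sp = species_of[allele_id]
            codes = seq_cache[(sp, allele_id)]
            starts = rng.integers(0, codes.size - L + 1, size=c)
            for serial, st in enumerate(starts):
                read = codes[st : st + L]
                if config.seq_error_rate > 0:
                    read = _mutate(rng, read, config.seq_error_rate)
                reads.append(
                    (f"{sample}|{sp}|{allele_id}|{st}|{serial}", decode_seq(read))
                )
        out[sample] = reads
    return out


def _stable_hash(text: str) -> int:
    """Deterministic small hash of a string (Python's hash() is salted)."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return h
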