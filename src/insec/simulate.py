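"""Synthetic WGS data with a known truth, for exercising the corrector.

The generator emulates a whole-genome resequencing experiment at reduced
scale: a uniform-random genome with annotated gene regions, an individual
genome diverged from the reference by planted SNPs (so the gene reference
I_g differs from the individual's true gene T_g), and uniformly placed
100 bp single- or paired-end reads carrying uniform substitution errors at
an Illumina-like rate (0.5-2%, default 1%).  Every injected error is logged
so TP/FP/FN/TN can be tallied exactly.

Everything is reproducible from the seed: independent RNG streams are
derived per stage so, e.g., changing the error rate does not reshuffle the
genome.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .extract import _CODE, decode, encode
from .io import GeneReference, Read

_GENOME_STREAM = 1
_SNP_STREAM = 2
_READ_STREAM = 3
_DECOY_STREAM = 4


@dataclass(frozen=True)
class DecoyRepeat:
    """Duplicate a gene subsequence at a distant locus (slightly diverged)
    so some extracted reads genuinely come from elsewhere in the genome."""

    gene_index: int = 0
    start: int = 0  # offset within the gene
    length: int = 500
    divergence: float = 0.01


@dataclass(frozen=True)
class SimConfig:
    genome_len: int
    gene_intervals: tuple
    snp_rate: float = 0.001
    error_rate: float = 0.01
    read_len: int = 100
    coverage: float = 30.0
    layout: str = "single"
    insert_mean: int = 300
    insert_sd: int = 30
    seed: int = 42
    decoy_repeat: Optional[DecoyRepeat] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_intervals",
                           tuple((int(s), int(e)) for s, e in self.gene_intervals))
        ivs = sorted(self.gene_intervals)
        for (s, e) in ivs:
            if not (0 <= s < e <= self.genome_len):
                raise ValueError(f"gene interval ({s},{e}) outside the genome")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("gene intervals overlap")
        if not (0 <= self.snp_rate < 1 and 0 <= self.error_rate < 1):
            raise ValueError("rates must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.layout not in ("single", "paired"):
            raise ValueError("layout must be 'single' or 'paired'")
        if self.read_len < 1 or self.read_len > self.genome_len:
            raise ValueError("read length must fit in the genome")


@dataclass
class TruthLog:
    """Injected-error log plus each read's true origin window.

    ``entries[read_id]`` lists (pos_in_read, true_base, observed_base);
    ``origins[read_id]`` is (genome_start, genome_end, strand) of the
    error-free source window on the individual genome.
    """

    entries: dict = field(default_factory=dict)
    origins: dict = field(default_factory=dict)

    def rows(self):
        for rid in self.entries:
            for pos, true, obs in self.entries[rid]:
                yield rid, pos, true, obs

    def n_errors(self) -> int:
        return sum(len(v) for v in self.entries.values())


def place_gene_intervals(genome_len: int, lengths: Sequence[int],
                         margin: int = 1000) -> list:
    """Evenly spaced non-overlapping intervals for the given gene lengths."""
    total = sum(lengths)
    gap = (genome_len - 2 * margin - total) // max(1, len(lengths) + 1)
    if gap < 200:
        raise ValueError("genome too short for the requested gene lengths")
    intervals = []
    pos = margin + gap
    for L in lengths:
        intervals.append((pos, pos + L))
        pos += L + gap
    return intervals


def make_genome(config: SimConfig):
    """Uniform-random reference genome plus the gene reference records.

    With ``decoy_repeat`` set, a subsequence of the chosen gene is copied
    (with slight divergence) into the largest intergenic gap, to exercise
    the corrector's repeat ('out') handling.
    """
    rng = np.random.default_rng([config.seed, _GENOME_STREAM])
    codes = rng.integers(0, 4, config.genome_len, dtype=np.uint8)
    if config.decoy_repeat is not None:
        d = config.decoy_repeat
        gs, ge = config.gene_intervals[d.gene_index]
        if gs + d.start + d.length > ge:
            raise ValueError("decoy subsequence exceeds the gene")
        src = codes[gs + d.start:gs + d.start + d.length].copy()
        drng = np.random.default_rng([config.seed, _DECOY_STREAM])
        mut = drng.random(d.length) < d.divergence
        src[mut] = (src[mut] + drng.integers(1, 4, int(mut.sum()))) % 4
        target = _largest_gap_position(config, d.length)
        codes[target:target + d.length] = src
    genome = decode(codes)
    genes = [GeneReference(f"g{i + 1}", genome[s:e], ("sim", s, e))
             for i, (s, e) in enumerate(config.gene_intervals)]
    return genome, genes


def _largest_gap_position(config: SimConfig, length: int) -> int:
    bounds = [(0, 0)] + sorted(config.gene_intervals) + [
        (config.genome_len, config.genome_len)]
    best, pos = -1, 0
    for (_, e1), (s2, _) in zip(bounds, bounds[1:]):
        gap = s2 - e1
        if gap > best:
            best, pos = gap, e1 + (gap - length) // 2
    if best < length + 200:
        raise ValueError("no intergenic gap large enough for the decoy")
    return pos


def plant_snps(genome: str, gene_intervals: Sequence, snp_rate: float,
               seed: int):
    """Mutate the reference into an individual genome at the SNP rate.

    Every position mutates independently to a different uniform base with
    probability ``snp_rate``.  Returns (individual_genome, snp_table) where
    the table rows are (pos, ref_base, alt_base, gene_index) with gene_index
    -1 outside all gene intervals.
    """
    if snp_rate < 0:
        raise ValueError("snp_rate must be >= 0")
    rng = np.random.default_rng([seed, _SNP_STREAM])
    codes = encode(genome).copy()
    hit = np.nonzero(rng.random(len(genome)) < snp_rate)[0]
    old = codes[hit]
    codes[hit] = (old + rng.integers(1, 4, hit.size)) % 4
    gene_of = np.full(len(genome), -1, dtype=np.int64)
    for gi, (s, e) in enumerate(gene_intervals):
        gene_of[s:e] = gi
    table = [(int(p), genome[p], decode(codes[p:p + 1]), int(gene_of[p]))
             for p in hit]
    return decode(codes), table


def simulate_reads(individual_genome: str, config: SimConfig):
    """Simulate reads from the individual genome; returns (reads, TruthLog).

    Reads are uniformly placed on both strands; each base flips to a
    different uniform base with probability ``error_rate``.  Paired layout
    draws the fragment length from Normal(insert_mean, insert_sd) truncated
    at the read length, and emits reference-forward/reverse mates with
    ``/1``/``/2`` id suffixes.
    """
    rng = np.random.default_rng([config.seed, _READ_STREAM])
    codes = encode(individual_genome)
    L = config.read_len
    glen = len(individual_genome)
    truth = TruthLog()
    reads: list[Read] = []
    if config.layout == "single":
        n = int(round(config.coverage * glen / L))
        starts = rng.integers(0, glen - L + 1, n)
        strands = rng.integers(0, 2, n)
        mats = codes[starts[:, None] + np.arange(L)]
        ids = [f"r{i:07d}" for i in range(n)]
        mates = ["unpaired"] * n
        spans = [(int(s), int(s) + L, "-" if st else "+")
                 for s, st in zip(starts, strands)]
    else:
        n_frag = int(round(config.coverage * glen / (2 * L)))
        frag = np.rint(rng.normal(config.insert_mean, config.insert_sd,
                                  n_frag)).astype(np.int64)
        frag = np.clip(frag, L, glen)
        starts = (rng.random(n_frag) * (glen - frag + 1)).astype(np.int64)
        flip = rng.integers(0, 2, n_frag)
        left = starts
        right = starts + frag - L
        m1_start = np.where(flip == 0, left, right)
        m2_start = np.where(flip == 0, right, left)
        m1_strand = flip  # first mate reads the fragment's leading strand
        m2_strand = 1 - flip
        starts = np.empty(2 * n_frag, dtype=np.int64)
        strands = np.empty(2 * n_frag, dtype=np.int64)
        starts[0::2], starts[1::2] = m1_start, m2_start
        strands[0::2], strands[1::2] = m1_strand, m2_strand
        mats = codes[starts[:, None] + np.arange(L)]
        ids, mates = [], []
        for i in range(n_frag):
            ids += [f"p{i:07d}/1", f"p{i:07d}/2"]
            mates += ["first", "second"]
        spans = [(int(s), int(s) + L, "-" if st else "+")
                 for s, st in zip(starts, strands)]
    rc = strands == 1
    mats[rc] = 3 - mats[rc][:, ::-1]
    err = rng.random(mats.shape) < config.error_rate
    ei, ej = np.nonzero(err)
    old = mats[ei, ej].copy()
    mats[ei, ej] = (old + rng.integers(1, 4, ei.size)) % 4
    flat = decode(mats.reshape(-1))
    for i, rid in enumerate(ids):
        reads.append(Read(rid, flat[i * L:(i + 1) * L], None, mates[i]))
        truth.origins[rid] = spans[i]
    for idx in range(ei.size):
        rid = ids[ei[idx]]
        truth.entries.setdefault(rid, []).append(
            (int(ej[idx]), "ACGT"[old[idx]], reads[ei[idx]].seq[ej[idx]]))
    return reads, truth


@dataclass
class SimResult:
    config: SimConfig
    genome_ref: str
    genome_individual: str
    genes: list
    snp_table: list
    reads: list
    truth: TruthLog

    def true_gene(self, gene_index: int) -> str:
        s, e = self.config.gene_intervals[gene_index]
        return self.genome_individual[s:e]


def run_simulation(config: SimConfig) -> SimResult:
    """Full study generation: genome, genes, SNPs, reads, truth log."""
    genome, genes = make_genome(config)
    individual, snp_table = plant_snps(genome, config.gene_intervals,
                                       config.snp_rate, config.seed)
    reads, truth = simulate_reads(individual, config)
    return SimResult(config, genome, individual, genes, snp_table, reads, truth)
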