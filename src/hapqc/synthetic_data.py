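"""Synthetic diploid genomes, fragmented assemblies, reads, and gene annotations.

The generator emulates the situation that motivates haplotig purging: a diploid
genome with substantial per-base heterozygosity (default 1.65%, i.e., roughly
one SNP per 60 bp) is assembled from short reads, and regions where the two
haplotypes diverge strongly come out as two separate scaffolds at half read
depth, while less variable regions collapse into one scaffold at full depth.
Truth bookkeeping (which scaffold is whose haplotig) is retained so purging can
be scored.  Gene annotations carry the characteristic intron-length structure
of plant genomes: a sharp "minimal intron" peak (89 +/- 12 bp) over a
long-intron log-normal tail.

All generators take an explicit integer seed and hold no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Scaffold, write_gff3

__all__ = [
    "DiploidGenome",
    "SimulatedAssembly",
    "IntronMixtureParams",
    "GeneStructure",
    "simulate_diploid",
    "simulate_fragmented_assembly",
    "simulate_reads",
    "simulate_gene_annotation",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class DiploidGenome:
    """Two haplotype sequences of equal length plus the positions where they differ."""

    hapA: str
    hapB: str
    het_positions: np.ndarray  # sorted bp offsets where hapA != hapB
    het_rate: float
    seed: int

    def __post_init__(self) -> None:
        assert len(self.hapA) == len(self.hapB)

    def __len__(self) -> int:
        return len(self.hapA)


@dataclass
class SimulatedAssembly:
    """A fragmented assembly with truth labels for haplotig pairs.

    ``truth_pairs`` lists (primary_id, haplotig_id); ``collapsed_ids`` are the
    merged single-scaffold segments; ``depth_table`` maps every scaffold id to
    its simulated mean read depth.
    """

    scaffolds: list[Scaffold]
    truth_pairs: list[tuple[str, str]]
    collapsed_ids: list[str]
    depth_table: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pair_ids = {i for p in self.truth_pairs for i in p}
        assert not (pair_ids & set(self.collapsed_ids))
        all_ids = {s.id for s in self.scaffolds}
        assert pair_ids | set(self.collapsed_ids) == all_ids


@dataclass(frozen=True)
class IntronMixtureParams:
    """Two-component intron-length mixture: a Gaussian short-intron peak plus a
    log-normal long tail.

    Defaults place the peak at 89 +/- 12 bp with 35% of introns in it, a weight
    at which roughly a third of all introns fall in the minimal-intron window,
    as seen in large-genome plants; the tail (median ~600 bp) keeps the overall
    mean a few hundred bp.
    """

    peak_mean: float = 89.0
    peak_sd: float = 12.0
    peak_weight: float = 0.35
    tail_log_mean: float = float(np.log(600.0))
    tail_log_sd: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 <= self.peak_weight <= 1.0):
            raise ValueError("peak_weight must be in [0, 1]")
        if self.peak_sd <= 0:
            raise ValueError("peak_sd must be > 0")


@dataclass
class GeneStructure:
    """A simulated gene: placement on a scaffold plus exon/intron lengths."""

    id: str
    seq_id: str
    start: int  # 0-based half-open span over the scaffold coordinate system
    end: int
    strand: str
    exon_lengths: list[int]
    intron_lengths: list[int]


# ---------------------------------------------------------------------------
# diploid genome
# ---------------------------------------------------------------------------

def simulate_diploid(length: int, het_rate: float, seed: int) -> DiploidGenome:
    """Simulate a diploid genome of ``length`` bp with i.i.d. heterozygous sites.

    hapA is uniform over ACGT; each position is independently heterozygous with
    probability ``het_rate``, in which case hapB carries a different base.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0.0 <= het_rate < 0.25):
        raise ValueError("het_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    codes_a = rng.integers(0, 4, size=length, dtype=np.int8)
    het = rng.random(length) < het_rate
    het_positions = np.flatnonzero(het)
    codes_b = codes_a.copy()
    # substitute to one of the three other bases, uniformly
    shift = rng.integers(1, 4, size=het_positions.size, dtype=np.int8)
    codes_b[het_positions] = (codes_a[het_positions] + shift) % 4
    hapA = _BASES[codes_a].tobytes().decode()
    hapB = _BASES[codes_b].tobytes().decode()
    return DiploidGenome(
        hapA=hapA,
        hapB=hapB,
        het_positions=het_positions,
        het_rate=het_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# fragmented assembly
# ---------------------------------------------------------------------------

def simulate_fragmented_assembly(
    genome: DiploidGenome,
    segment_len: int = 10_000,
    divergence_threshold: float = 0.01,
    lambda_hom: float = 67.0,
    seed: int = 0,
) -> SimulatedAssembly:
    """Tile the genome into segments and emit scaffolds per local divergence.

    A segment whose local heterozygous-site density exceeds
    ``divergence_threshold`` yields TWO scaffolds (one per haplotype), each at
    depth ~ Poisson(lambda_hom / 2); otherwise ONE consensus scaffold (the hapA
    copy) at depth ~ Poisson(lambda_hom).  Segment-level granularity mirrors
    how assemblers split whole scaffolds at divergent regions without modeling
    assembler internals.  The trailing partial segment is merged into the last
    full one so the collapsed/one-haplotype concatenation reconstructs hapA.
    """
    n = len(genome)
    if segment_len < 200:
        raise ValueError("segment_len must be >= 200 (too short for similarity estimation)")
    if segment_len > n:
        raise ValueError("segment_len exceeds genome length")
    if lambda_hom <= 0:
        raise ValueError("lambda_hom must be > 0")
    rng = np.random.default_rng(seed)

    starts = list(range(0, n, segment_len))
    if len(starts) > 1 and n - starts[-1] < segment_len:
        starts.pop()  # merge the short tail into the previous segment
    bounds = [(s, starts[i + 1] if i + 1 < len(starts) else n) for i, s in enumerate(starts)]

    het = genome.het_positions
    scaffolds: list[Scaffold] = []
    truth_pairs: list[tuple[str, str]] = []
    collapsed_ids: list[str] = []
    depth_table: dict[str, float] = {}
    width = len(str(len(bounds)))
    for i, (s, e) in enumerate(bounds):
        n_het = int(np.searchsorted(het, e) - np.searchsorted(het, s))
        base = f"seg{i:0{width}d}"
        if n_het / (e - s) > divergence_threshold:
            pid, hid = f"{base}_p", f"{base}_h"
            scaffolds.append(Scaffold(id=pid, seq=genome.hapA[s:e]))
            scaffolds.append(Scaffold(id=hid, seq=genome.hapB[s:e]))
            depth_table[pid] = float(rng.poisson(lambda_hom / 2.0))
            depth_table[hid] = float(rng.poisson(lambda_hom / 2.0))
            truth_pairs.append((pid, hid))
        else:
            scaffolds.append(Scaffold(id=base, seq=genome.hapA[s:e]))
            depth_table[base] = float(rng.poisson(lambda_hom))
            collapsed_ids.append(base)
    return SimulatedAssembly(
        scaffolds=scaffolds,
        truth_pairs=truth_pairs,
        collapsed_ids=collapsed_ids,
        depth_table=depth_table,
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(
    genome: DiploidGenome,
    coverage: float,
    read_len: int,
    seed: int,
    error_rate: float = 0.0,
) -> list[str]:
    """Draw error-free reads uniformly from both haplotypes, forward strand only.

    Each haplotype contributes coverage/2; total bases ~= coverage * length.
    An optional uniform substitution ``error_rate`` exercises the error peak at
    multiplicity 1 in downstream k-mer spectra.
    """
    n = len(genome)
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if read_len > n:
        raise ValueError("read_len exceeds genome length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(coverage * n / read_len))
    n_a = n_reads // 2
    reads: list[str] = []
    for hap, count in ((genome.hapA, n_reads - n_a), (genome.hapB, n_a)):
        starts = rng.integers(0, n - read_len + 1, size=count)
        reads.extend(hap[s : s + read_len] for s in starts)
    if error_rate > 0.0:
        reads = _add_errors(reads, error_rate, rng)
    return reads


def _add_errors(reads: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    arr = np.frombuffer("".join(reads).encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    lut = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
    codes = np.array([lut.get(bytes(b), 0) for b in arr[hit]], dtype=np.int8)
    shift = rng.integers(1, 4, size=hit.size, dtype=np.int8)
    arr[hit] = _BASES[(codes + shift) % 4]
    flat = arr.tobytes().decode()
    out, pos = [], 0
    for r in reads:
        out.append(flat[pos : pos + len(r)])
        pos += len(r)
    return out


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def simulate_gene_annotation(
    n_genes: int,
    params: IntronMixtureParams | None = None,
    seed: int = 0,
    mean_introns_per_gene: float = 3.87,
    mean_exon_len: float = 285.0,
    intergenic_len: int = 2000,
    seq_id: str = "chrSim",
) -> list[GeneStructure]:
    """Simulate gene structures with a minimal-intron length mixture.

    Intron count per gene is geometric (support >= 0) with the given mean;
    intron lengths come from the Gaussian-peak + log-normal-tail mixture,
    rounded and floored at 10 bp; exon lengths are log-normal with the given
    mean.  Genes are laid head-to-tail along one synthetic scaffold.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    params = params or IntronMixtureParams()
    rng = np.random.default_rng(seed)

    # geometric on {1,2,...} has mean 1/p; shift to support {0,1,...}
    p = 1.0 / (1.0 + mean_introns_per_gene)
    intron_counts = rng.geometric(p, size=n_genes) - 1

    # exon log-normal with the requested arithmetic mean
    exon_sigma = 0.75
    exon_mu = np.log(mean_exon_len) - exon_sigma**2 / 2.0

    genes: list[GeneStructure] = []
    pos = 0
    width = len(str(n_genes))
    for g in range(n_genes):
        k = int(intron_counts[g])
        exons = np.maximum(
            np.round(rng.lognormal(exon_mu, exon_sigma, size=k + 1)).astype(int), 3
        )
        introns = _draw_intron_lengths(k, params, rng)
        span = int(exons.sum() + introns.sum())
        genes.append(
            GeneStructure(
                id=f"gene{g:0{width}d}",
                seq_id=seq_id,
                start=pos,
                end=pos + span,
                strand="+",
                exon_lengths=[int(x) for x in exons],
                intron_lengths=[int(x) for x in introns],
            )
        )
        pos += span + intergenic_len
    return genes


def _draw_intron_lengths(
    k: int, params: IntronMixtureParams, rng: np.random.Generator
) -> np.ndarray:
    if k == 0:
        return np.empty(0, dtype=int)
    from_peak = rng.random(k) < params.peak_weight
    lengths = np.empty(k)
    n_peak = int(from_peak.sum())
    lengths[from_peak] = rng.normal(params.peak_mean, params.peak_sd, size=n_peak)
    lengths[~from_peak] = rng.lognormal(
        params.tail_log_mean, params.tail_log_sd, size=k - n_peak
    )
    return np.maximum(np.round(lengths).astype(int), 10)


def genes_to_gff3(genes: list[GeneStructure], path) -> None:
    """Write simulated gene structures (gene + exon rows) as GFF3."""
    feats = []
    for g in genes:
        feats.append((g.seq_id, "gene", g.start, g.end, g.strand, {"ID": g.id}))
        pos = g.start
        for i, ex in enumerate(g.exon_lengths):
            feats.append(
                (
                    g.seq_id,
                    "exon",
                    pos,
                    pos + ex,
                    g.strand,
                    {"ID": f"{g.id}.exon{i + 1}", "Parent": g.id},
                )
            )
            pos += ex
            if i < len(g.intron_lengths):
                pos += g.intron_lengths[i]
    write_gff3(feats, path)
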