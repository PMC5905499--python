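"""Assembly statistics: N50/NG50, gap census, size classes, contig termini.

Conventions follow standard assembly reporting: Nx is the length at which the
cumulative sum of descending-sorted lengths first reaches x% of the total (of
the estimated genome size for NGx); contigs are obtained by cutting scaffolds
at runs of >= ``min_run`` consecutive Ns; percentage denominators are explicit
because the field mixes them (gap percentages use the gapped assembly size,
genome-relative percentages use an externally estimated genome size).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import re

from intervaltree import IntervalTree

from .io_formats import Category, Interval, Scaffold

__all__ = [
    "AssemblyStats",
    "TerminusClassification",
    "Contig",
    "GapRecord",
    "cut_at_gaps",
    "nx_stats",
    "assembly_summary",
    "classify_termini",
    "percent",
    "inferred_repeat_pct",
    "ssr_density",
]


@dataclass(frozen=True)
class Contig:
    """A gap-free segment of a scaffold, in scaffold coordinates."""

    scaffold_id: str
    start: int
    end: int
    seq: str


@dataclass(frozen=True)
class GapRecord:
    scaffold_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AssemblyStats:
    n_sequences: int
    total_with_gaps: int
    total_without_gaps: int
    n_over_10kb: int
    n_over_20kb: int
    n_over_100kb: int
    n_over_1mb: int
    longest: int
    average: float
    n50: int
    l50: int
    ng50: int | None
    gc_pct: float
    gap_count: int
    gap_bp: int
    gap_pct: float


@dataclass
class TerminusClassification:
    """Per-category contig-termini counts and percentages."""

    counts: dict[str, int]
    n_termini: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.n_termini == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.n_termini for k, v in self.counts.items()}


# ---------------------------------------------------------------------------
# gaps and contigs
# ---------------------------------------------------------------------------

def cut_at_gaps(
    scaffold: Scaffold, min_run: int = 25
) -> tuple[list[Contig], list[GapRecord]]:
    """Cut a scaffold at maximal runs of >= ``min_run`` consecutive Ns.

    N-runs shorter than ``min_run`` stay inside contigs; contigs and gaps
    concatenate back to the scaffold exactly.  An all-N scaffold yields zero
    contigs and one gap.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    gaps = [
        GapRecord(scaffold.id, m.start(), m.end())
        for m in re.finditer(f"N{{{min_run},}}", scaffold.seq)
    ]
    contigs: list[Contig] = []
    pos = 0
    for g in gaps:
        if g.start > pos:
            contigs.append(Contig(scaffold.id, pos, g.start, scaffold.seq[pos : g.start]))
        pos = g.end
    if pos < len(scaffold):
        contigs.append(Contig(scaffold.id, pos, len(scaffold), scaffold.seq[pos:]))
    return contigs, gaps


# ---------------------------------------------------------------------------
# Nx / NGx
# ---------------------------------------------------------------------------

def nx_stats(
    lengths: Sequence[int], x: float = 50.0, genome_size: int | None = None
) -> tuple[int, int] | tuple[int, int, int]:
    """(Nx, Lx) and, when ``genome_size`` is given, NGx.

    Nx: sort lengths descending; the length at which the cumulative sum first
    reaches x% of the total (inclusive tie convention).  Lx counts the
    sequences up to and including that one.  NGx uses genome_size as the
    denominator; it is still computed (and may exceed the data) when
    genome_size is below the assembly total.
    """
    if len(lengths) == 0:
        raise ValueError("lengths must be nonempty")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr[-1] <= 0:
        raise ValueError("all lengths must be > 0")
    cum = np.cumsum(arr)
    threshold = x / 100.0 * cum[-1]
    idx = int(np.searchsorted(cum, threshold))
    nx, lx = int(arr[idx]), idx + 1
    if genome_size is None:
        return nx, lx
    g_threshold = x / 100.0 * genome_size
    if cum[-1] < g_threshold:
        ngx = int(arr[-1])  # assembly never reaches x% of the genome
    else:
        ngx = int(arr[int(np.searchsorted(cum, g_threshold))])
    return nx, lx, ngx


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def assembly_summary(
    scaffolds: Iterable[Scaffold],
    genome_size: int | None = None,
    min_len: int = 1000,
) -> AssemblyStats:
    """Headline assembly statistics over scaffolds of at least ``min_len`` bp.

    Gap accounting counts every N run (cut_at_gaps with min_run=1); GC% is
    computed over non-N bases only; gap_pct uses the gapped total as its
    denominator.
    """
    kept = [s for s in scaffolds if len(s) >= min_len]
    if not kept:
        raise ValueError(f"no scaffolds of length >= {min_len}")
    lengths = np.array([len(s) for s in kept], dtype=np.int64)
    gap_count = 0
    gap_bp = 0
    gc = 0
    non_n = 0
    for s in kept:
        _, gaps = cut_at_gaps(s, min_run=1)
        gap_count += len(gaps)
        gap_bp += sum(g.length for g in gaps)
        gc += s.seq.count("G") + s.seq.count("C")
        non_n += len(s) - s.seq.count("N")
    total = int(lengths.sum())
    if genome_size is not None:
        n50, l50, ng50 = nx_stats(lengths, 50.0, genome_size)
    else:
        n50, l50 = nx_stats(lengths, 50.0)
        ng50 = None
    return AssemblyStats(
        n_sequences=len(kept),
        total_with_gaps=total,
        total_without_gaps=total - gap_bp,
        n_over_10kb=int((lengths > 10_000).sum()),
        n_over_20kb=int((lengths > 20_000).sum()),
        n_over_100kb=int((lengths > 100_000).sum()),
        n_over_1mb=int((lengths > 1_000_000).sum()),
        longest=int(lengths.max()),
        average=float(lengths.mean()),
        n50=n50,
        l50=l50,
        ng50=ng50,
        gc_pct=100.0 * gc / non_n if non_n else 0.0,
        gap_count=gap_count,
        gap_bp=gap_bp,
        gap_pct=100.0 * gap_bp / total,
    )


# ---------------------------------------------------------------------------
# contig termini
# ---------------------------------------------------------------------------

_PRECEDENCE = [
    Category.ZERO_COVERAGE,
    Category.INTERSPERSED_REPEAT,
    Category.TANDEM_REPEAT,
    Category.GENE,
]


def classify_termini(
    contigs: Iterable[Contig],
    intervals: Iterable[Interval],
    flank: int = 0,
    scaffold_lengths: dict[str, int] | None = None,
) -> TerminusClassification:
    """Assign each contig terminus one annotation category.

    Termini are the scaffold-coordinate positions of each contig's first and
    last base.  A terminus overlapping several interval categories gets ONE by
    precedence zero_coverage > interspersed_repeat > tandem_repeat > gene
    (zero-coverage is evidence-based, annotations are not); a terminus hitting
    nothing counts as 'none'.  ``flank`` widens the terminus point by +/-flank.
    """
    trees: dict[tuple[str, Category], IntervalTree] = {}
    for iv in intervals:
        trees.setdefault((iv.seq_id, iv.category), IntervalTree()).addi(
            iv.start, iv.end
        )
    counts = {c.value: 0 for c in _PRECEDENCE}
    counts["none"] = 0
    n = 0
    for contig in contigs:
        if scaffold_lengths is not None:
            limit = scaffold_lengths.get(contig.scaffold_id)
            if limit is not None and contig.end > limit:
                raise ValueError(
                    f"contig {contig.scaffold_id}:{contig.start}-{contig.end} "
                    f"extends past scaffold length {limit}"
                )
        for pos in (contig.start, contig.end - 1):
            n += 1
            lo, hi = pos - flank, pos + flank + 1
            for cat in _PRECEDENCE:
                tree = trees.get((contig.scaffold_id, cat))
                if tree is not None and tree.overlap(lo, hi):
                    counts[cat.value] += 1
                    break
            else:
                counts["none"] += 1
    return TerminusClassification(counts=counts, n_termini=n)


# ---------------------------------------------------------------------------
# report arithmetic helpers
# ---------------------------------------------------------------------------

def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage with explicit operands and rounding, as printed in reports."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round(100.0 * numerator / denominator, decimals)


def inferred_repeat_pct(
    masked_bp: int, assembly_bp: int, genome_size: int, decimals: int = 1
) -> float:
    """Genome-wide repeat percentage inferred from assembly masking.

    Adds the genome bases not captured by the assembly (genome_size -
    assembly_bp, presumed repeat-rich) to the masked bases, over genome_size.
    """
    return percent(masked_bp + (genome_size - assembly_bp), genome_size, decimals)


def ssr_density(n_ssr: int, total_bp: int) -> float:
    """Simple-sequence-repeat density as count per Mbp."""
    return n_ssr / (total_bp / 1e6)
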