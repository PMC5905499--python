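"""Gene-model triage, confidence classes, feature statistics, minimal introns.

Triage follows the evidence rules used in plant genome annotation pipelines:
a model is selected on homology (Cscore >= 0.5 and peptide coverage >= 0.5) or
on transcript support (EST coverage with CDS repeat overlap < 20%), except
that models whose CDS overlaps repeats by more than 20% must clear a strict
bar (Cscore >= 0.9 and coverage >= 70%).  Cscore — the ratio of a peptide's
BLASTP score to the mutual-best-hit score — is an input here, not computed.

The "minimal intron" class is anything within n_sd standard deviations of the
dominant short-intron peak (default 89 +/- 12 bp, 3 SD, i.e., 53-125 bp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assembly_metrics import nx_stats

__all__ = [
    "GeneModelRecord",
    "IntronPeakParams",
    "select_gene_model",
    "confidence_class",
    "minimal_intron_bounds",
    "minimal_intron_stats",
    "gene_feature_summary",
    "average_per_gene",
]


@dataclass
class GeneModelRecord:
    """A predicted gene with its evidence scores and exon/intron structure."""

    id: str
    cscore: float = 0.0
    peptide_coverage: float = 0.0
    repeat_overlap: float = 0.0
    has_transcript_coverage: bool = False
    est_cds_coverage: float = 0.0
    exon_lengths: list[int] = field(default_factory=list)
    intron_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("peptide_coverage", "repeat_overlap", "est_cds_coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.exon_lengths and self.intron_lengths:
            if len(self.intron_lengths) != len(self.exon_lengths) - 1:
                raise ValueError(
                    f"gene {self.id!r}: intron count must be exon count - 1"
                )


@dataclass(frozen=True)
class IntronPeakParams:
    """Short-intron peak location/width and the SD multiplier for the window."""

    mean: float = 89.0
    sd: float = 12.0
    n_sd: int = 3

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_sd < 1:
            raise ValueError("n_sd must be >= 1")


# ---------------------------------------------------------------------------
# triage
# ---------------------------------------------------------------------------

def select_gene_model(r: GeneModelRecord) -> tuple[bool, str]:
    """Apply the evidence selection rule; returns (selected, reason).

    Repeat-heavy models (repeat_overlap > 0.20) are held to the strict branch:
    cscore >= 0.9 and peptide_coverage >= 0.70.  Otherwise selection is
    (cscore >= 0.5 AND peptide_coverage >= 0.5) OR (transcript coverage AND
    repeat_overlap < 0.20).  At exactly 20% repeat overlap only the homology
    branch can select.  The reason string names the branch that fired (or the
    one that failed) so decisions can be audited.
    """
    for name in ("cscore", "peptide_coverage", "repeat_overlap"):
        if getattr(r, name) is None:
            raise ValueError(f"gene {r.id!r}: missing evidence field {name!r}")
    if r.repeat_overlap > 0.20:
        if r.cscore >= 0.9 and r.peptide_coverage >= 0.70:
            return True, "strict: repeat_overlap > 20% with cscore >= 0.9 and coverage >= 70%"
        return False, "rejected: repeat_overlap > 20% and strict homology bar not met"
    if r.cscore >= 0.5 and r.peptide_coverage >= 0.5:
        return True, "homology: cscore >= 0.5 and peptide_coverage >= 0.5"
    if r.has_transcript_coverage and r.repeat_overlap < 0.20:
        return True, "transcript: EST support with repeat_overlap < 20%"
    return False, "rejected: no homology or transcript branch satisfied"


def confidence_class(r: GeneModelRecord) -> str:
    """'high' iff full or >=80% EST CDS coverage, or Cscore >= 0.5; else 'low'."""
    if r.est_cds_coverage == 1.0 or r.est_cds_coverage >= 0.80 or r.cscore >= 0.5:
        return "high"
    return "low"


# ---------------------------------------------------------------------------
# minimal introns
# ---------------------------------------------------------------------------

def minimal_intron_bounds(p: IntronPeakParams | None = None) -> tuple[float, float]:
    """(low, high) = mean -/+ n_sd * sd, with low clamped to 1 bp."""
    p = p or IntronPeakParams()
    low = p.mean - p.n_sd * p.sd
    high = p.mean + p.n_sd * p.sd
    if low < 1:
        warnings.warn(
            f"minimal-intron lower bound {low:.0f} < 1 bp; clamped to 1", stacklevel=2
        )
        low = 1.0
    return low, high


def minimal_intron_stats(
    genes: Iterable[GeneModelRecord] | Iterable[Sequence[int]],
    bounds: tuple[float, float] | None = None,
) -> tuple[float | None, float | None]:
    """(pct of introns in the minimal window, pct of intron-containing genes
    with at least one such intron).

    ``genes`` may be GeneModelRecords or bare per-gene intron-length lists.
    Genes without introns are excluded from the gene-percentage denominator.
    With no introns at all both statistics are undefined and returned as None.
    """
    low, high = bounds if bounds is not None else minimal_intron_bounds()
    n_introns = n_minimal = 0
    n_genes_with_introns = n_genes_with_minimal = 0
    for g in genes:
        introns = g.intron_lengths if isinstance(g, GeneModelRecord) else list(g)
        if not introns:
            continue
        n_genes_with_introns += 1
        hits = sum(1 for x in introns if low <= x <= high)
        n_introns += len(introns)
        n_minimal += hits
        if hits:
            n_genes_with_minimal += 1
    if n_introns == 0:
        return None, None
    return (
        100.0 * n_minimal / n_introns,
        100.0 * n_genes_with_minimal / n_genes_with_introns,
    )


# ---------------------------------------------------------------------------
# feature statistics
# ---------------------------------------------------------------------------

def average_per_gene(total_features: int, n_genes: int, decimals: int = 2) -> float:
    """Average feature count per gene, rounded as printed in report tables."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    return round(total_features / n_genes, decimals)


def gene_feature_summary(genes: Sequence[GeneModelRecord]) -> dict[str, float]:
    """Counts, per-gene averages, and average/N50 lengths of exons and introns.

    Gene length is the transcription span (exons plus introns).
    """
    n_genes = len(genes)
    exon_lengths = [x for g in genes for x in g.exon_lengths]
    intron_lengths = [x for g in genes for x in g.intron_lengths]
    gene_lengths = [
        sum(g.exon_lengths) + sum(g.intron_lengths) for g in genes if g.exon_lengths
    ]
    out: dict[str, float] = {
        "n_genes": n_genes,
        "n_exons": len(exon_lengths),
        "n_introns": len(intron_lengths),
        "exons_per_gene": average_per_gene(len(exon_lengths), n_genes) if n_genes else 0,
        "introns_per_gene": average_per_gene(len(intron_lengths), n_genes) if n_genes else 0,
    }
    if exon_lengths:
        out["avg_exon_len"] = float(np.mean(exon_lengths))
        out["exon_n50"] = nx_stats(exon_lengths)[0]
    if intron_lengths:
        out["avg_intron_len"] = float(np.mean(intron_lengths))
        out["intron_n50"] = nx_stats(intron_lengths)[0]
    if gene_lengths:
        out["avg_gene_len"] = float(np.mean(gene_lengths))
        out["gene_n50"] = nx_stats(gene_lengths)[0]
    return out
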