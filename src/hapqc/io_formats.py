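"""Readers/writers for the formats the pipeline touches and the shared record model.

All internal coordinates are 0-based, half-open; conversion to and from the
1-based closed convention of GFF3 happens only at the file boundary.  Soft-masked
(lowercase) residues are uppercased on read and masking state is discarded;
ambiguity codes other than N are mapped to N with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Scaffold",
    "Interval",
    "SimilarityMatch",
    "Category",
    "read_fasta",
    "write_fasta",
    "read_psl",
    "read_intervals",
    "read_depth_table",
    "FormatError",
]

_VALID = set("ACGTN")
# IUPAC one-letter ambiguity codes (anything not ACGT/N) collapse to N.
_AMBIG = set("RYSWKMBDHVU")


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line/record."""


class Category(str, Enum):
    """Annotation classes used by the contig-termini analysis."""

    INTERSPERSED_REPEAT = "interspersed_repeat"
    TANDEM_REPEAT = "tandem_repeat"
    GENE = "gene"
    ZERO_COVERAGE = "zero_coverage"
    OTHER = "other"


@dataclass(frozen=True)
class Scaffold:
    """An assembly sequence: id plus residues over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"scaffold {self.id!r} has an empty sequence")
        seq = self.seq.upper()
        bad = set(seq) - _VALID
        if bad:
            if bad - _AMBIG:
                raise FormatError(
                    f"scaffold {self.id!r} contains invalid residues {sorted(bad - _AMBIG)}"
                )
            warnings.warn(
                f"scaffold {self.id!r}: ambiguity codes {sorted(bad)} mapped to N",
                stacklevel=2,
            )
            seq = "".join("N" if c in _AMBIG else c for c in seq)
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """A half-open annotated interval on a scaffold."""

    seq_id: str
    start: int
    end: int
    category: Category = Category.OTHER
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"interval {self.seq_id}:{self.start}-{self.end} has start >= end"
            )
        if self.strand not in "+-.":
            raise FormatError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class SimilarityMatch:
    """A filtered pairwise scaffold alignment summary."""

    query_id: str
    target_id: str
    identity_pct: float
    query_coverage_pct: float
    match_bases: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise FormatError(f"identity_pct {self.identity_pct} outside [0,100]")
        if not (0.0 <= self.query_coverage_pct <= 100.0):
            raise FormatError(
                f"query_coverage_pct {self.query_coverage_pct} outside [0,100]"
            )

    @property
    def is_self_hit(self) -> bool:
        return self.query_id == self.target_id


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Scaffold]:
    """Read a FASTA file into Scaffold records, in file order.

    Headers are tokenized at the first whitespace for the id.  An empty file
    yields an empty list; text before the first ``>`` or an empty sequence body
    is a :class:`FormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header starting with '>'"
                )
            break
    scaffolds: list[Scaffold] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate scaffold id {rec.id!r}")
        seen.add(rec.id)
        scaffolds.append(Scaffold(id=rec.id, seq=str(rec.seq)))
    return scaffolds


def write_fasta(scaffolds: Iterable[Scaffold], path: str | Path, wrap: int = 60) -> None:
    """Write scaffolds as FASTA with sequence lines wrapped at ``wrap`` columns."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    records = (SeqRecord(Seq(s.seq), id=s.id, description="") for s in scaffolds)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# PSL (21-column BLAT output, optional 5-line header)
# ---------------------------------------------------------------------------

_PSL_NCOL = 21


def _psl_identity(fields: list[str]) -> float:
    # Standard BLAT "milliBad" percent identity for untranslated alignments.
    import math

    matches, mismatches, repmatches = int(fields[0]), int(fields[1]), int(fields[2])
    q_num_insert = int(fields[4])
    q_start, q_end = int(fields[11]), int(fields[12])
    t_start, t_end = int(fields[15]), int(fields[16])
    total = matches + repmatches + mismatches
    if total == 0:
        return 0.0
    q_ali = q_end - q_start
    t_ali = t_end - t_start
    size_dif = max(q_ali - t_ali, 0)
    milli_bad = (
        1000 * (mismatches + q_num_insert + round(3 * math.log(1 + size_dif)))
    ) / total
    return 100.0 - milli_bad * 0.1


def read_psl(path: str | Path) -> list[SimilarityMatch]:
    """Read a PSL alignment file (with or without its 5-line header).

    Percent identity follows the standard BLAT milli-identity convention;
    query coverage is (qEnd - qStart) / qSize * 100.
    """
    path = Path(path)
    matches: list[SimilarityMatch] = []
    with open(path) as fh:
        lines = fh.readlines()
    start = 0
    if lines and lines[0].startswith("psLayout"):
        # canonical header: psLayout line, version line, column names x2, dashes
        for i, line in enumerate(lines[:6]):
            if line.startswith("----"):
                start = i + 1
                break
        else:
            raise FormatError(f"{path}: psLayout header without '----' separator")
    for lineno, line in enumerate(lines[start:], start + 1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != _PSL_NCOL:
            raise FormatError(
                f"{path}: line {lineno}: expected {_PSL_NCOL} PSL columns, got {len(fields)}"
            )
        q_size = int(fields[10])
        q_start, q_end = int(fields[11]), int(fields[12])
        coverage = 100.0 * (q_end - q_start) / q_size if q_size else 0.0
        matches.append(
            SimilarityMatch(
                query_id=fields[9],
                target_id=fields[13],
                identity_pct=_psl_identity(fields),
                query_coverage_pct=min(coverage, 100.0),
                match_bases=int(fields[0]) + int(fields[2]),
                strand=fields[8][0],
            )
        )
    return matches


# ---------------------------------------------------------------------------
# BED / GFF3 intervals
# ---------------------------------------------------------------------------

def _default_category(label: str) -> Category:
    try:
        return Category(label.lower())
    except ValueError:
        return Category.OTHER


def read_intervals(
    path: str | Path,
    dialect: str,
    category_from: Callable[[str], Category] | dict[str, Category] | None = None,
) -> list[Interval]:
    """Read annotation intervals from BED or GFF3.

    BED coordinates are taken verbatim (0-based half-open); GFF3 start is
    shifted by -1 to the internal convention.  The category comes from the BED
    name column / GFF3 type column through ``category_from`` (a mapping or
    callable); labels it does not resolve become ``Category.OTHER``.
    """
    path = Path(path)
    dialect = dialect.upper()
    if dialect not in {"BED", "GFF3"}:
        raise ValueError(f"unknown dialect {dialect!r}; use 'BED' or 'GFF3'")
    if category_from is None:
        mapper: Callable[[str], Category] = _default_category
    elif isinstance(category_from, dict):
        table = category_from
        mapper = lambda label: table.get(label, Category.OTHER)  # noqa: E731
    else:
        mapper = category_from

    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if dialect == "BED":
                    seq_id, start, end = fields[0], int(fields[1]), int(fields[2])
                    label = fields[3] if len(fields) > 3 else ""
                    strand = fields[5] if len(fields) > 5 else "."
                else:  # GFF3: 1-based closed -> 0-based half-open
                    seq_id = fields[0]
                    label = fields[2]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6] if len(fields) > 6 else "."
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if start >= end:
                raise FormatError(
                    f"{path}: line {lineno}: empty interval {seq_id}:{start}-{end}"
                )
            intervals.append(
                Interval(
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    category=mapper(label),
                    strand=strand if strand in "+-." else ".",
                )
            )
    return intervals


def write_gff3(
    features: Sequence[tuple[str, str, int, int, str, dict[str, str]]],
    path: str | Path,
    source: str = "hapqc",
) -> None:
    """Write (seq_id, type, start, end, strand, attributes) features as GFF3.

    Coordinates are internal (0-based half-open) and converted on output.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seq_id, ftype, start, end, strand, attrs in features:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{seq_id}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_str}\n"
            )


# ---------------------------------------------------------------------------
# depth TSV
# ---------------------------------------------------------------------------

def read_depth_table(path: str | Path) -> "pandas.DataFrame":
    """Read a TSV with a header row into a DataFrame (scaffold depth columns)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: depth table needs at least two columns")
    return df


def write_depth_table(depths: dict[str, float], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"scaffold": list(depths), "mean_depth": list(depths.values())}
    ).to_csv(path, sep="\t", index=False)
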