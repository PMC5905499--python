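"""Haplotype-redundancy removal for heterozygous diploid assemblies.

A scaffold is considered a redundant haplotig when (i) after all-vs-all
similarity filtering at minId 92% / minCover 80% it matches exactly one other
scaffold, and (ii) its mean read depth falls in the haploid component of the
fitted depth mixture.  Within each such pair only the largest member is kept.

Similarity can come from an external PSL alignment file (the fidelity path) or
from an internal canonical k-mer containment estimator (the zero-dependency
path): containment c of a's k-mers in b inverts to an identity estimate
100 * c^(1/k) through the k-mer survival model, and coverage is the fraction
of a's positions inside merged shared-k-mer seed runs.  The estimator's
identity floor (~92% at k=15 containment ~0.3) mirrors the method's own
sensitivity limit: beyond ~8% divergence haplotig pairs are invisible to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .depth_model import DepthMixtureModel, classify_scaffold, fit_poisson_mixture
from .io_formats import Scaffold, SimilarityMatch

__all__ = [
    "PurgeConfig",
    "PurgeReport",
    "estimate_similarity",
    "all_vs_all",
    "filter_best_matches",
    "identify_redundant",
    "purge",
    "run_purge_pipeline",
]

# containment below this is indistinguishable from random k-mer collisions
_CONTAINMENT_FLOOR = 0.01


@dataclass(frozen=True)
class PurgeConfig:
    """Thresholds for the haplotig purge (defaults minId 92 / minCover 80)."""

    min_identity_pct: float = 92.0
    min_coverage_pct: float = 80.0
    depth_rule: str = "posterior"
    posterior_band: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct must be in (0, 100]")
        if not (0 < self.min_coverage_pct <= 100):
            raise ValueError("min_coverage_pct must be in (0, 100]")


@dataclass
class PurgeReport:
    """Audit record of a purge run."""

    removed: list[tuple[str, str, float, float, str]] = field(default_factory=list)
    retained_ids: list[str] = field(default_factory=list)
    n_input: int = 0
    n_output: int = 0

    @property
    def removed_ids(self) -> set[str]:
        return {r[0] for r in self.removed}


# ---------------------------------------------------------------------------
# internal similarity estimator
# ---------------------------------------------------------------------------

def _kmer_set_and_positions(seq: str, k: int) -> tuple[set[int], np.ndarray]:
    from .kmer_spectrum import _CODE, _chunk_kmers, _revcomp_codes

    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = codes.size
    if n < k:
        raise ValueError(f"sequence shorter than k={k}")
    valid = codes >= 0
    bad = np.cumsum(~valid)
    window_ok = (bad[k - 1 :] - np.concatenate(([0], bad[: n - k]))) == 0
    safe = np.where(valid, codes, 0).astype(np.uint64)
    fwd = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | safe[j : j + n - k + 1]
    canon = np.minimum(fwd, _revcomp_codes(fwd, k))
    canon = np.where(window_ok, canon, np.uint64(0xFFFFFFFFFFFFFFFF))
    return set(canon[window_ok].tolist()), canon


def estimate_similarity(
    a: Scaffold, b: Scaffold, k: int = 15, max_merge_gap: int | None = None
) -> tuple[float, float]:
    """Alignment-free (identity_pct, query_coverage_pct) of scaffold ``a`` vs ``b``.

    Containment c = |kmers(a) & kmers(b)| / |kmers(a)| inverts to identity via
    the survival model (1 - d)^k = c.  Coverage merges shared-k-mer seed runs,
    bridging gaps up to ``max_merge_gap`` (default 3k, so isolated mismatches
    inside an aligned block stay covered, as they would in a true alignment).
    Containment below the random-collision floor returns identity 0.
    """
    if len(a) < 200 or len(b) < 200:
        raise ValueError("sequences must be >= 200 bp for similarity estimation")
    if max_merge_gap is None:
        max_merge_gap = 3 * k
    set_a, canon_a = _kmer_set_and_positions(a.seq, k)
    set_b, _ = _kmer_set_and_positions(b.seq, k)
    if not set_a:
        return 0.0, 0.0
    shared = set_a & set_b
    containment = len(shared) / len(set_a)
    if containment < _CONTAINMENT_FLOOR:
        return 0.0, 0.0
    identity = 100.0 * containment ** (1.0 / k)

    sentinel = np.uint64(0xFFFFFFFFFFFFFFFF)
    shared_arr = np.fromiter(shared, dtype=np.uint64, count=len(shared))
    hit = np.isin(canon_a, shared_arr) & (canon_a != sentinel)
    starts = np.flatnonzero(hit)
    covered = 0
    if starts.size:
        run_start = int(starts[0])
        run_end = run_start + k
        for s in starts[1:].tolist():
            if s <= run_end + max_merge_gap:
                run_end = max(run_end, s + k)
            else:
                covered += run_end - run_start
                run_start, run_end = s, s + k
        covered += run_end - run_start
    coverage = 100.0 * covered / len(a)
    return min(identity, 100.0), min(coverage, 100.0)


def all_vs_all(
    scaffolds: list[Scaffold], k: int = 15, prefilter_identity: float = 50.0
) -> list[SimilarityMatch]:
    """Internal all-vs-all similarity: one match per ordered pair above the floor.

    k-mer sets are built once per scaffold; the expensive coverage run-merge is
    only computed for pairs whose containment-based identity clears
    ``prefilter_identity``.
    """
    sets: list[set[int]] = []
    canons: list[np.ndarray] = []
    for s in scaffolds:
        kset, canon = _kmer_set_and_positions(s.seq, k)
        sets.append(kset)
        canons.append(canon)
    matches: list[SimilarityMatch] = []
    for i, a in enumerate(scaffolds):
        if not sets[i]:
            continue
        for j, b in enumerate(scaffolds):
            if i == j:
                continue
            shared = sets[i] & sets[j]
            containment = len(shared) / len(sets[i])
            if containment < _CONTAINMENT_FLOOR:
                continue
            if 100.0 * containment ** (1.0 / k) < prefilter_identity:
                continue
            identity, coverage = estimate_similarity(a, b, k=k)
            if identity <= 0.0:
                continue
            matches.append(
                SimilarityMatch(
                    query_id=a.id,
                    target_id=b.id,
                    identity_pct=identity,
                    query_coverage_pct=coverage,
                    match_bases=int(round(coverage / 100.0 * len(a))),
                )
            )
    return matches


# ---------------------------------------------------------------------------
# filtering and the redundancy rule
# ---------------------------------------------------------------------------

def filter_best_matches(
    matches: list[SimilarityMatch], config: PurgeConfig | None = None
) -> list[SimilarityMatch]:
    """Drop self-hits and sub-threshold matches; keep each query's best matches.

    Thresholds are inclusive (identity 92.0 and coverage 80.0 pass).  For each
    query, all matches tied (within 1e-9) for the maximal match_bases are kept,
    mirroring filterPSL's best-matches-per-query behavior.
    """
    config = config or PurgeConfig()
    passing = [
        m
        for m in matches
        if not m.is_self_hit
        and m.identity_pct >= config.min_identity_pct
        and m.query_coverage_pct >= config.min_coverage_pct
    ]
    best: dict[str, float] = {}
    for m in passing:
        if m.query_id not in best or m.match_bases > best[m.query_id]:
            best[m.query_id] = m.match_bases
    return [m for m in passing if abs(m.match_bases - best[m.query_id]) <= 1e-9]


def identify_redundant(
    filtered: list[SimilarityMatch], depth_classes: dict[str, str]
) -> list[tuple[str, str]]:
    """Candidate haplotig pairs under the "exactly one partner" rule.

    A scaffold S is a redundancy candidate iff its filtered matches hit exactly
    one distinct partner P (partner-level counting, robust to split alignment
    records) and S's depth class is 'haploid'.  Each unordered pair is emitted
    once.
    """
    partners: dict[str, set[str]] = {}
    for m in filtered:
        partners.setdefault(m.query_id, set()).add(m.target_id)
    pairs: set[tuple[str, str]] = set()
    for s, ps in partners.items():
        if len(ps) != 1:
            continue
        if s not in depth_classes:
            raise ValueError(f"no depth class for scaffold {s!r}")
        if depth_classes[s] != "haploid":
            continue
        p = next(iter(ps))
        pairs.add(tuple(sorted((s, p))))
    return sorted(pairs)


def purge(
    pairs: list[tuple[str, str]],
    scaffolds: list[Scaffold],
    similarity: dict[tuple[str, str], tuple[float, float]] | None = None,
    depth_classes: dict[str, str] | None = None,
) -> tuple[list[Scaffold], PurgeReport]:
    """Remove the shorter member of each candidate pair, keep-largest.

    Pairs are processed in decreasing kept-member length; a scaffold that has
    already been removed cannot cause further removals (its remaining pairs
    are skipped), so alignment chains A-B, B-C yield exactly one removal per
    surviving pair.  Equal lengths break by removing the lexicographically
    larger id.
    """
    by_id = {s.id: s for s in scaffolds}
    for a, b in pairs:
        for sid in (a, b):
            if sid not in by_id:
                raise ValueError(f"pair references unknown scaffold {sid!r}")

    def split(pair: tuple[str, str]) -> tuple[str, str]:
        a, b = pair
        la, lb = len(by_id[a]), len(by_id[b])
        if la != lb:
            return (a, b) if la > lb else (b, a)
        return (a, b) if a < b else (b, a)  # tie: remove the lexicographically larger

    ordered = sorted(pairs, key=lambda p: -len(by_id[split(p)[0]]))
    removed: set[str] = set()
    report = PurgeReport(n_input=len(scaffolds))
    for pair in ordered:
        keep, drop = split(pair)
        if keep in removed or drop in removed:
            continue
        removed.add(drop)
        ident, cov = (similarity or {}).get(
            tuple(sorted(pair)), (float("nan"), float("nan"))
        )
        dclass = (depth_classes or {}).get(drop, "haploid")
        report.removed.append((drop, keep, ident, cov, dclass))
    retained = [s for s in scaffolds if s.id not in removed]
    report.retained_ids = [s.id for s in retained]
    report.n_output = len(retained)
    return retained, report


def run_purge_pipeline(
    scaffolds: list[Scaffold],
    depth_table: dict[str, float],
    config: PurgeConfig | None = None,
    psl_matches: list[SimilarityMatch] | None = None,
    model: DepthMixtureModel | None = None,
    seed: int = 0,
) -> tuple[list[Scaffold], PurgeReport]:
    """All-vs-all similarity -> best-match filter -> depth classes -> purge.

    If ``psl_matches`` is given (parsed from an external aligner's PSL output)
    it replaces the internal estimator.  If no match survives filtering the
    assembly is returned unchanged without fitting a depth model (nothing to
    classify, and a unimodal homozygous assembly would make the mixture
    degenerate).
    """
    config = config or PurgeConfig()
    matches = psl_matches if psl_matches is not None else all_vs_all(scaffolds)
    filtered = filter_best_matches(matches, config)
    report_empty = PurgeReport(
        n_input=len(scaffolds),
        n_output=len(scaffolds),
        retained_ids=[s.id for s in scaffolds],
    )
    if not filtered:
        return list(scaffolds), report_empty

    if model is None:
        model = fit_poisson_mixture(list(depth_table.values()), seed=seed)
    depth_classes = {
        sid: classify_scaffold(
            d, model, rule=config.depth_rule, posterior_band=config.posterior_band
        )
        for sid, d in depth_table.items()
    }
    pairs = identify_redundant(filtered, depth_classes)
    similarity = {
        tuple(sorted((m.query_id, m.target_id))): (m.identity_pct, m.query_coverage_pct)
        for m in filtered
    }
    return purge(pairs, scaffolds, similarity=similarity, depth_classes=depth_classes)
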