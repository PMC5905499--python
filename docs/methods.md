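# Methods

## Scope and coordinate conventions

`hapqc` analyzes an existing assembly; it does not assemble, map reads, or
discover repeats. Depth enters as a per-scaffold TSV (producing it from BAM is
the caller's concern), similarity either from an external PSL file or from the
internal estimator, and annotations as BED/GFF3. All internal coordinates are
0-based half-open; GFF3's 1-based closed convention is converted only at file
boundaries. Soft-masking (lowercase) is discarded on read, and IUPAC ambiguity
codes other than N are mapped to N with a warning: downstream logic only
distinguishes N (gaps) from called bases.

## K-mer spectrum model

Counting uses canonical k-mers (lexicographic minimum of a k-mer and its
reverse complement; with A<C<G<T this equals 2-bit numeric order). k must be
odd — an even k admits reverse-complement palindromes that would be counted
once where all other k-mers collapse two strands into one — and ≤ 31 so a
k-mer packs into a 64-bit word. The default k = 25 matches common short-read
practice; k = 21 works identically. Implementation: reads are concatenated
with `N` separators, 2-bit encoded, and k-mer values built by a rolling shift;
windows containing N are masked via a cumulative invalid-base count; canonical
form uses a bitwise reverse-complement; per-chunk `np.unique` results are
merged into global counts. This keeps ~10⁸ k-mers under a minute without a
disk-based counter.

Peak detection smooths the dense histogram with a 3-bin moving average (raw
Poisson noise creates spurious extrema at moderate coverage), then:

- **error cutoff** — the first local minimum when the histogram starts
  descending (an error peak at multiplicity 1); the lowest multiplicity
  otherwise (error-free input has no error peak).
- **het/hom pair** — among local maxima above the cutoff (ignoring maxima
  below 0.5% of the global maximum), the pair with position ratio in
  [1.6, 2.4] maximizing combined watershed area. Areas are Σ m·counts[m]
  between flanking minima. Areas, not raw heights, feed the heterozygosity
  estimator: heights are bin-width-sensitive, areas are not.
- **orientation** — if the *lower* peak of the pair carries more area, the
  spectrum is read as a unique-coverage peak with a 2-copy repeat shoulder
  and reported as unimodal (hom = lower peak). In the heterozygosity regime
  this model targets (r ≲ 2.5% at k = 25, where ρ = (1−q)/q < 1) the het peak
  is always the smaller; a dominant lower peak therefore signals repeats, not
  heterozygosity.

Estimators, with c = het depth, 2c = hom depth, T = non-error observations:
G = T / hom_depth (het loci contribute 2 k-mers at depth c, hence hom_depth
observations per locus, same as hom loci — unbiased under the two-peak model);
r = 1 − (1/(1+ρ))^(1/k); repeat fraction = share of T at multiplicity
> 1.5 · hom_depth. This is deliberately a two-peak model, not a four-peak
negative-binomial fit: the toolkit profiles diploid spectra where exactly two
peaks dominate, and the simplification is tested against simulation truth
rather than against any specific profiling tool's internals.

## Depth mixture

Per-scaffold mean depths are continuous, so the Poisson log-pmf is evaluated
continuously via log Γ (x log λ − λ − lgamma(x+1)) instead of rounding depths
to integers. EM initializes λ at the 25th/75th percentiles (deterministic — no
random restarts, so fits are reproducible functions of the data), runs to
|Δ log L| < 1e−6 or 500 iterations, asserts monotone log-likelihood each step,
and orders components λ_hap < λ_dip. λ_dip is *not* constrained to 2·λ_hap:
empirical haploid/diploid depth pairs (e.g., 34/67) violate the exact 2:1
ratio because mapping and GC effects differ between collapsed and separated
regions.

Classification offers two rules because the field uses both readings:
`posterior` (default) assigns the component with posterior > 0.5, returning
`ambiguous` within ±0.05 of the crossover so knife-edge scaffolds are never
purged; `central_interval` calls haploid iff the depth falls in the central
99% interval of Poisson(λ_hap). On unimodal data a forced two-component fit
degenerates (near-equal λs or a vanishing weight) — this is documented
behavior, and the purge pipeline avoids fitting entirely when no similarity
candidates exist.

## Haplotig purge

The redundancy rule: a scaffold is a candidate iff (i) after best-match
filtering its matches hit **exactly one distinct partner** and (ii) its depth
class is haploid. Partner-level counting (not alignment-record counting) is
used because aligners emit split records; requiring haploid depth of the
candidate only (not the partner) follows the natural reading of the rule —
the kept partner may legitimately be a collapsed, diploid-depth scaffold.
Filtering drops self-hits, applies inclusive thresholds (identity ≥ 92,
coverage ≥ 80 by default), and keeps all matches tied for maximal match-bases
per query. Resolution removes the shorter member of each pair (tie: the
lexicographically larger id), processing pairs in decreasing kept-member
length, and a scaffold already removed cannot trigger further removals — so
chains A–B, B–C yield one removal per surviving pair and the operation is
idempotent. Removal is whole-scaffold; no sub-scaffold trimming.

The internal similarity estimator is alignment-free: containment
c = |kmers(a) ∩ kmers(b)| / |kmers(a)| at k = 15 inverts to identity
100·c^(1/k) via the survival model (1−d)^k = c; coverage is the fraction of
the query inside merged shared-k-mer seed runs, bridging gaps up to 3k so
isolated mismatches inside an aligned block stay covered (as they would in a
real alignment). Containment below 1% is indistinguishable from random
collisions and returns identity 0. The estimator's sensitivity floor is
intrinsic and matches the method's: at divergence d, identity ≈ 100(1−d), so
pairs beyond ~8% divergence fall below the 92% threshold and are invisible —
recall collapses there by design, and the test suite asserts this. When a PSL
file is supplied it replaces the estimator (the fidelity path); both paths
agree on synthetic haplotig pairs within ~2 identity points.

## Assembly metrics

Contigs come from cutting scaffolds at runs of ≥ `min_run` Ns (runs shorter
than the threshold stay inside contigs); contigs+gaps reassemble the scaffold
exactly. Nx uses the inclusive first-reaches-≥x% cumulative convention; NGx
substitutes the genome size as denominator and is still reported when the
assembly exceeds it. Percentage denominators are explicit because reporting
conventions mix them: gap percentages use the gapped assembly size,
genome-relative size-class percentages use the externally estimated genome
size — both are parameters, never silently chosen.

Contig termini (first/last base of each contig, in scaffold coordinates) get
ONE category by precedence zero_coverage > interspersed_repeat >
tandem_repeat > gene > none. The precedence is a design choice: zero coverage
is read evidence, annotation intervals are predictions, and single assignment
keeps percentages summing to 100.

## Gene-model triage

The selection sentence in annotation pipelines is ambiguous in operator
precedence; it is resolved as (Cscore ≥ 0.5 AND peptide coverage ≥ 0.5) OR
(transcript coverage AND repeat overlap < 20%), with repeat overlap > 20%
forcing a strict override (Cscore ≥ 0.9 AND coverage ≥ 70%). At exactly 20%
only the homology branch can select — the strict branch requires "greater
than" and the transcript branch "less than". Reason strings expose the branch
that fired. Confidence is `high` iff EST CDS coverage is 100%, or ≥ 80%, or
Cscore ≥ 0.5. Minimal-intron bounds are mean ± n_sd·σ (default 89 ± 3·12 →
53–125 bp, clamped below at 1 bp with a warning); the gene-level percentage
uses intron-containing genes as its denominator (an intronless gene can't
contain a minimal intron). Gene length for summaries is the transcription
span including introns. Cscore itself is an input: computing it needs
peptide-vs-proteome alignment, out of scope.

## Synthetic data generator

What it emulates: a diploid genome with i.i.d. uniform composition and i.i.d.
heterozygous substitutions at a given per-base rate (default 1.65%); an
assembly produced by tiling the genome into fixed segments (default 10 kb)
where a segment's local het density above a threshold emits two haplotype
scaffolds at Poisson(λ/2) depth and below it one hapA-copy consensus at
Poisson(λ) — segment-level divergence decisions mirror scaffold-level
haplotype splitting without modeling assembler internals; error-free
forward-strand reads at equal coverage per haplotype (an optional uniform
substitution rate exercises the error peak at multiplicity 1); and gene
structures with geometric intron counts (mean 3.87), log-normal exon lengths
(mean 285 bp), and intron lengths from a Gaussian peak (89 ± 12 bp, weight
0.35) plus a log-normal tail (meanlog log 600, sdlog 0.7, so < 1.5% of tail
mass leaks into the minimal window and the minimal-intron fraction tracks the
peak weight).

What it does not emulate — hence what passing tests do not show about real
data: sequencing errors and quality scores (unless enabled), indel
heterozygosity, repeat families and segmental duplications (beyond explicit
constructions in tests), GC bias in coverage, joint structure between
scaffold length and depth class (lengths are fixed by segmentation,
independent of class), and assembler-specific artifacts such as IUPAC codes
at branch points. Estimator-recovery results on this generator validate the
estimators under their own model assumptions; real assemblies add the above
confounders.

Defaults are the study conditions: heterozygosity 1.65%, haploid/diploid
depths ~34/67 (λ_hom 67), k = 25, minId 92 / minCover 80, minimal-intron peak
89 ± 12 bp at 3 SD. The acceptance script uses a 2-Mbp genome at 60× (≈ 10⁸
25-mers) and 2000 mixture draws — sizes chosen so every peak and component is
estimated with comfortable statistical margin while a full run stays in the
minutes range on one CPU.

## Numerical choices and degenerate inputs

- EM tolerance 1e−6 on the log-likelihood, cap 500 iterations; identical
  depths or n < 50 are errors, not silent fits.
- Peak smoothing window 3 bins; maxima below 0.5% of the global maximum
  ignored; spectrum padded with zeros so a terminal peak is detectable.
- Threshold comparisons in filtering are inclusive; match-bases ties compare
  within 1e−9.
- Zero-intron inputs yield `None` statistics, not 0; scaffolds missing from a
  depth table are reported missing, not zero-depth.
- All simulators take explicit seeds (numpy `default_rng`); no global random
  state anywhere.

## Known limitations

The k-mer counter is in-memory (fine to ~10⁹ k-mer observations with a few
GB; not a disk-based counter). The internal similarity estimator has no
alignment extension, so its coverage is approximate near divergence hotspots;
supply PSL alignments when exact alignment semantics matter. The two-peak
spectrum model cannot separate a het peak from a repeat shoulder when both
sit at half/double positions with comparable area, and heterozygosity above
~2.5% (at k = 25) makes the het peak dominate, which the orientation rule
would misread as a repeat pattern — outside the regime this toolkit targets.
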