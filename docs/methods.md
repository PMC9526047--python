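# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `haploqc`, in the order the pipeline runs them.

## k-mer counting

k-mers are packed two bits per base into a 64-bit word, which caps k at 31;
the default k = 21 follows the common convention for genome profiling from
k-mer spectra. The canonical form of a k-mer is the lexicographic minimum of
the k-mer and its reverse complement under A < C < G < T, matching the
behaviour of mainstream k-mer counters, so counting a sequence and counting
its reverse complement give identical tables. Windows containing any symbol
outside {A, C, G, T} (case-insensitive) are skipped entirely — ambiguity
codes are not expanded. Counting is in-memory (sorted code arrays via
`numpy.unique`); it is sized for desk-scale validation work (up to roughly
10^8 k-mer instances), not for production counting of full sequencing runs,
where a disk-based counter would be the right tool.

## Spectra-cn partition

Each distinct read k-mer with read multiplicity x is assigned to copy class
c = min(assembly multiplicity, Cmax); class 0 holds read k-mers absent from
the assembly and the last class (default Cmax = 4, "4+") is open-ended.
Column sums over classes reproduce the read histogram exactly — this
conservation is asserted in tests and is the invariant that makes the
downstream intersection meaningful. Assembly k-mers with no read support are
tallied separately ("assembly-exclusive"), by assembly multiplicity; they
play no role in the intersection but are a useful QC signal for consensus
errors.

## Histogram mixture model

The distinct-k-mer histogram is modelled with three components:

* error: `W·x^(−a)`, a power law with W ≥ 0 and a > 1. Error k-mers arise
  from read errors and are dominated by multiplicity 1–3; a power law is a
  deliberately simple shape that tracks that decay without trying to model
  the error process mechanistically.
* heterozygous: `2hG·NB(x; μ = λ, size = σ_het)` — each heterozygous k-mer
  locus contributes two haplotype-specific k-mers sampled at the haploid
  coverage λ.
* homozygous: `(1−h)G·NB(x; μ = 2λ, size = σ_hom)` — shared k-mers are
  sampled from both haplotypes, at 2λ.

Here G is the number of haploid k-mer loci and h = 1 − (1−r)^k the
probability that a k-mer locus overlaps at least one heterozygous site given
per-base heterozygosity r. The negative binomial is parameterised by mean
and size (variance μ + μ²/size) so the component means stay pinned at λ and
2λ while the dispersions are free. Repeat components (3λ, 4λ, …) are
intentionally omitted: the intersection stage uses only the error /
heterozygous / homozygous curves, and the simulator generates repeat-free
genomes; on repeat-rich real data the hom component will absorb some repeat
mass and the fit range cap (below) limits the damage.

### Fitting

Weighted least squares over x ∈ [1, ceil(8·λ₀)], minimising
`Σ w(x)·(hist[x] − total(x))²` with w(x) = 1/(hist[x]+1), bounded
(`scipy.optimize.least_squares`, trf). The weights stop the huge error bins
at x = 1–2 from dominating while keeping them informative. Initialisation:
the trough (first local minimum of the lightly smoothed histogram whose
subsequent rise is substantial — the guard rejects count-level noise in the
right tail) separates the error tail from genomic peaks; λ₀ candidates are
the post-trough histogram peak and half of it, covering both the case where
the homozygous peak dominates (peak ≈ 2λ) and where the heterozygous peak
does (peak ≈ λ). The best weighted residual wins, ties broken toward smaller
λ. r₀ = 0.005, G₀ = post-trough distinct-k-mer count, σ₀ = 15, a₀ = 3,
W₀ = hist[1]. The fit is deterministic given the histogram. Degenerate
histograms (empty, or a single nonzero bin) raise a model-degeneracy error;
optimiser non-convergence is flagged on the result rather than raised.

Heterozygosity is reported as 100·r percent. Haploid genome size is
`Σ_{x ≥ trough} x·hist[x] / (2λ)` — total genomic k-mer instances divided by
the diploid k-mer coverage; when no trough is detectable (error-free data)
the sum starts at the fit-range minimum and the fallback is recorded. The
fitted G is reported alongside for comparison.

Note that λ is the *k-mer* coverage: a read of length L contributes
L − k + 1 windows, so λ ≈ base_coverage · (L − k + 1)/L, further reduced by
the fraction of error-free windows ((1 − e)^k for substitution rate e). The
fit absorbs both effects; `simdata.kmer_coverage` exposes the first for
truth-aware tests.

## Intersection and the duplication proxy

For each component curve and each multiplicity x, the curve's expected count
is distributed across copy classes by a sequential minimum rule: the next
class in the stacking order receives `min(class_count(c, x), remaining)`,
with `remaining` starting at the component value and decreasing with every
allocation. This conserves model mass (a component can never allocate more
than its curve holds) and respects the data (a class can never receive more
than its histogram column).

The stacking order was the one genuinely open design choice. Three variants
are implemented:

* `stacked` (default): assembly-present classes in ascending copy number
  (1, 2, …, Cmax+), with class 0 taking the residual last.
* `stacked-zero-first`: strictly bottom-up plot order (0, 1, …, Cmax+).
* `independent`: plain per-class element-wise minimum (R's `pmin` applied to
  each class separately), with no remaining-mass bookkeeping.

The default was chosen on truth-aware simulations: with class 0 served
first (and likewise with independent minima), the homozygous component's
lower NB tail overlaps the heterozygous peak region, where the 0× column
holds the missing alternate alleles; that column then soaks up homozygous
model mass, and a primary-haplotype-only assembly that provably contains
every homozygous k-mer is reported as missing ~3% of homozygous content.
With the 0× class as the residual, the same assembly reports ~0 homozygous
missingness, matching ground truth. The trade-off is a modest downward bias
in the heterozygous 0× fraction (~0.43 observed where the idealised value is
0.5), because assembly-present classes can absorb heterozygous-curve mass in
the same overlap region. Both biases shrink as coverage separates the peaks.

The duplication proxy is `D/(S+D)` over the homozygous component, with S the
mass at copy class 1 and D the mass at classes ≥ 2 ("duplicated" deliberately
means two *or more* copies, since gene-level duplication counts do not
distinguish 2 from >2 either). It is undefined (flagged, not a sentinel)
when S + D = 0. The error component is allocated and reported for QC parity
but never enters the proxy. Missingness is reported as the class-0 mass of
the het and hom components, absolute and as a fraction of each component's
allocated total.

## Simulator

The generator emulates exactly the structure the model assumes, which is
both its purpose and its limitation:

* Haploid template: i.i.d. bases with a configurable GC fraction (default
  0.42, a typical insect-genome value).
* Diploidisation: SNP-only heterozygosity — each base mutates independently
  with probability r (default 0.011, the moderately-high regime the
  assessment targets), with optional HDR blocks carrying an elevated local
  rate. Heterozygous indels are deliberately excluded: the model components
  are defined on SNP-driven k-mer splitting, and the diploid stays colinear
  so truth records are exact.
* Reads: fixed-length (default 1 kb) fragments drawn uniformly from both
  haplotypes and strands until each haplotype reaches the requested mean
  coverage (default 25×), with per-base substitution (default 1%) and
  optional indel errors. Read ids encode haplotype, serial number, template
  interval and strand, so tests can trace every read to its origin. Real
  long-read length distributions, coverage biases and error burstiness are
  not emulated.
* Assembly: the primary haplotype split at uniform random breakpoints, plus
  redundant haplotigs — non-overlapping random blocks of the alternate
  haplotype totalling exactly `round(f·genome_length)` bases; `realized_f`
  is an exact length ratio, not a sampled estimate.
* Coding pairs: random stop-free CDSs with exactly the requested numbers of
  synonymous and nonsynonymous single-nucleotide changes at distinct codons,
  with per-change truth records. Codons that cannot host the requested
  change type (e.g. ATG has no synonymous single-nt neighbour) are resampled,
  and generation fails cleanly when no codon can.

All generators are pure functions of their inputs and a seed (one seed per
run, sub-seeds spawned deterministically). Because the simulator matches the
model's assumptions, passing recovery tests demonstrates internal
consistency of the pipeline — correctness of counting, fitting, intersection
and accounting — not robustness to repeat content, pooled multi-haplotype
samples, coverage bias or structural variation, none of which are simulated.

## Divergence statistics

Protein pairs are aligned with an exact global affine-gap aligner (Gotoh;
BLOSUM62, gap open 11, gap extend 1, a gap of length L costing
open + (L−1)·extend). Pairwise-exact alignment replaces a multiple-aligner
dependency because every comparison here involves exactly two sequences.
Traceback tie-breaking is deterministic: substitution preferred over a gap,
then gap-in-first-sequence over gap-in-second. Aligning against an empty
sequence yields a flagged all-gap alignment.

The alignment is threaded back onto the coding sequences codon-by-codon
(gap → `---`). Terminal stop codons are trimmed first; internal stops and
translation mismatches are hard errors naming the offending residue.

NG86: per codon, the synonymous site count is (synonymous single-nucleotide
neighbours)/3 summed over positions, averaged over the two codons; neighbours
that create stop codons count as nonsynonymous, so N + S = 3 per codon holds
exactly. Codon pairs containing gaps, ambiguity codes or stops are excluded
pairwise. Codons differing at 2–3 positions are scored by equal-weight
averaging over all orderings of the changes, excluding pathways that pass
through a stop; in the (rare) case that every pathway is blocked, all
pathways are used with stop transitions counted as nonsynonymous. pN = Nd/N
and pS = Sd/S receive the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3)
where defined; p ≥ 3/4 and dS = 0 are reported as explicit flags with the
raw counts intact, so either downstream convention (dropping such pairs, or
mapping them to 0/∞) can be derived — the package does not pick one.

The alignment-free comparison counts overlapping words of size 2 (all 16
dinucleotides; windows with ambiguity codes skipped) over the full genomic
span of each copy and reports the raw Canberra distance
`Σ |x−y|/(x+y)` (0/0 terms contribute nothing). The raw sum matches the
common alignment-free definition; an optional normalisation by the number of
nonzero-denominator terms is available for cross-length comparability.

Gene pairs can come from a BUSCO-style full table (status `Duplicated`,
exactly two copies; start/end taken verbatim and interpreted as 1-based
inclusive, the BUSCO convention, configurable) plus an assembly FASTA —
this path yields genomic spans for the alignment-free statistic — or from
paired FASTA records (`<gene>__copy1` / `<gene>__copy2`) carrying CDSs
and/or spans. Genes with more than two copies are counted and skipped;
multi-copy handling and maximum-likelihood codon models are out of scope.

## Problem sizes and reproducibility

The bundled validation work runs at desk scale: recovery tests and the
acceptance script use a 500 kb diploid at 25× per-haplotype coverage
(~25 Mbp of reads, ~5M distinct 21-mers), a redundancy grid sharing one read
set and fit across f ∈ {0, 0.25, 0.5, 1}, and 30 simulated gene pairs per
enrichment regime; these sizes give stable statistics (heterozygosity
recovered within a few percent relative, proxy within ~0.05 absolute across
seeds) while keeping a full run in tens of seconds. Every stochastic stage
takes an explicit seed; stage seeds are spawned from the one user seed via
`numpy.random.SeedSequence`, and repeated runs are byte-identical.

## Known limitations

* Strictly diploid: pooled samples with >2 haplotypes per locus are only
  approximated as elevated effective heterozygosity.
* Repeat-free model and simulator: repeat-rich genomes will push repeat mass
  into the hom component and the 4+ class; the proxy then conflates repeats
  with haplotigs, as any two-copy statistic must.
* The proxy is a relative QC measure between assemblies of the same read
  set; coverage stochasticity prevents per-locus claims.
* The power-law error term is phenomenological; heavily biased error
  processes may misallocate mass between the error and het components at
  very low coverage.
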