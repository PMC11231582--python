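# Methods

`retrobench` is a fully synthetic, end-to-end testable emulation of a
simulation study of quantification bias in endogenous-retrovirus (ERV)
expression analysis.  Every stage — family genome, reads, alignment,
quantification, bias metrics — is generated and measured inside the package,
so each claim the pipeline makes can be checked against a known ground
truth.

## The scientific problem

ERV families such as HML-2 (HERV-K) consist of tens of genomic integrations
descended from near-identical ancestors.  Young integrations have had little
time to accumulate substitutions and are therefore nearly identical repeats;
old integrations are individually recognizable.  Short sequencing reads from
young loci align equally well to several family members, and a
locus-specific expression estimate becomes an arbitrary redistribution of
those multi-mapping fragments.  The package quantifies how large that
redistribution bias is, per locus, as a function of read length, error
profile, integration age and quantification strategy — and how it vanishes
when counts are aggregated to the family level.

## Family genome model

A single ancestral "master" element of 10 kb is drawn i.i.d. at a configurable
GC content (default 0.41, a typical mammalian value).  Each locus evolves
from the master by i.i.d. per-site substitution with probability

    p(age) = 3/4 * (1 - exp(-4/3 * r * age)),

the Jukes–Cantor expected observable divergence after `age` million years
(MY) at substitution rate `r` (default 2.2e-3 substitutions/site/MY, roughly
the human neutral rate).  Substitution-only evolution keeps effective
lengths exactly at their nominal values (1000 nt solo-LTR, 10 000 nt
provirus), so the coverage-equalization arithmetic is exact; an indel-free
model is a deliberate simplification.

The default family is 30 simulated loci — ten per age stratum, with ages
drawn uniformly from

* young: U(1.9, 9.38) MY
* intermediate: U(10, 20) MY
* old: U(24.25, 53.79) MY

The strata sampling ranges are kept disjoint and consistent with the
age-group cutpoints used in reporting (young < 10, intermediate 10–20, old
> 20 MY), so a locus's stratum never disagrees with its age-group label.
Per stratum, 6 loci are solo-LTRs and 4 are proviruses (18/12 overall).
Solo-LTRs evolve from the master's first 1000 nt — the region a provirus
also carries — giving the LTR-like cross-class sequence sharing that makes
family-wide multi-mapping realistic without modelling LTR/internal
substructure explicitly.

One extra provirus locus is an exact copy of a randomly chosen simulated
young provirus, annotated (`simulated=False`) but never a read source.  It
emulates a post-integration segmental duplication: reads simulated from the
source locus match the twin with identical scores, which is the single
unavoidable, structurally forced failure mode of locus-specific counting.

All loci are placed non-overlapping on one i.i.d. background contig
(default 300 kb) with at least 1 kb flanks.  The background carries no genes
or unrelated repeats: reads are only ever generated from, and aligned to,
family loci.

## Read simulation

Six presets mirror common technology layouts: Illumina-like 76/150 nt
single- and paired-end (substitution-only, 0.2 %/base, flat along the
read), a CLR-like long-read profile (750 nt single-end, 12 % total error
split 2 % substitution / 6 % insertion / 4 % deletion) and a HiFi-like
profile (750 nt single-end, 0.2 % total error split 0.1 % / 0.05 % /
0.05 %).  Base qualities are constant (Phred 35, or 13 for the CLR-like
profile) and only serve FASTQ validity; nothing downstream is
quality-aware.

Read counts per locus equalize coverage (default 10×) over the effective
length: `floor(cov*L/len)` single-end reads or `2*floor(cov*L/(2*len))`
paired reads, identical across equal-geometry profiles.  Fragment starts
are uniform within the locus, strands uniform; paired-end fragment lengths
are Normal(300, 30) truncated to [2·read_length, locus length].  Reads are
contained entirely within locus boundaries (no junction reads).  Every read
name encodes its truth as `locus|start|strand|mate|serial`.

Errors are applied per template base with independent deletion,
substitution and insertion draws; deletions pull extra template so the read
length is preserved, and in the rare case the template runs out near a
locus end the tail is padded with uniform bases.  Simulation metadata
(error events, template consumed) is kept on each record so tests can
verify the realized error rate against its exact binomial expectation.

## Alignment

Reads are aligned only against the annotated locus set.  Candidates are
loci sharing at least one exact k-mer (k = 13) with the read on either
strand; each candidate is scored by a read-global, locus-ends-free dynamic
program (match +1, mismatch −1, gap −2, linear) inside a window around the
best-supported seed diagonal with band half-width `band_fraction ×
read_length` (default 0.25).  The inner DP is JIT-compiled with numba.
Identity is matches/aligned-columns from the traceback; hits under
`min_identity` are discarded, the rest sorted by score (ties by locus id)
and truncated to `max_hits` (default 100).

The strict/lenient contrast of short-read vs long-read aligners on
high-error reads is encoded purely as the identity threshold: 0.8 for
accurate profiles, 0.9 ("strict", an end-to-end short-read aligner that
rejects 12 %-error reads) and 0.6 ("lenient", a long-read-tolerant aligner)
for the CLR-like profile.  Since `max_hits` exceeds the locus count,
aligning once at the lenient threshold and re-filtering reproduces the
strict run exactly.

`brute_force_align` is an independent full-matrix, unseeded, unbanded
NumPy implementation with identical scoring and filtering; tests require
the seeded aligner to reproduce its best-locus sets on noisy toy families,
and a third implementation (Biopython's `PairwiseAligner` with free
target-end gaps) cross-checks the scoring scheme itself.

## Quantification

* **naive** — each fragment goes to its best-scoring locus; exact score
  ties are broken uniformly at random (seeded) or by first locus id.
* **em** — MAP-EM over a mixture of source loci.  Fragment–locus weights
  are `q(f,t) = exp((score(f,t) − best(f))/temperature)` (temperature 1.0
  in score units, i.e. one mismatch ≈ e^−2); mixing proportions start
  uniform; the E-step sets responsibilities ∝ π·q, the M-step applies the
  MAP update π ∝ Σr + α₀ with α₀ = theta_prior/n_loci (defaults max_iter
  200, theta_prior 200 000, the settings commonly used with Telescope-style
  reassignment tools;
  convergence at max|Δπ| < 1e−6).  Final integer counts hard-assign each
  fragment to its argmax-responsibility locus, exact ties to the smallest
  locus id.  The penalized log-posterior is tracked and is non-decreasing.
* **family** — the number of fragments with ≥1 accepted hit anywhere in
  the family; invariant to how any single-assignment method redistributes
  fragments.

Paired fragments score as the sum of the mates' best per-locus scores;
mates hitting disjoint loci make the fragment ambiguous across the union.

## Bias metrics and statistics

Per locus: percent error `|assigned − mapped|/assigned × 100`; fold change
`mapped/assigned` with falsely-up (> 1.1) / falsely-down (< 0.9) calls
(boundaries count as unchanged); rows for annotation-only loci (assigned =
0) are flagged rather than dropped and excluded from summaries, whose
denominator is always the number of simulated loci.  Family recovery is
`100 × family_total / fragments_simulated`.  Mann–Whitney U (exact
enumeration for tie-free samples of ≤8 each, tie-corrected normal
approximation otherwise) compares percent-error distributions between
methods, read lengths and age strata; Spearman's rho correlates percent
error with integration age.  No multiple-testing correction is applied
(single-comparison reporting at α = 0.05).

## What the synthetic data does and does not show

The generator reproduces the *structure* of a real family quantification
experiment — age-stratified divergence, an exact duplicate, equalized
coverage, technology-shaped error — but not real genomic sequence: no
LTR/internal substructure,
recombination, insertional polymorphism, host transcripts, positional
quality decay or junction reads.  Two consequences matter when reading
results:

1. The qualitative phenomena are reproduced: short reads from young loci
   multi-map and bias locus-specific counts; the duplicated locus loses
   ~half its reads to its twin under best-hit counting with random
   tie-breaks while EM consolidation assigns the tied reads to a single
   locus; high-error long reads collapse under strict alignment (every
   locus falsely down) but not under lenient alignment; family-level
   totals stay essentially unbiased whenever reads align at all.
2. One real-world advantage of EM reassignment does *not* transfer to
   this closed world: EM does not achieve a lower median per-locus bias
   than naive counting here.  In a genome-wide analysis the family
   annotation typically contains many loci that express nothing, and a
   naive best-hit baseline leaks multi-mapping reads to them — a leak that
   EM's learned mixing proportions win back.  With only one unsimulated
   annotation entry (the
   twin) and equalized coverage, multi-mapping tie cliques are symmetric,
   the truth-optimal split of a clique is uniform (which random
   tie-breaking achieves in expectation), and any winner-take-all
   consolidation must over-concentrate.  The corresponding acceptance test
   is left failing by design and the mechanism is asserted positively by
   the duplicate-rescue and false-upregulation tests.

## Numerical and design choices

* Coverage defaults to 10×, a depth at which per-locus counts are large
  enough for fold-change calls to be stable but every run stays fast;
  all simulations in tests and the acceptance script use
  the default 30-locus family at this coverage — desk-scale sizes chosen so
  the whole study runs on one CPU in minutes.
* Stage seeds derive from the master seed via SHA-256 of
  `master/stage/profile/locus`, so runs are reproducible byte-for-byte and
  adding a profile never perturbs another's reads.
* Alignment windows clamp at locus boundaries; candidate diagonals are the
  mode of seed diagonals per (locus, strand); per-locus hits keep the best
  strand.  DP tracebacks prefer diagonal over vertical over horizontal
  moves, making identities deterministic.
* Degenerate inputs are errors, not silent results: zero-length masters,
  non-positive coverage, loci shorter than a read, assigned-zero
  denominators and constant vectors in rank statistics all raise typed
  exceptions (flagged rows for the annotation-only twin).
* The noiseless-limit property is tested on an old-strata family because
  "unique loci" is a sequence property: error-free reads from two young
  loci can still be exactly identical, which is non-uniqueness of the
  loci, not noise.

## Limitations

Closed-world alignment (no background mapping, no off-family annotation)
makes naive counting more favorable than in a genome-wide setting; absolute
medians are therefore smaller than a full-genome study would show, and the
EM-vs-naive median ordering reverses (see above).  The aligner is
deliberately simple (single seed diagonal, linear gaps, no quality
weighting), adequate for contained reads but not a general-purpose mapper.
Statistics are reported as raw two-tailed p-values; with seven runs and
three strata a multiplicity-aware analysis would be stricter.
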