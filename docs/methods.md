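# Methods

## The problem and the approach

A shotgun metagenome is a mixture: each read comes from one (unknown) member
of a community. Full-scale annotation of hundreds of millions of reads is
expensive, so `metaskim` studies the *preview* strategy — select an extremely
small subset of reads, analyze only that, and treat the result as an estimate
of the full run's coarse taxonomic profile. Because the quality of such an
estimate can only be judged against known truth, the package couples the
preview machinery to a mock-community simulator in which every read's source
strain is known a priori.

The statistical backbone is elementary and deliberately so: if reads are
exchangeable, the number of sampled reads attributable to a taxon with true
share *p* is Binomial(*n*, *p*), so a sample's taxon share estimates the
pool's with standard error √(p(1−p)/n), independent of how large the pool
is. Everything the package measures — ratio dispersion across selection
methods, GC deviation, top-taxon recovery — is an empirical check of how far
real selection schemes (which are not all uniform-random) deviate from that
idealization.

## The mock community

The default community has 10 bacterial strains. Its proportions are the
per-strain BLAST hit ratios of a published HiSeq benchmark run of the same
10-strain mixture, taken as exact hit-count fractions (the printed
four-decimal ratios sum to 1.0001 and are not used; the counts sum exactly).
Per-strain GC targets are the published genomic GC of each organism
(E. coli ≈ 0.506/0.509 down to S. epidermidis 0.321 and up to
A. chlorophenolicus 0.659); their abundance-weighted mean is ≈ 0.539, so a
simulated pool lands near 54% GC, close to the benchmark run's 53.1% —
by construction of the targets, not by fitting to data.

Simulator design choices:

- **Genomes are i.i.d. base strings**, default 100 kb per strain, with
  P(G)=P(C)=gc/2. No repeats, no shared sequence between strains. This is
  sufficient because every downstream statistic depends only on the
  read→strain assignment and base composition, not genome structure. It is
  also the main idealization: real genomes share homologous regions, so a
  real BLAST search produces cross-hits between related strains (the two
  E. coli strains especially) that the synthetic community does not exhibit.
  Passing tests therefore validate the sampling statistics, not classifier
  robustness to homology.
- **Reads are error-free, single-end, fixed 101 b** (the read length implied
  by the benchmark's "100 reads = 10,100 b" arithmetic). An optional uniform
  substitution rate (default 0) exists to stress the k-mer classifier; no
  attempt is made to emulate Illumina error profiles, adapters or quality
  distributions.
- **Truth labels ride in the read id** as a `|strain=<percent-encoded name>`
  suffix token, so samples written to standard FASTQ remain classifiable
  after round-tripping through any tool that preserves ids.
- **Determinism**: one seed fixes genome generation (per-strain child
  streams) and read generation; identical arguments give byte-identical
  output.

The taxon-count fixture generator (`generate_taxon_table`) emulates the
*shape* of an annotation service's output — one dominant taxon plus a
Dirichlet/Zipf long tail — with exact count conservation and a strict
dominant maximum. It makes no claim to model any real community's abundance
distribution.

## Selection semantics

Positions are 0-based, intervals half-open, and K is the number of records
skipped, so K=0 "from the start" is the head of the file.

- *from the start*: positions [K, K+n); single pass, stops early.
- *from the end*: positions [N−K−n, N−K); buffers only the trailing K+n
  records when N is unknown.
- *uniform*: stride = ⌊(N−K)/n⌋ anchored at K; the remainder is absorbed at
  the tail (the last selected position may fall short of N−1). A
  floor-stride was chosen over random-uniform positions because it is
  deterministic and matches "uniformly distributed positions" without
  interpolation.
- *random*: uniform without replacement via single-pass reservoir sampling
  with geometric skips (Algorithm L), output restored to stream order so all
  four families yield order-preserved samples.

Requesting more reads than the stream holds is a hard error, never a short
return: a silently truncated sample would corrupt any size-versus-error
analysis.

The benchmark design's four K values and four random seeds are not published;
the defaults K ∈ {0, 1000, 2000, 3000} and seeds {1, 2, 3, 4} were chosen
once, and the dispersion results are insensitive to the specific values
(any fixed offsets into an exchangeable pool are statistically equivalent).
Likewise the 11 sizes are fixed as {100, 200, 500, 1000, 2000, 5000, 10000,
15000, 20000, 30000, 50000} — roughly log-spaced across the stated 100 to
50,000 range.

## Hit counting

Hits are binary per read per strain: each read contributes at most 1 to each
strain it matches. (A real BLAST run can report several HSPs per read —
the benchmark's hit sum exceeds its read count by two orders of magnitude —
but multiplicity is an alignment artifact; the ratio n_i/s is the object of
study and is cleaner under the binary rule.) Multi-strain hits count once
per strain; ratios are computed only when s > 0 (an all-zero table carries a
sentinel rather than raising mid-pipeline); genome size is deliberately not
corrected for.

The k-mer classifier indexes each reference genome's canonical
(strand-minimum) 21-mers and calls a hit at ≥ 2 shared k-mers. k = 21 makes
chance collisions negligible (a random 101 b read shares a given 21-mer with
1 Mb of random genome with probability ≈ 2·81·10⁶·4⁻²¹ ≈ 4·10⁻⁵) while
2 shared 21-mers on an error-free 101 b read is a lenient, BLAST-like
sensitivity threshold.

## Sample-size planning and coverage

`required_sample_size` implements n = ⌈z²·p(1−p)/E²⌉ with worst-case p = ½.
By default z is the two-decimal z-table value (85% → 1.44, giving n = 5184);
`z_convention="exact"` uses the full quantile (1.4395…, giving 5181).
Rounding n up (ceiling) keeps planned sizes conservative.

A caveat the package computes rather than asserts: coverage of the ±E
interval on the integer lattice oscillates with n. At n = 5184, E = 0.01,
p = ½, the interval spans counts 2541–2643 — an effective half-width of 51
counts against a binomial SD of 36, i.e. z_eff = 51.5/36 ≈ 1.431 — so the
exact coverage (`coverage_exact`, by summing the pmf) is 84.74%, slightly
*below* the nominal 85%, even though the continuous-level coverage of
z = 1.44 is 85.01%. At n = 5181 the lattice aligns favourably and exact
coverage is 85.15%. Monte-Carlo (`coverage_simulation`) agrees with the
exact pmf within sampling error; both compare |X − np| ≤ nE in count space
with a 10⁻⁹ guard so boundary outcomes are not lost to float rounding.
Because all mock-community shares are below ½, the p = ½ variance term
overstates their sampling error; p is exposed as a parameter and no further
correction is applied.

## Dispersion and comparison conventions

- The per-size scatter of ratios across the 16 method variants uses the
  population SD (divide by 16): the variants are the entire method set under
  study, not a sample from a method population.
- "Most annotated" ties break lexicographically (deterministic; real tables
  essentially never tie).
- The 1% diversity threshold reads "ignore taxa with *less than* 1% of
  hits" literally: a share of exactly 1% survives. Threshold 0 counts all
  taxa with nonzero counts. Rank totals are per rank; phylum and class
  lists are independent, and taxon names match by exact trimmed string
  equality (no taxonomy-database reconciliation).
- GC content excludes N and other ambiguity codes from both numerator and
  denominator, making the statistic invariant to the amount of masking.

## Problem sizes

The test suite and the bundled experiments run on a 60,000-read pool
(the smallest pool that accommodates the largest sample size, 50,000, plus
the largest skip, 3,000), 100 kb genomes, 200 random-subsample replicates
per size for convergence trends, 1,000 multinomial simulations for
top-taxon recovery, and 100,000 trials for the reservoir-uniformity
chi-square — sizes at which every binomial/multinomial oracle bound in the
tests has comfortable power. The benchmark run these statistics emulate was
~1.22 million reads; all claims checked here are scale-free (they depend on
sample size n, not pool size N, once N ≫ n).

## Known limitations

- No homology between synthetic genomes, hence no cross-hits; classifier
  behaviour on closely related strains is only exercised by explicitly
  constructed shared segments.
- The preview pipeline does not model annotation-service noise
  (over-/mis-annotation); the 1% threshold logic is implemented, but its
  effectiveness against real mis-annotation cannot be established
  synthetically.
- Single-end reads only; no quality filtering or trimming (none is applied
  before selection in the emulated design).
- The k-mer classifier is a containment test, not an aligner: it has no
  notion of alignment score, E-value, or partial homology.
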