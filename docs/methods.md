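# Methods

This note documents the statistical models, parameter choices and numerical
conventions behind `snpdemog`, and what its synthetic-data tests do and do
not demonstrate about real data.

## Genotype model and coding

Genotypes are diploid biallelic dosages: at each locus, 0/1/2 copies of a
panel-wide reference allele `a1`, with −1 for missing. One allele coding per
locus is fixed for the whole panel, never per population. This matters only
for *signed* statistics: the sign of the LD correlation r flips with the
coding of either locus, so cross-population comparisons of r (phase
persistence) are meaningful only under a shared coding. PLINK binary input
takes `a1` from the `.bim` allele-1 column; PLINK text input has no
allele-order metadata, so `a1` is the first allele seen in file order — a
deterministic rule under which written files round-trip byte-for-byte
(heterozygotes are written with sorted alleles) and a re-read panel is
stable after one cycle.

Coordinates are 1-based (as in `.map`/`.bim`); all internal bin and window
arithmetic is 0-based half-open, converted only at I/O boundaries.

## Quality control

- Missingness: loci with a missing fraction above 5% (default) over *all*
  samples are dropped once, before any per-population work; sex-chromosome
  and mitochondrial loci are dropped at read time.
- Per-population LD QC: minor-allele frequency < 0.05 and exact
  Hardy-Weinberg p < 0.001 (defaults) remove loci before LD estimation.
  The HWE test is the exact conditional test (sum of probabilities of all
  heterozygote counts, given the allele counts, no more probable than the
  observed one), computed with log-gamma arithmetic; a chi-square variant is
  available behind a flag. No mid-p correction.

## Linkage disequilibrium

Two-locus haplotype frequencies are estimated from unphased genotypes by EM
under random mating: only double heterozygotes are phase-ambiguous, and the
E-step splits them between cis and trans at their current expected odds.
The allele frequencies are the MLEs of the margins and stay fixed, leaving
one free parameter (f11). Convergence: largest frequency change < 1e-9, at
most 1000 iterations.

Initialisation needs care: the linkage-equilibrium point `f11 = p·q` is an
exact fixed point of the EM map whenever the counts are symmetric under an
allele swap at one locus (for example a locus where every individual is
heterozygous), and there it is a saddle, not a mode. The ascent therefore
starts from two deterministic points a quarter of the way from `p·q` toward
each boundary of the feasible interval, and the higher-likelihood solution
is kept. When the two modes tie exactly (allele-swap-symmetric data), the
smaller f11 is reported — an arbitrary but fixed convention, matching a
grid-search argmax from the low end. Pairs with a fixed margin among the
jointly called samples, or fewer than two such samples, are skipped and
counted rather than estimated.

From the converged frequencies, `D = f11 − p·q`,
`r = D/√(p(1−p)q(1−q))`, `r² = r²`. A composite (dosage-correlation)
estimator is available behind a flag for speed; at 25-50 samples it agrees
with the EM in aggregate (correlation > 0.95 across pairs) but differs
pair-by-pair. Pairs are formed within chromosomes at distances strictly
below 3 Mbp (default); per-chromosome summaries use the sample SD (n−1).

## Persistence of phase

For two populations, the signed r values of SNP pairs defined (post-QC
polymorphic) in *both* populations are grouped into 100-kbp distance bins
(up to 10 Mbp), and each bin's Pearson correlation between the two r
vectors is reported. Intersection semantics are the only coherent choice —
a correlation needs the same pairs on both sides. Bins with fewer than 3
shared pairs are reported as missing with their count. r rather than r² is
correlated: squaring erases the phase information the statistic exists to
measure.

## Effective population size

At drift-recombination equilibrium the expected squared correlation between
loci at recombination distance c Morgans in a population of effective size
Ne is `r² = 1/(4·Ne·c + 1)`, hence `Ne = (1/4c)(1/r² − 1)`. The genome is
cut into 1-Mb bins; a SNP pair contributes to a bin only if both loci lie
inside it. Each bin carries the mean r² of its pairs and
`c = (rate_cM/Mb / 100) · (mean pair distance in Mb)`, the bin's map rate
being the length-weighted mean of the recombination-map windows overlapping
it. The current-Ne estimate is the mean ± sample SD across bins (bins, not
chromosomes, are the unit of the SD). Bins with r² = 0 are excluded
(infinite Ne); r² = 1 gives Ne = 0 and is kept.

Because LD at distance c reflects drift roughly `T = 1/(2c)` generations
ago, the per-bin points (T, Ne) form a trajectory through time;
low-recombination bins probe deeper time. Bins with c < 1e-6 Morgans are
excluded from the trajectory (c must dominate the per-generation mutation
rate for the approximation to hold).

The per-bin c convention (bin rate × mean within-bin pair distance) is one
of several defensible definitions; it is recorded in all outputs.

An optional sample-size correction subtracts `1/(2n)` from each bin's r² —
the expected contribution of sampling 2n haplotypes to observed r² — before
inversion. It is OFF by default in the pipeline, and ON in the
parameter-recovery validation scenarios: a recovery experiment against a
known truth should remove a bias whose form is known, and at n = 25 the
uncorrected estimate is biased to roughly two-thirds of the true size.

## Runs of homozygosity

A run is a maximal stretch of consecutive SNPs in one individual that (i)
starts and ends at a homozygous call, (ii) contains at most 1 heterozygous
and 2 missing calls strictly inside, (iii) never spans an inter-SNP gap
above 1 Mb, and is reported only if it (iv) spans ≥ 10 kbp, (v) contains
≥ 20 homozygous SNPs, and (vi) has ≥ 1 SNP/Mb density. The detector
enumerates every window that is maximal with respect to the het/missing
budgets (two-pointer scan per gap-delimited segment), trims ends to
homozygous calls, filters by (iv)-(vi), and keeps a non-overlapping subset
greedily from the left (longer first on ties). Each emitted run is
individually maximal — extending it one SNP in either direction violates a
constraint — and runs never overlap. This declarative scan is deliberately
not PLINK's sliding-window proportion heuristic: the five parameters define
runs directly, and the scan implements exactly them, so edge-case behaviour
may differ from PLINK.

Summaries: per sample, count, total and mean length, and genome fraction,
whose denominator is the SNP-covered genome span (sum over autosomes of
last-minus-first SNP position), because the panel defines what is
observable. Per population: means of those, plus the proportions of
individuals carrying at least one long (> 100 Mbp) or mid-class (50-100
Mbp) run. The chromosome-level correlation matrix relates mean r², mean ROH
length and mean map rate across chromosomes (Pearson, two-sided p).

## Synthetic data

The generator is a discrete-generation forward Wright-Fisher simulator of N
monoecious diploids per population: every offspring draws two parents
uniformly (selfing allowed); each transmitted gamete recombines with a
Poisson number of crossovers given the chromosome's genetic length,
breakpoints uniform in physical coordinates (so the map is uniform per
chromosome; rates may differ across chromosomes). Founders carry biallelic
sites at frequencies drawn uniform(0.05, 0.95) at linkage equilibrium;
there is no mutation. Sites monomorphic in the final sample are dropped.
Splits seed a derived population from the base population's parent pool at
a stated number of generations before sampling; admixture pulses redirect a
fraction of a target population's parent draws to a source population for
one generation. One mandatory seed drives everything; identical seeds give
identical panels byte-for-byte.

What the generator emulates: drift at realistic small sizes, recombination
heterogeneity across chromosomes, recent bottlenecks, divergence and
admixture, autozygosity (via demography, or via explicitly planted
homozygous tracts with controlled heterozygote error). What it does not:
mutation (so deep-time equilibria are unreachable — deep-time tests are
trend-level only), SNP-array ascertainment bias (arrays under-represent
rare alleles, which inflates short-ROH counts on real chips), genotyping
error outside planted tracts, sex chromosomes, and overlapping generations.
Passing tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to array ascertainment or call-error
processes.

Expected-behaviour checks on the simulator itself: heterozygosity decays by
(1 − 1/2N)^t and allele-frequency drift variance matches p(1−p)·t/2N within
Monte-Carlo tolerance; an independent coalescent simulation (msprime) of a
constant-size population reproduces the LD-decay trend and short-range r²
magnitude at trend-level tolerance.

## Validation scenarios (`snpdemog.validation`)

- *Constant-size Ne recovery*: N = 100, 20 chromosomes × 5 Mb at 1 cM/Mb,
  burn-in 300 generations (≥ 2.5× the slowest within-bin LD timescale,
  ~110 generations), 11,000 founder sites so that ≥ 2,000 SNPs survive
  drift, 25 sampled diploids. Sample-size correction applied (see above).
  The trajectory of a constant-size population is also checked for absence
  of trend: |median Spearman ρ(T, Ne)| < 0.4 across seeds (pilot medians
  around −0.25; per-bin Ne noise propagates a weak spurious trend through
  the shared 1/c factor, which the threshold accommodates without being
  able to hide a real size change).
- *Bottleneck direction*: 1000 → 50 diploids 100 generations before
  sampling; 6 chromosomes at 2.8 cM/Mb cover horizons T < 100 and 18 at
  0.2 cM/Mb the window T ≈ 500-1000; all 50 survivors sampled; MAF floor
  0.01 in this scenario, because with the full population genotyped the
  rare alleles are well measured and they carry the haplotype contrasts
  distinguishing surviving bottleneck lineages. A bottleneck of this
  severity (t/2N = 1) leaves ≤ 2 ancestral lineages in a low-recombination
  region with probability ≈ 0.6, collapsing such bins to r² = 1 (Ne = 0);
  the direction test (recent median below ancient median) therefore
  succeeds in most but not all demographic realizations — an inherent
  property of the scenario, documented rather than hidden.
- *ROH recovery*: 100 tracts (1-2 Mb, ≥ 30 SNPs) planted into fully
  heterozygous individuals — the designed worst case for boundary
  precision — with 1% heterozygote error; tracts with ≤ 1 error must be
  recovered exactly once with boundaries within one inter-SNP interval.
- *Differentiation and phase*: split halves of one panmictic sample (null:
  θ ≈ 0, phase correlation ≈ 1 at short range) versus populations diverged
  180 generations at N = 150 (lower, distance-declining phase correlation).
- *Correlation signs*: 9 chromosomes at 0.3 and 9 at 1.2 cM/Mb, N = 100 for
  150 generations: low-recombination chromosomes carry more LD and longer
  ROH, giving a positive LD × ROH-length and a negative ROH-length × rate
  correlation across chromosomes.

Problem sizes in these scenarios (chromosome counts, site numbers, seeds
per experiment) were chosen to keep each scenario's Monte-Carlo noise well
below the effect being measured while remaining runnable on a laptop.

## Numerical conventions and degenerate inputs

- Distances: "within 3 Mbp" is a strict inequality; distance bins and
  genome bins are half-open `[k·w, (k+1)·w)`.
- Empty recombination map, empty population after QC, all loci filtered,
  no shared SNP pairs between catalogs: explicit errors naming the input at
  fault, never silent empties (an empty LD table is returned, with a
  warning, only for an empty population — a data condition, not a usage
  error).
- Fst is clamped to [0, 1]; Nei's D returns +inf when every locus is fixed
  for opposite alleles; ASD pairs with no jointly called locus are NaN and
  logged.
- All pipeline outputs are plain TSV with a fixed float format; rerunning a
  configuration reproduces outputs byte-for-byte.

## Known limitations

- The LD-Ne inversion assumes drift-recombination equilibrium in an
  isolated, randomly mating population of constant (or slowly, linearly
  changing) size; after strong recent size changes, bins mix time horizons
  and the trajectory is qualitative, not quantitative.
- Per-bin Ne estimates are extremely noisy at small sample sizes (the
  across-bin SD in outputs is the honest width); estimates for populations
  under ~15 samples trigger a warning.
- The ROH caller's het/missing allowances are per run, not per sliding
  window, so counts are not numerically identical to PLINK's.
- Text-format allele coding is canonical only after one read-write cycle
  (see above); binary input preserves coding exactly.
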