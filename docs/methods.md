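# Methods

This note records the models implemented in `readsmith`, the defaults and
why they hold, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Coverage model

Coverage is modelled at fragment sites (sequence, start, length, strand).
The observed pair count at site n is negative binomial with mean
`mu_n = N * b_seq * b_len * b_GC(GC_n) * b_start,n * b_end,n` and
dispersion `r_n = mu_n/(alpha + beta*mu_n)`, equivalent to
`sigma^2 = mu + alpha*mu + beta*mu^2`. `alpha = beta = 0` is treated as
the Poisson limit. The two sources of the linear and quadratic
overdispersion terms are duplication processes (PCR/optical), which is why
sites carry a strand: duplicates land on the same site and strand.

*GC bias*: 101 percent bins described by `exp` of a natural cubic spline
with six knots, constant beyond the outer knots; outer knots sit on the
extreme GC bins containing counted fragments and inner knots may not sit
on empty bins. *Flanking bias*: one parameter per nucleotide per position
−10..19 relative to the fragment start (120 parameters). Start and end
share the table; the end context is reverse-complemented so positions keep
their meaning. The per-position parameters combine by summation passed
through twice the inverse logit (a product across 30 positions would
compound multiplicatively and fit real count means poorly). A site and its
opposite-strand twin swap start/end contexts, so their bias product is
identical; site enumeration still carries both strands because counts are
strand-specific.

Within one (sequence, fragment length) combination, `b_seq` and `b_len`
are constants and are absorbed into the normalisation; the spline's level
absorbs the normalisation in turn, leaving 128 relevant parameters
(120 + 6 + 2).

### Fitting

Three steps per (sequence, length) fit:

1. **Poisson warm start.** With flank biases fixed, the per-bin GC optimum
   is available in closed form (`sum k / sum flank-product` per bin); with
   GC fixed, the flank parameters are fitted by L-BFGS-B with analytic
   gradients. The two alternate (at most 4 rounds). Flank parameters are
   identifiable only up to per-position shifts at this stage and are
   centered to per-position mean zero before refinement.
2. **Knot placement.** Inner knots start equally spaced in cumulative site
   counts; hill climbing moves one inner knot at a time to the adjacent
   populated GC bin, refitting the six spline values on the binned Poisson
   likelihood (a 6-parameter problem on at most 101 bins), and keeps the
   best move until no move improves. Restricting moves to adjacent bins
   keeps each round at O(8) refits; the likelihood surface over knot
   positions is smooth enough that longer jumps were never needed on
   synthetic data.
3. **Full NB.** All 128 parameters are maximised jointly by L-BFGS-B with
   analytic gradients (digamma terms for the dispersion), knots fixed.
   Bounds: flank ±10, spline values ±20, alpha/beta in [1e-8, 1e5]. The
   flank design is a sparse one-hot matrix so likelihood and gradient are
   sparse matrix-vector products.

After the fit the 101 GC biases are renormalised so the mean over the
best-represented bins (fewest bins jointly holding ≥ 80% of sites) is 1.
Fits are scheduled for the L80 sequences (minimal set of longest sequences
covering 80% of the genome) at `clamp(round(60/n), 5, 30)` of each
sequence's thirty most abundant fragment lengths, equally spaced by
abundance rank. The printed anchors are 30 fits for one sequence and
4·15 = 60 for a 4-of-7 L80. A fit needs at least 10⁴ usable sites by
default, else it is skipped with a warning.

Converged fits combine by medians: plain medians for flank and dispersion,
a weighted median per GC bin with per-fit weight
`sqrt(l_GC) − 1` spread to neighbouring bins with decay 10^−d and
normalised to sum 1 within each fit (empty bins contribute zero, not
negative, weight). The weighted median takes the smallest value whose
cumulative normalised weight reaches 0.5.

Reference-sequence and fragment-length biases solve
`b_ref = C_ref / sum_len(b_len * b_sum,ref,len)` and its mirror by
alternating updates with the scale fixed every iteration (count-weighted
mean of `b_len` equal 1). The normalisation matters: the two equations
share an exact solution only when total per-sequence and per-length counts
agree, and real corrected counts satisfy that only approximately.
Convergence criterion: maximal relative change < 10⁻⁶. Bias sums over all
sites are computed exactly every 20th fragment length (starting at the
first counted length, stopping at a zero-count length unless lengths with
≥ 10 counts lie beyond) and extended to other lengths by natural splines:
in training via the smooth count/bias ratio with knots greedily reduced to
six by least squares (the spline is linear in its knot values, so each
candidate reduction is an exact least-squares solve), in simulation via
the ratio of bias sum over length bias with every sample a knot.

## Margin statistics and IPF

Six statistics are collected: error tendency and error rate per template
position and strand; sequence quality; base quality and base call
(each stratified by segment, tile and reference base); and InDels. Their
conditioning variables follow the trained-simulator architecture: region
position in bins of ten (bin 0 = region start or outside), GC in the
window of half a read length before the base, the region-start rate in ten
equal-width bins (bin 0 = outside), dominant reference base / dominant
error over the trailing five bases with ties broken toward the most recent
occurrence, previous quality (the sequence quality stands in at cycle 0),
errors so far (capped at 20), and fragment length in bins of ten. Reads
with unparseable Illumina tile fields share one "default" tile. The rate
statistic is collected at systematic positions only; "none" positions
carry no rate of their own.

Each statistic keeps only its C(d, 2) two-dimensional margins. For
simulation the joint is reconstructed as
`m_x = exp(sum_pairs T_ab[x_a, x_b])` — a Fienberg-style truncation of the
interaction expansion whose pair terms absorb the overall level and
one-dimensional effects, with the exponential guaranteeing positivity.
Iterative proportional fitting enforces one margin at a time
(multiplicative on the joint, additive on the pair term), sweeping pairs
in lexicographic order for bit-reproducibility. Margin cells with zero
count are structural zeros. Stopping: relative margin error < 10⁻³ or
200 sweeps; because structural zeros can make the margins unreachable by a
positive pairwise-exponential joint, fitting also stops when two
consecutive sweeps improve the error by less than 5% (the irreducible
error is typically 0.5–2% and the resulting conditionals are insensitive
to further sweeps at the 10⁻⁶ level).

Exact marginalisation iterates the dense outcome space, so cardinalities
are capped (10⁶ cells for template statistics, 2·10⁶ for read statistics
by default). Above the cap, unobserved categories are dropped first
(recording original values as labels) and condition dimensions are then
halved, widest first, labelling each coarse bin by its middle member; the
drawn (first) dimension is only coarsened as a last resort, since biasing
its labels shifts every simulated value. Conditional queries translate raw
values through nearest-observed-label lookup.

Impossible fixed combinations at query time fall back to the first
dimension's one-dimensional margin, then uniform, with a log message.

## Systematic errors

Training side: for every covered (position, strand) the top substitution
count c is tested against `Poisson(mu = coverage * r_e / 3)` where `r_e`
is the median per-position error rate in bins of 10⁴ reference bases (the
two strands of a bin share one estimate). If a bin's median is zero —
which happens when coverage is so low that most positions carry no error —
the bin's mean error rate substitutes, keeping the null mean positive; at
the read depths the model is meant for this path is not taken.
Benjamini-Hochberg runs once over all tests genome-wide; adjusted p < 0.05
is systematic. Positions where both strands are called and the forward top
error is the complement of the reverse top error (errors are recorded in
read orientation) look like variants and are excluded from every
statistic. Each call opens an error region of one read length carrying the
call's rate; a later call with a higher rate inside a region ends it and
starts a new one, in the sequencing direction of the strand.

Simulation side: tendencies then rates are drawn per position per strand,
sweeping 5'→3', conditioning on the same region bookkeeping; the drawn map
is storable as TSV and reloadable bit-identically (regions rebuild
deterministically from positions and rates). When the base-call model
emits an error at a position whose tendency is a nucleotide, that
nucleotide is substituted; at "none" positions the call model's own
distribution decides.

## Read synthesis

Per fragment: an allele (fair coin for diploid templates), then reads in
sequencing orientation. Sequence quality is drawn per read; base
qualities form a chain over cycles conditioned on previous quality, cycle,
sequence quality and the position's systematic rate; base calls condition
on quality, cycle, errors so far, systematic rate and dominant error.
InDel events, when the trained model carries any InDel mass, consume or
repeat template positions through a per-read pointer (deletions redraw the
cycle's event up to three times). Fragments shorter than the read length
run into the segment's adapter and then a poly-A spacer — poly-A rather
than a repeated adapter, because adapter inference on resimulated data
must see the same tail structure real libraries show (the poly-A trimming
rule assumes it). Cycles with no template or adapter get random bases at
quality 2.

Site counts are drawn per (sequence, length, strand) with
`mu = target_pairs * bias / total_bias_sum`, the total coming from the
simulation-mode bias-sum estimate, so the expected pair count equals the
target. Adapter detection uses suffix-prefix overlap alignment
(mismatch-only, ≤ 10% errors, ≥ 6 bases); training also treats a trailing
soft clip that starts at the pair's fragment length as adapter
read-through without re-expansion, because tails shorter than the overlap
floor would otherwise be compared to reference garbage.

## Adapters

Inference collects 10-mer counts over unmapped read parts per segment
(whole read when unmapped, suffix beyond the fragment length otherwise),
rejecting reads whose starting 10-mer recurs in their own unmapped part
and filtering homopolymer 10-mers. The most abundant starting 10-mer seeds
the adapter if it reaches `max(50, 0.01%)` of considered reads; extension
in each direction takes the candidate with the highest total abundance
provided it exceeds five times the runner-up (a positive best against a
zero runner-up passes, but only above `max(2, 1%)` of the seed count — a
single stray 10-mer must not extend the adapter) and is not already
contained in the adapter. Trailing poly-A runs of length ≥ 3 are trimmed;
an adapter that itself ends in A therefore loses that A to the merged
poly-A run, which is the expected behaviour of the rule, not an error.

## Synthetic data and what the tests show

`readsmith.fixtures` generates genomes with target GC, fragment sites with
NB counts from planted biases, and truth-perfect coordinate-sorted SAM
with planted adapters (followed by poly-A), planted strand-specific
systematic errors, AR(1) quality chains (default mean quality 25 falling
by 6 across the read — an older-HiSeq-like effective error level of
0.3–1%, chosen so that binned median error rates are positive at the
coverages the tests use) and quality-driven random errors. Fragments are
placed uniformly; coverage-bias recovery is exercised through
`simulate_site_counts`, not through the read generator, so trained
dispersion on fixture SAM is near zero by construction.

Default study conditions: read length 100, fragment length Normal(150, 40)
truncated at 40, systematic-error density 10⁻³ per (position, strand) with
rates 0.2–0.5, mapping quality 60 (clusters of MQ 0 plantable), one tile.
Test problem sizes: 2·10⁵ sites per coverage fit (10 seeds), 4·10⁴
training pairs on a 30 kb genome, 10⁵ simulated pairs for the round trip.

Passing tests show that each estimator recovers what it was pointed at
under its own generative assumptions, and that the full train → simulate →
retrain loop is self-consistent (fragment-length total variation < 0.05;
per-cycle error rates within 3 binomial sigma for ≥ 95% of cycles — the
allowance exists because simulation redistributes systematic errors over
fresh template positions, a variance the binomial sigma does not count).
They do not show that real flow cells obey the pairwise-margin truncation,
that real soft clips are always adapter or low quality, or that the
fixture's AR(1) quality chain spans the diversity of real quality
profiles; tile effects and InDels are carried structurally but the
fixtures plant neither.

## Known limitations

- The pairwise-exponential family cannot represent three-way interactions;
  sequential drawing from its conditionals can drift when a conditioning
  variable (errors so far) is itself generated by the chain. At the
  fixture's error rates the effect is within the round-trip tolerances.
- Flank positions are independent in the model; interactions between
  flanking bases are not represented.
- One adapter per segment; adapter dimers are out of scope.
- Haploid and diploid templates only; abundance overrides provide a
  minimal metagenomic knob.
- The template error-map draw is sequential per position and dominates
  simulation start-up on large templates.
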