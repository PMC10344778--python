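# Methods

`poreselect` implements a decision engine for dynamic adaptive sampling
("Read Until") on nanopore sequencers, together with a closed-loop simulator
for exercising it. This note documents the model, its assumptions, the
tunable parameters, and the design choices made where the design was
genuinely open.

## Genotype model

At every reference position `i` we maintain a probability distribution over
genotypes `g`. For a haploid reference the genotype space is the extended
alphabet `{A, C, G, T, DEL}`; for a diploid reference it is the set of
unordered allele pairs (15 genotypes over 5 alleles). The posterior after
observing base counts `D` at the site is

    f_i(g | D)  ∝  π_i(g) · ∏_d φ(d | g)^{count(d)},

computed in log space with per-site renormalization; the normalizer `Z_i(D)`
is the data likelihood. Counts are sufficient statistics, so the posterior is
invariant to read order.

**Priors.** The genotype matching the reference base receives `prior_weight`
(default 0.99). Haploid: the remaining mass is split equally over the other
alleles. Diploid: the remainder is split 2:1 between heterozygotes containing
the reference allele (equally) and all remaining genotypes (equally), so
heterozygote detection stays feasible while the reference is favoured.
Ambiguity codes (N etc.) get a uniform prior — no information means no bias.

**Observation matrix.** With substitution error rate `ε`, a miscall is one of
the three other bases with probability `ε/3` each. The deletion allele is a
minimal extension: a non-deleted allele is called as a deletion with the
spurious-deletion rate `δ_s` (default 0.05), with the substitution row
rescaled by `1 − δ_s`; a deleted allele is miscalled as each base with
`δ_m/4` (default `δ_m = 0.1`). The parameterization is isolated in one matrix
(`build_observation_matrix`) so it can be swapped wholesale. Diploid rows are
the equal mixture of the two constituent haploid rows (each read samples one
chromosome uniformly).

A caveat worth stating plainly: with `prior_weight = 0.99` and `ε ≈ 0.03`, a
*single* agreeing observation already pushes a non-variant site's posterior
above 0.999. Sites therefore "resolve" at a depth of 1–2 reads, and the
benefit field concentrates on uncovered sites and genuinely contradictory
(variant, deletion-bearing) sites. Lowering `prior_weight` makes resolution
require proportionally more agreeing reads.

## Positional benefit scores

The score of a site is the expected Kullback–Leibler divergence (natural log;
nats) between the posterior after one additional observation and the current
posterior, weighted by the predictive distribution `P(d | D) = Σ_g f(g|D)
φ(d|g)` of the next symbol. The candidate-symbol set includes DEL whenever
the deletion model is active. The expected-KL form is algebraically identical
to the expected reduction in Shannon entropy; both are implemented and
cross-checked to 1e-10 in the tests. The KL base only rescales all scores and
cancels in the ratio objective, but is fixed (nats) for reproducibility.

Scores depend only on (reference base, count vector), so a count-keyed cache
(`ScoreCache`) makes repeated evaluation cheap; cache hits are bit-identical
to recomputation, and counts beyond a ceiling (default 1000 per symbol) are
scored 0 — the score is numerically zero long before. The simulator instead
uses a fully vectorized field evaluation (`score_field`) with incremental
dirty-site rescoring: only sites whose counts changed since the previous
strategy update are rescored.

## Expected read benefit

A read starting at `i` with orientation `o` covers consecutive sites; its
expected benefit is the read-length-distribution-weighted sum of the
positional scores it would reach. We evaluate the exact identity

    U_{i,fwd} = Σ_{k≥0} S_{i+k} · P(L ≥ k+1)

(the CCDF suffix-sum form of the double sum over lengths) by a single
convolution; the reverse orientation mirrors indices. Reads truncate at
contig ends; a circular-genome flag enables wraparound for bacterial
chromosomes (off by default). The initial-fragment benefit `S^μ` is a fixed
μ-window sum in the read direction.

**Read-length distribution.** A discretized truncated-normal prior (defaults:
mean 3000, sd 1500, truncated below at μ, capped at `max_read_length`)
blended with the empirical per-length histogram of *accepted* reads by
effective-sample-size weighting (`prior_weight` pseudo-reads, default 100).
The histogram is exact per length (bin width 1) — coarser binning is used
only for export — so a degenerate update (prior weight 0, one observation)
yields an exact point mass. Rejected reads are excluded: their observed
length is an artifact of the decision point.

**Read-start distribution.** `w_{i,o}` is the probability that the next read
starts at `(i, o)`, normalized globally across all contigs under management
(uniform default `1/(2N)`). Empirical start counts are smoothed with a 2-kb
boxcar (preserving per-contig totals) and blended with the uniform prior by
effective-sample-size weighting (default 100 pseudo-reads), so unseen origins
are never locked out. A per-position additive pseudo-count was rejected: its
total prior mass grows with genome size and overwhelms realistic read counts.

**Piecewise CCDF approximation.** `approximate_benefit` replaces the CCDF
staircase by a `knots`-segment piecewise-constant function (runs merged into
contiguous groups, each replaced by its positional mean, which preserves the
mean read length). With `knots` ≥ the number of distinct tail levels it is
exact; at 8 knots on a truncated-normal CCDF the elementwise relative error
stays below 5% on random score fields. The exact form remains the reference
computation throughout.

## Optimal decision strategies

With time in base-translocation units (one base through the pore = one unit),
a read costs `α` (acquisition) plus: its full length `l` if accepted, or
`min(l, μ) + ρ` if rejected (μ decision bases, default 0.8 s × 450 nt/s =
360; ρ rejection overhead, default 300; α default 300). Under strategy `S`
with start field `w` and mean read length `λ`:

    Ū = Σ w·S^μ + Σ_{(i,o)∈S} w·(U − S^μ)
    t̄ = α + μ + ρ + (Σ_{(i,o)∈S} w)·(λ − μ − ρ)

The initial-fragment benefit accrues at *every* position — rejected reads
still deliver their first μ bases — matching the printed form of the average
benefit. The optimum of `Ū/t̄` is a threshold set in the marginal
benefit-per-time ratio `(U − S^μ)/(λ − μ − ρ)`, so ranking candidates by that
ratio (equivalently by the gain `U − S^μ` when all contigs share one length
distribution) and scanning ranked prefixes attains the global maximum; this
is verified against exhaustive enumeration over all `2^(2N)` strategies on
random small instances, for uniform and non-uniform start fields. Ties are
broken by (contig, position, orientation) through a stable sort, making
strategies bit-reproducible. When `λ ≤ μ + ρ`, rejection can only waste time
and the accept-all strategy is returned directly.

Multiple references are merged by weighting each reference's start
distribution with its observed read-origin share and solving one joint
ranking, so the engine sequences the most informative reads of the mixture
rather than of each genome separately. ROI masks restrict the candidate set:
forward starts are admitted on `[start − flank, end)`, reverse starts on
`[start, end + flank)`; everything else is pinned to reject.

**Update gating and cadence.** To keep the strategy from getting greedy on
thin evidence, a 20-kb window only participates in optimization once it has
reached 5× mean coverage; below that it keeps its initial accept state.
Strategies are recomputed every 10 s of simulated time or every 500 newly
mapped reads, whichever comes first. The early, frequent updates matter: they
produce the gradual decline of the accepted fraction and the within-genome
redistribution; with only a read-count cadence the abundant community member
is fully resolved before the first update fires.

## Simulator

The mock community plants SNPs and deletions site-wise at configurable rates
into random or user-supplied references (a fraction of SNPs may be
heterozygous for diploid models); every variant is recorded in a truth table
that exports to VCF. Within-genome coverage bias is an exponentiated smoothed
Gaussian field with mean 1 (default sd 0.3, smoothing scale 5 kb) — a generic
positive bias, deliberately not a mechanistic (e.g. GC) model. Fragments draw
their species proportional to abundance × genome length × mean bias, their
start from the bias field, a fair-coin orientation, and a lognormal length
(default mean 3110 bases, log-sd 0.6) truncated to fit the genome. A fraction
`p_unid` (default 0.15) of fragments cannot be identified from their first μ
bases and is rejected under the dynamic condition regardless of origin — a
false rejection when the origin was in the accepted set.

Two channel groups (dynamic and control) receive identically seeded copies of
the fragment stream and equal per-channel time budgets, so comparisons are
paired: the k-th fragment is identical in both groups regardless of
decisions, and with an accept-all strategy and `p_unid = 0` the two groups
produce identical read logs. Within a group, channels share the stream via
min-clock scheduling. Mapping is truth-based (the simulator knows each
fragment's origin); an optional offline path maps real PAF records instead.
Base calls are drawn per site from the haploid observation row of the true
allele, so an error-free model reproduces the sample genome exactly.

What the simulator does *not* model: pore blocking and death, channel-quality
heterogeneity, translocation-speed variability (time is exactly one base per
unit), signal-level artifacts, insertions, and structural variation beyond
single-base deletions. Passing tests therefore demonstrate the decision
engine's behaviour under clean, well-specified conditions — not performance
on real flowcells, where unresolved regions persist much longer (strain-level
structural divergence, repeats) and give the dynamic strategy more to work
with.

## Evaluation metrics

Per species and condition, on a fixed 20-point simulated-time grid: mean
coverage depth; fraction of sites below 5×; number of unresolved sites (a
site is resolved only when its maximum genotype posterior strictly exceeds
0.99 — the reference prior of 0.99 alone does not resolve a site); coverage
evenness `E = (1/N) Σ min(d_i, C̄)/C̄` (1 iff uniform, invariant under
scaling, undefined at zero mean); the strategy's accepted-site fraction
`|S|/2N`; and read-count abundance estimates, which remain unbiased under
adaptive sampling even as base-yield shares skew. A deliberately simple
posterior-argmax variant caller is included for scoring simulations against
the planted truth; it is labelled as such and is not a production caller.

## Problem sizes and defaults of the shipped experiment

The default `RunConfig` runs two channel groups of 2 channels for 1.25M time
units each over two 100-kb genomes at 90:10 abundance with 0.5% planted SNPs
and ε = 0.03 — small enough to iterate on a laptop, large enough that the
dynamic arm's enrichment of the rare species (roughly 2× final mean coverage
and a halved <5× fraction at equal time) is unambiguous. At these depths
(10–20×) the evenness score of the *abundant* species is dominated by its
Poisson sampling component, and the dynamic arm — which deliberately stops
collecting data on resolved regions — typically lands a few thousandths below
the control there while beating it clearly on the rare species; at flowcell
scale the sampling component vanishes and redistribution dominates.

## Numerical choices

Log-space likelihoods with per-site renormalization; `0·log 0 ≡ 0`
throughout; exact zeros in the observation matrix (error-free limits) are
handled by masked summation in the scalar path and by clamping `log 0` to a
huge negative finite value in the vectorized path. Argmax ties (genotypes,
ranking) are broken by canonical order. Expected-benefit convolutions use
`scipy.signal.convolve` (FFT for large inputs), which agrees with the naive
double sum to better than 1e-9 absolute. Strategy files are written
atomically (temp file + rename) so a concurrent reader never observes a
partial bitmap.
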