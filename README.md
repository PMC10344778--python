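# poreselect

Dynamic adaptive sampling ("Read Until") decision engine for nanopore
sequencing, with a built-in mock-community generator and closed-loop
sequencing-process simulator.

Nanopore sequencers can eject a DNA molecule after reading only its first few
hundred bases. Existing selection schemes decide from fixed, a-priori regions
of interest; `poreselect` instead *learns where data is still needed* while
the run is in progress. It is aimed at people studying adaptive-sampling
strategies — for example, mitigating abundance bias in microbial mixtures or
focusing coverage on unresolved variant sites — without access to a live
flowcell.

## The model in brief

- **Per-site genotype posteriors.** At each reference position the engine
  keeps a distribution over genotypes g (haploid alleles or diploid pairs,
  with a deletion allele): f_i(g|D) ∝ π_i(g)·∏_d φ(d|g)^{count(d)}, where the
  prior π is informed by the reference base and φ is the observation (error)
  matrix.
- **Positional benefit scores.** S_i = Σ_d P(d|D)·D_KL(f_i(·|D+e_d) ‖
  f_i(·|D)) — the expected information gain (nats) of one more observation at
  site i, equal to the expected reduction in Shannon entropy. Sites covered
  by many agreeing reads score ≈ 0; thin or contradictory sites score high.
- **Expected read benefit.** U_{i,o} = Σ_l L(l)·S^l_{i,o} accumulates the
  scores a read starting at (i, o) would reach, weighted by the read-length
  distribution L (truncated-normal prior, continuously updated); evaluated
  through the identity U_{i,fwd} = Σ_k S_{i+k}·P(L ≥ k+1).
- **Optimal strategy.** With acquisition time α, rejection overhead ρ and μ
  decision bases (all in base-translocation units), the Boolean strategy S
  maximizing benefit per unit time Ū/t̄, with t̄ = α+μ+ρ + (accepted start
  mass)·(λ−μ−ρ), is found by ranking (position, orientation) pairs by their
  marginal benefit-per-time and scanning ranked prefixes — provably optimal,
  and verified against exhaustive enumeration in the tests.
- **Simulator.** A paired dynamic-vs-control flowcell model: identical
  fragment streams, equal time budgets; accepted fragments cost α+l, rejected
  ones α+min(l,μ)+ρ. Mock communities with planted SNPs/deletions, coverage
  bias and unidentifiable fragments provide ground truth.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Run the default paired experiment — two synthetic 100-kb genomes at 90:10
abundance, 0.5% planted SNPs, 3% base-call errors, equal time budgets for the
dynamic and control channel groups:

```python
import poreselect as ps
from poreselect.simulator import random_references, make_community

refs = random_references(2, 100_000, seed=7)
community = make_community(refs, [0.9, 0.1], snp_rate=0.005, seed=7)
result = ps.run_experiment(ps.RunConfig(error_rate=0.03, seed=1), community=community)

final = result.snapshots.query("time == time.max()")
print(final[["condition", "species", "mean_coverage", "low_coverage_fraction"]])
```

```
   condition   species  mean_coverage  low_coverage_fraction
38   dynamic  species1        9.60726                0.03312
39   dynamic  species2        4.35977                0.58508
78   control  species1       20.48860                0.00000
79   control  species2        2.26462                0.90738
```

Reading the numbers: at equal simulated time the dynamic condition sacrificed
coverage of the abundant species (9.6× vs 20.5×) to nearly double the rare
species' mean coverage (4.4× vs 2.3×) and to cut its fraction of sites below
5× from 91% to 59% — the strategy history in
`result.strategy_history` shows the abundant species' accepted fraction
decaying from 1.0 toward 0 as its sites resolve. Read-count abundance
estimates (`poreselect.metrics.abundance_estimates`) remain within a point of
the true 90:10 in both conditions (89.7% / 10.3% dynamic, 89.4% / 10.6%
control) even while base yields diverge.

The same loop is available from the shell:

```bash
poreselect community --reference refs.fasta --abundance 0.9 --abundance 0.1 \
    --snp-rate 0.005 --seed 7 --out community/
poreselect run --config run.toml --seed 1 --out results/run1/
poreselect report --config run.toml --out results/report/
poreselect strategy --reference refs.fasta --paf mapped.paf --out strategy/
```

`strategy` computes a decision strategy offline from mapped reads (PAF with
cs/CIGAR tags) and writes per-contig packed-Boolean strategy files plus a BED
export of accepted intervals.

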