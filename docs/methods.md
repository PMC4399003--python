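# Methods

## The analysis model

The pipeline treats bovine high-altitude pulmonary hypertension (HAPH) as
an autosomal-dominant trait with incomplete penetrance. An animal is a
*carrier* when it holds at least one alternate allele at a candidate site
(het or hom-alt — dominant semantics throughout). Case-control status is
assigned from mean pulmonary artery pressure (PAP) with herd-specific
thresholds: by default PAP strictly above 50 mm Hg is affected, strictly
below 39 mm Hg unaffected, and the zone between is *indeterminate* and
excluded from every carrier-status analysis (the 42–48 mm Hg band is
diagnostically uncertain in adult cattle at altitude; a younger replication
herd is handled with an inclusive ≥45 threshold via configuration).

### Co-segregation filter

For an extreme design with n affected and m unaffected sequenced animals, a
filter stage (k, j) keeps a variant iff at least k affected animals carry
it and at most j unaffected do. Stages are evaluated *independently* on the
consequence-class-filtered variant list (protein-changing SNVs and short
coding indels by default), not sequentially, so the nesting
S(n,0) ⊆ S(n−1,0) ⊆ S(n−1,1) is a verifiable property rather than an
artifact of execution order; the default cascade for a 5v5 design is
(5,0), (4,1), (4,0). A gene passes a stage iff at least one of its variants
does, since candidate reporting is gene-level. Same-gene variants with
bit-identical carrier vectors collapse into one cis-haplotype unit: with no
observed recombinant they are statistically one dominant allele (the
EPAS1-style double variant is the motivating case).

Missing genotypes are never silently coerced: the default policy counts
them as non-carriers (conservative for the affected-carrier requirement),
`as_fail` drops any variant with a missing call in a statused sample, and
`exclude_sample` removes the call from both counts. Upstream
genotype-quality masking (e.g. GQ-based removals) is available as an
optional boolean pre-mask that turns individual calls missing before
filtering; variant calling itself is out of scope.

### Association statistics

All carrier-by-status inference uses the 2×2 table (a, b; c, d) =
(affected carriers, affected non-carriers; unaffected carriers, unaffected
non-carriers).

* Pearson χ², 1 df, **no continuity correction by default** — the
  screening-study convention this pipeline follows; Yates is a flag.
* Relative risk and odds ratio with Wald 95% CIs on the log scale
  (z = 1.96); zero cells leave CIs undefined unless an explicit
  continuity/Haldane–Anscombe flag is set. Note the Woolf upper bound for
  the herd-1 odds ratio computes to ≈56.4; some reports print a larger
  value from an unstated method — this implementation reports Wald only.
* Predictive values are Bayes-rule post-test probabilities under an
  *assumed* pre-test prevalence (default 0.5, the at-altitude development
  likelihood used for screening arithmetic); they are not sample
  frequencies.
* Cochran–Armitage trend uses dose weights (0, 1, 2) over the three
  genotype columns; weights (0, 1, 1) reduce it exactly to the uncorrected
  carrier χ², which the tests verify numerically.
* The Wilcoxon rank-sum test is exact (subset-sum convolution over doubled
  mid-ranks, two-sided by distance from the null mean) for combined n ≤ 20
  and a tie-corrected normal approximation without continuity correction
  beyond; mid-ranks handle ties in both regimes.
* Multi-herd joint analysis is cell-wise pooling of the per-herd tables —
  deliberately simple, matching the original joint analysis; it is not a
  stratified (Mantel–Haenszel) estimate.

### Expression enrichment

Gene-set genes are kept when their group-mean log2 expression strictly
exceeds the reliable-signal floor (default 7 log2 units) in *either*
group. Each kept gene is called up/down/neither by a two-sided t-test
(Welch by default; "uncorrected" means no multiple-testing adjustment) at
α = 0.05 combined with a strict linear fold-change threshold of 1.25
computed from anti-logged group means (2^Δmean — the Affymetrix
convention), never per-sample ratios. Background up/down rates are the
fractions of *all* floor-passing genes on the array called up/down by the
same criteria. The enrichment statistic is a three-category Pearson χ²
with 2 df against expected counts (n·p_up, n·p_down, remainder).

`expected_mode` matters: `rounded_counts` (default) rounds the up/down
expectations to whole genes with the neither category absorbing the
difference — the convention needed to reproduce whole-gene expected counts
like (5, 5, 58) on a 68-gene set, giving χ² = 96.4; `raw_proportions`
keeps fractional expectations (4.76, 5.44, 57.8), giving χ² ≈ 103.3, and
is the statistically standard choice. Both are first-class and the result
records which was used.

## The synthetic cohort generator

The generator produces the joint distribution the analysis assumes, not
sequence data. Per animal: carrier ~ Bernoulli(carrier_freq); affected
with probability penetrance (carriers) or phenocopy (non-carriers);
rejection sampling fills the requested affected/unaffected counts, so the
cohort is conditioned on status like a real case-control series. PAP is
drawn from status-specific normals truncated below at 15 mm Hg. The causal
haplotype is emitted as two heterozygous records in one gene with
identical carrier sets; background variants get per-variant population
frequencies uniform in a configurable range and carrier states independent
of status. Microsatellites are 10 markers × 8 equifrequent alleles,
independent across markers. Everything is a pure function of
(config, seed); seeds for replicate runs are spawned from one root seed
via `numpy.random.SeedSequence`.

Defaults are the first-herd study conditions: 20 affected / 21 unaffected,
carrier frequency 0.41 (the lowland screen estimate), PAP 94.2 ± 5.3 /
30.8 ± 0.8 mm Hg (the extreme-group values). Penetrance has no published
point estimate; 0.75 is adopted as consistent with 15/20 affected
carriers, and the phenocopy default of 0.05 reflects that a fifth of
affected animals in the original herd carried no candidate variant.
Hardy–Weinberg hom-alt carriers are available behind a flag (default off —
genotyped carriers were reported heterozygous).

What the generator does **not** emulate: linkage disequilibrium beyond the
planted perfect-LD pair, pedigree/relatedness structure, breed-specific
allele spectra, and covariate effects of age/altitude on PAP (no covariate
model is published, so none is guessed). Passing tests therefore
demonstrate correctness of the *statistical machinery* under the assumed
generative model, not robustness to population structure in real herds —
in particular, the diversity-selection stage exists precisely to blunt the
relatedness the generator lacks.

`simulate_expression` plants a configurable log2 upshift in
affected-carrier samples for gene-set genes over a Gaussian noise floor,
with a configurable fraction of genes re-based below the expression floor
to exercise that filter. `power_of_design` reports the probability that
the planted haplotype survives a filter stage and the mean count of
passing background genes; for background variants at carrier frequency c
in an n-vs-m design with stage (k, 0) the per-variant false-pass
probability has the closed form Σ_{i≥k} C(n,i)c^i(1−c)^{n−i} · (1−c)^m,
which the tests use as an oracle.

## Diversity selection

Pairwise distance between two animals is, per microsatellite marker,
2 minus the multiset overlap of their unordered allele pairs, summed over
markers (0..2M). Markers with a missing allele in either animal contribute
0 and are logged — this keeps the matrix complete at the cost of slightly
deflating distances for incompletely typed pairs. Subset selection
maximises total within-subset pairwise distance, exhaustively up to a
subset-count budget (default 10⁶) and by greedy max-min beyond, with the
method recorded in the result; ties break lexicographically by sample id
so selection is deterministic. The published verbal definition ("number of
alleles that differed") leaves the selection objective open; total
within-subset distance was chosen because it is reproducible and
oracle-checkable by enumeration.

## Numerical and design choices

* Two-sided p-values throughout; χ² reference distributions (not Fisher's
  exact, which is provided only as an explicit alternative path via scipy
  if users want it — the default must match the χ² convention).
* Zero-margin tables, all-one-genotype trend inputs and zero expected
  enrichment counts return explicit "undefined" results (NaN + note)
  rather than raising mid-pipeline.
* Exact rank-sum p uses ≥ with a 1e-9 slack when comparing rank-sum
  deviations, so mid-rank ties at the observed statistic are counted as
  extreme (the conservative convention).
* The simulated-cohort tests that check frequency recovery condition on
  status where the sampling does (e.g. carrier fraction among unaffected),
  since rejection sampling biases the raw cohort fraction; the pooled RR
  over 200 replicates of a 200v200 design is compared with the analytic RR
  implied by Bayes inversion of (penetrance, phenocopy, carrier frequency)
  on the log scale within 3 Wald s.e. — per-replicate RR means are
  Jensen-biased and would not converge to the analytic value.
* Problem sizes in tests and the acceptance script (10⁴ variants for the
  filter oracle, 500 null datasets for enrichment type-I, 200 replicates
  for parameter recovery, a 2,000-animal lowland screen) were chosen to
  hold Monte-Carlo error well inside the 3-s.e. assertion bands while the
  full suite runs in seconds.

## Known limitations

* The VCF dialect is deliberately minimal (GT only; INFO GENE/CLASS/ANN);
  symbolic alleles, breakends and likelihood fields are rejected upstream.
* Gene-level aggregation means a gene with one passing and many failing
  variants still passes; no burden-style weighting is attempted.
* The pooled joint analysis ignores between-herd heterogeneity.
* The enrichment χ² with rounded expected counts is slightly conservative
  or anti-conservative depending on rounding direction; use
  `raw_proportions` for calibrated inference.
* `expressed_subset` uses strict inequality at the floor; genes sitting
  exactly on the floor in both groups are excluded.
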