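# haph

Dominant-model co-segregation analysis for bovine high-altitude pulmonary
hypertension (HAPH) exome studies.

HAPH — the cause of brisket disease — is a heritable, autosomal-dominant
trait with incomplete penetrance in cattle residing above ~7,000 ft.
Extreme-phenotype exome designs hunt for the causal variant by sequencing a
handful of severely affected animals (mean pulmonary artery pressure, PAP,
far above the >50 mm Hg disease threshold) against unaffected controls
(PAP <39 mm Hg) and keeping only variants whose carrier pattern tracks
disease. This package implements that analysis as a tested, reusable
pipeline for geneticists and veterinary researchers:

* **I/O** for a minimal VCF v4.2 dialect, phenotype/microsatellite/expression
  TSVs and plain-text gene sets;
* **diversity selection** — pairwise microsatellite allele-difference
  distances and maximally diverse subset selection before sequencing;
* **co-segregation filtering** — the dominant-model filter cascade over a
  genotype matrix, with consequence-class filtering and collapsing of
  same-gene variants with identical carrier sets into cis-haplotype units;
* **association statistics** — Pearson χ² (no continuity correction),
  Cochran–Armitage trend, exact Wilcoxon rank-sum, relative risk and odds
  ratio with Wald 95% CIs, predictive values under an assumed prevalence,
  and pooled multi-herd analysis;
* **expression enrichment** — expression-floor filtering, per-gene
  uncorrected t-test + fold-change calls, empirical background rates, and a
  three-category (up/down/neither) χ² with 2 df;
* **synthetic cohorts** — a generative model (carrier frequency, penetrance,
  phenocopy rate, status-specific PAP distributions, background variants)
  that makes every stage testable without raw sequencing data, plus a
  filter-design power estimator.

## The statistics at the core

For a 2×2 table of carrier status against disease status
(a, b = affected carriers/non-carriers; c, d = unaffected ditto):

* Pearson χ² = n(ad − bc)² / ((a+b)(c+d)(a+c)(b+d)), 1 df, two-sided;
* RR = (a/(a+c)) / (b/(b+d)), 95% CI exp(ln RR ± 1.96·SE),
  SE² = 1/a − 1/(a+c) + 1/b − 1/(b+d);
* OR = ad/bc, Woolf CI with SE² = 1/a + 1/b + 1/c + 1/d;
* PPV = se·π / (se·π + (1−sp)(1−π)) and
  NPV = sp(1−π) / (sp(1−π) + (1−se)π) for prevalence π;
* enrichment χ² = Σ (O − E)²/E over (up, down, neither) calls in a gene
  set, with E from genome-wide empirical call rates, 2 df.

## Worked example

Association statistics for two herds from their carrier counts — herd 1:
15/20 affected and 4/21 unaffected animals carried the candidate variant;
herd 2: 11/15 and 4/16:

```
$ haph assoc --table 15 5 4 17 --table 11 4 4 12
herd1: chi2=12.9 p=0.000329 RR=3.47 (1.55-7.77) OR=12.75 PPV=79.7% NPV=76.4%
herd2: chi2=7.242 p=0.00712 RR=2.93 (1.19-7.23) OR=8.25 PPV=74.6% NPV=73.8%
pooled: chi2=20.02 p=7.68e-06 RR=3.23 (1.77-5.89) OR=10.47 PPV=77.5% NPV=75.3%
```

Herd 1 carriers have 3.47× the disease risk of non-carriers; with a 50%
pre-test likelihood of developing HAPH at altitude, a positive genotype
implies a 79.7% post-test probability of disease and a negative genotype a
76.4% probability of staying healthy. Pooling both herds strengthens the
association to p ≈ 7.7 × 10⁻⁶.

The full simulated pipeline (5v5 extreme cohort with a planted dominant cis
haplotype at penetrance 0.9, diversity selection, filter cascade,
association, enrichment):

```
$ haph run --config examples/demo.yaml --out demo_out
stages run: ['simulate', 'diversity', 'filter', 'assoc', 'enrich']; report in demo_out/run_report.json
```

In `demo_out/run_report.json` the cascade reports 1 gene at stage (5,0),
4 at (4,1) and 2 at (4,0); the planted two-variant haplotype collapses to a
single cis unit, tops the association ranking (p ≈ 1.6 × 10⁻³ on the full
cohort), and the planted expression upshift drives the enrichment χ² far
beyond its null expectation. Each subcommand (`simulate`, `diversity`,
`filter`, `assoc`, `enrich`, `power`) also runs standalone on the persisted
artifacts.

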