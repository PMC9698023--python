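# Methods

## Pipeline and its assumptions

The package consumes a genus-level 16S count table (taxa × samples), a
feature→lineage map when the table is still at feature (ASV) level, and a
per-cat survey table. The stages are strictly ordered: (1) collapse
features to genus labels; (2) drop samples with fewer than 5000 total reads;
(3) restrict to the healthy reference cohort; (4) extract the core genus
set; (5) drop samples whose summed core relative abundance falls strictly
below the cohort's 2.5th percentile; (6) compute per-genus percentile
reference ranges; (7) screen each core genus's abundance distribution for
multimodality. Collapsing conserves total reads, so steps 1 and 2 commute;
the pipeline collapses first.

Genus relabeling: the genus string is kept unless empty or one of the
uninformative placeholders (`uncultured`, `uncultured bacterium`,
`uncultured organism`, `gut metagenome`; matched case-insensitively after
stripping whitespace). An empty genus becomes `Unclassified<Family>`, a
placeholder genus becomes `<Family> uncultured` — two *distinct* taxa under
the same family, reproducing both label styles that appear in published
core tables. If the family is empty too, the deepest informative rank is
used with a rank prefix (`o__Clostridiales`) and a warning.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `min_sample_reads` | 5000 | reads | library-size floor below which a sample is unusable |
| `detection_reads` | 25 | reads | presence threshold for prevalence, core metrics and assessment |
| `prevalence_threshold` | 0.55 | fraction | core membership cut (≥, so an exact 55% qualifies) |
| core-sum exclusion | 2.5 | percentile | removes samples atypically depleted of core taxa; strict `<`, ties kept |
| `bcs_range` / `bmi_max` | 3–6 / 50 | score / index | body-condition disjunction: either suffices |
| `age_range_years` | 0.5–12 | years | inclusive on both ends |
| age classes | 7–36, 36–84, 84–144, 144–168 | months | junior/prime/mature/senior; half-open, ties to the older class, top closed |
| `n_permutations` | 999 | — | permutation tests; p = (exceedances+1)/(n+1), so p ≥ 1/(n+1) |
| DA filters | 10% / 0.1% | prevalence / max rel. abund. | nonzero-count prevalence, deliberately unlike the 25-read core rule |
| DA transform | log2, half-min pseudo | — | per-feature pseudo-count = half its minimum nonzero relative abundance |
| FDR | 0.05 | — | Benjamini–Hochberg step-up across taxa per predictor |

Detection for *core taxa present* reuses the 25-read rule; the percentile
ranges are computed over detected samples only (a published low-prevalence
genus with a nonzero 2.5th percentile is only consistent with
detected-only quantiles), with `detected_only=False` available as a
switch. Percentiles use linear interpolation between order statistics; the
same convention is applied everywhere and is checked against a hand-written
interpolation oracle.

## Statistics

**PERMANOVA.** Pseudo-F by the hat-matrix partition of the Gower-centered
inner-product matrix G: for the model up to a term with hat matrix H and m
added degrees of freedom, `F = (tr(HGH)/m) / (tr((I−H_full)G(I−H_full)) /
(n − m_full − 1))`, sequential (Type I) attribution for multiple
predictors, categorical terms dummy-coded. p-values permute sample labels
of G; `permutations="exact"` enumerates all n! relabelings (identity
included, exceedances divided by the total) for small n. On univariate
Euclidean distances the pseudo-F reduces to the classical one-way ANOVA F
exactly, which the suite checks to 1e-9.

**PERMDISP.** Samples are embedded on the real (positive-eigenvalue) PCoA
axes; each sample's dispersion score is its Euclidean distance to its group
centroid (coordinate-wise medians available as a switch); a one-way ANOVA F
on the scores is assessed by permuting group labels of the fixed scores.
Negative PCoA eigenvalues are reported and logged but excluded — no
Cailliez/Lingoes correction.

**Dip.** `dip_statistic` is the classic greatest-convex-minorant /
least-concave-majorant alternating algorithm over the sorted sample,
returning the sup-distance between the empirical CDF and the nearest
unimodal CDF (minimum value 1/(2n)). An independent, slow oracle
(`felicore._dip_oracle`) transcribes the definition as linear programs —
piecewise-linear unimodal CDFs with one jump at the mode, minimizing the
band half-width over mode placements — and the two implementations agree to
≤1e-6 on the test battery. The dip is location/scale invariant but *not* a
rank statistic: it depends on the spacings of the sorted values, not only
their order (this is also why the Monte-Carlo null uses the uniform, the
asymptotically least favorable unimodal distribution, making the test
conservative for peaked unimodal data). The dip test's p-value is the share
of same-size uniform samples whose dip reaches the observed one, with the
+1 correction, seeded.

**Differential abundance.** Independent per-taxon OLS on the log2
total-sum-scaled abundances, two-sided t p-values, BH step-up q per
predictor, vectorized across taxa. Note BH is *not* idempotent:
reapplying the step-up to a q-vector can only inflate it
(`q2_i = min_{j≥i} (m/j) q_(j) ≥ q_i`); constant vectors are fixed points.

## The synthetic generator

Each taxon has a Bernoulli detection layer and a log-normal latent
abundance given detection; covariate effects add to the detection logit
and/or the latent log-mean, with covariates centered at their generator
means so the base parameters describe the cohort-average animal. Latents
are normalized per sample and reads drawn multinomially at a log-normal
library size (Dirichlet overdispersion optional), so column sums equal the
drawn library sizes exactly.

The canned `paperlike_spec` has 60 genera: 30 core (reusing the published
genus names, detection clipped to [0.80, 0.995], latent medians clipped to
[0.8, 23]%) and 30 rarer genera (detection 0.05–0.40). The clips are the
construction's margins: they keep every core genus's *realized* ≥25-read
prevalence above ~0.70 and every non-core genus below 0.40, so the planted
core is recoverable at n = 200 with per-taxon misclassification probability
below 1e-4. Eight mid-prevalence core genera (detection 0.86–0.96, where
the logit is not saturated) carry a −0.35/yr age effect on detection — the
size needed for the qualitative finding the pipeline targets (core
membership declines with age while the core sum stays flat) to be
detectable at n = 300. Diet and environment effects act on log-abundance
(e.g. dry food ↑ *Prevotella 9*/*Megasphaera*, shelter ↓
*Bacteroides*/*Collinsella*/*Peptoclostridium*, ↑ *Lactobacillus*). The
differential-abundance benchmark (`da_benchmark_spec`) plants |ln effect|
= 1 on 30 of 200 taxa with balanced signs (15 up, 15 down) on
moderate-abundance taxa, so the compositional total is nearly preserved and
null taxa stay null after total-sum scaling — without sign balancing,
closure would push every null taxon's coefficient away from zero and
inflate the observed FDR.

What the generator does **not** emulate: between-taxon correlation beyond
closure, phylogenetic structure, longitudinal sampling, overdispersion by
default (the Dirichlet knob is off), or the messy free-text metadata of
real surveys. Passing tests therefore demonstrate correctness of the
*algorithms* under the stated generative assumptions, not performance on
real cohorts; the synthetic cohorts are also more core-dominated (core sums
~95%) than the published healthy population (~83%).

## Benchmark sizes and numerical choices

Standard benchmark conditions (used by the validation suite and the
acceptance script): 5 cohorts of n = 200 for core recovery; 100 random
small cohorts for the percentile oracle; 1000 replicates for the dip and
PERMANOVA type-I calibrations (nominal α = 0.05, judged against the 99%
binomial band); 50 cohorts of n = 300 for the planted age effect; 20
replicates of the 200-taxon benchmark for differential abundance.

Ties at percentile boundaries go to the inner band in assessments; a
Bray–Curtis distance between two all-zero samples is defined as 0 with a
warning; permutation p-values can never be 0 by the +1 rule; exact
PERMANOVA enumeration divides by the total count with the identity
included; all stochastic stages take explicit seeds, and a run-level seed
fans out to stage seeds via `SeedSequence` spawning.

## Limitations

Genus-level only (no species/strain resolution, no phylogeny-aware
distances or UniFrac); no mixed-effects or repeated-measures designs; no
compositional DA methods (CLR/ANCOM); band membership in an assessment is a
descriptive placement against a healthy cohort, not a diagnosis. The
published cohort's raw data are not public, so the printed reference table
is bundled as a fixture for consistency checks rather than recomputed from
reads.
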