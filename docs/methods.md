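# Methods

## Models and procedures

### Gradient screen

For species *j* and an ordering of the three residency groups (the
default candidate orderings are rural→urban→external, its
urban-first and external-middle permutations), two two-sided
Wilcoxon rank-sum tests compare consecutive group pairs. The combined
p-value is the larger of the two: a species is a gradient species only if
it shifts detectably in *both* steps. This max-combination is the
screen's main protection against false discovery — under the null the
combined p behaves roughly like the product of two uniforms, so chance
hits at any fixed threshold are quadratically rarer than for a single
test. Two-sided pairwise tests are combined with a post-hoc
direction-consistency flag (both shifts must share sign); inconsistent
species stay in the output but never count as significant. BH-FDR runs
within each ordering over the species passing the prevalence filter
(detection in strictly more than 20% of samples). A consequence worth
knowing: a truly monotone species is near-significant under the *other*
orderings too (both its pairwise tests reject there as well), but with
conflicting directions — the consistency flag, not the p-value, is what
zeroes the alternative orderings.

Rank-sum p-values use exact enumeration for combined n ≤ 20 without
ties and the tie-corrected normal approximation with continuity
correction otherwise; ties always use mid-ranks, matching R's defaults.

### Pooled cytokine model

All available (cytokine, stimulus, subject) records are pooled into one
ordinary least-squares regression per candidate microbe: natural-log
concentration on an intercept, cytokine×stimulus dummies (one reference
level), age, sex (female = 0, male = 1), and the microbe's zero-anchored
abundance rank (undetected → 0, maximum → n−1, mid-ranks among detected
values). Records are treated as independent even though each subject
contributes up to 45 of them; the stringent Bonferroni gate
(p·m < 0.005, m = species tested) is the counterweight. Classification:
positive/negative by the sign of the rank coefficient when the gate and
the >20% prevalence filter are both passed, neutral otherwise.

Fitting uses a residualize-once path (Frisch–Waugh–Lovell): the response
and every species' rank column are projected off the shared covariates a
single time, after which each per-microbe fit is a simple regression
carrying the full model's residual degrees of freedom. This is
algebraically identical to refitting the full design per microbe (tested
to 1e-9) and makes a 200-species scan take seconds.

### Pathway copy-number model

Per pathway, ln(length-normalized copies) for each contributing
(species, sample) pair with positive copies is regressed on ln(total
read depth), raw relative abundance (not ranks — the two models
deliberately differ here), and dummies for the positive and negative
immunomodulatory classes with neutral as the reference. Significance
stars on the raw two-sided t-test p-values: * p < 0.1, ** p < 0.01,
*** p < 0.001; BH across pathways is available but off by default since
the per-pathway raw p is the reported quantity. Zero-copy rows are
excluded (their log is undefined; absence of a pathway in a species is
not evidence about copy-number magnitude). A pathway whose contributors
are all neutral returns an informative "undefined" result rather than an
error.

### Metabolome integration

Species-metabolome effects: Spearman correlations over the full
species × peak grid, one global BH pass (a single significance line),
and per species the maximum |ρ| with its best pair's adjusted p.
Spearman p-values use the t approximation; at cohort sizes (n ≈ 300)
this is indistinguishable from the exact permutation null, which is kept
as a test oracle for n ≤ 7. Class contrasts are one-sided rank-sum
tests (positive-vs-neutral, negative-vs-neutral, alternative "greater")
on the max-|ρ| values. Metabolite–cytokine tests correlate each peak
with each ln cytokine response over subjects carrying both, again with
one global BH pass. Pathway tallies count, per annotated pathway with at
least 10 detected enzymes, the peaks whose strongest significant
cytokine correlation is positive vs negative; a separate count flags
pathways with ≥ 3 peaks tied to immunomodulatory species.

Clustering: peaks are z-scored across samples and k-means-clustered
(peaks as points in sample space, 25 seeded restarts, best inertia). The
cluster count maximizes the adjusted Rand index against molecular-class
labels, ties broken toward smaller k; each cluster is annotated with its
most prevalent class.

### Composition statistics

Jensen–Shannon divergence (natural log, 0·log 0 := 0) is used directly
as the between-sample distance — not its square root; the root is easily
obtained and, unlike raw JSD, satisfies the triangle inequality (a
property test checks this). Merge heights come from average-linkage
hierarchical clustering, chosen for robustness on divergence matrices;
the cluster count is k = j+1 for the first descending-height ratio
h_j/h_{j+1} below 2, with k = n when no such step exists and k ≥ 2
always. PERMANOVA is computed from the distance-based sums of squares
(SS_total = Σ_{i<j} d²/n, within-group analogues per group), with
pseudo-F and R² = SS_between/SS_total; the permutation p enumerates all
distinct label arrangements when there are at most 10,000 of them and
otherwise uses seeded Monte-Carlo permutation counting the observed
arrangement (so p ≥ 1/(n_perm+1)). Metadata screens use the chi-square
test for categorical variables (Yates correction only on 2×2 tables, as
required to reproduce presence/absence×residency anchors) and
Kruskal–Wallis for ordinal weekly-frequency variables; age is pre-binned
into three equal-frequency bins by stable rank order (299 subjects →
100/100/99).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes,
with defaults set to the study conditions: 70 rural, 253 urban, 471
external subjects; 5 cytokines × 9 stimuli; 8.2% of cytokine records
deleted at random (≈12,348 of 13,455 at 299 subjects); age uniform on
[18, 65]; sex Bernoulli(1/2); negative default age and male
coefficients.

Abundances are log-normal on detected values (per-species baseline means
N(0,1), within-species log-SD 1.0), Bernoulli detection at 0.9, then
closure (renormalization per sample). Gradient species get monotone
group-mean shifts of 1.5 natural-log units per step with alternating
sign, *centered* and anchored one step below the typical species mean:
this keeps a planted species a modest community fraction in every group.
The anchoring matters — a planted species allowed to dominate the
community drags every null species' share the other way through closure
and manufactures spurious "gradient" species; centering reproduces the
realistic situation where gradient taxa are a small part of total mass.

Cytokine responses follow the pooled model's generative form exactly,
with noise i.i.d. per record (so the null per-microbe t-test is
correctly calibrated, and the type-I check at 200 null microbes lands in
[0.03, 0.07]). Metabolite peaks are log-normal around per-class latent
factors (five classes by default), giving planted k-means clusters;
species–metabolite couplings overwrite a peak's latent with
r·z + √(1−r²)·noise where z is the Gaussian copula score of the species'
abundance ranks and r = 2 sin(πρ/6) converts the target Spearman ρ.
Pathway copies follow the copy-number model's generative form with a
unit log-depth coefficient, planted class offsets, and log-SD 0.5 noise;
read depths are 4–40 million. Everything is a pure function of
(config, seed) via numpy's seeded generator; sub-streams are spawned by
SeedSequence so tables are independent but jointly reproducible.

What the generator does **not** emulate: phylogenetic correlation among
species, strain-level variation, batch effects, compositional bias from
variable sequencing effort, LC-MS peak artefacts, or subject-level
latent immune factors. Passing recovery tests therefore demonstrates
that the estimators are correct for the assumed data-generating process,
not that the models are robust to those real-data complications — in
particular the pooled cytokine model's independence assumption is
exactly true here, whereas on real data it is an acknowledged
approximation.

## Recovery experiment sizes

Two per-stage choices deserve explanation.

**Classification recovery runs at 2,000 subjects.** The pooled model
treats 45 records per subject as independent while the microbe covariate
varies only across subjects, so the t-value a null species gains from
chance rank correlation with a planted species is (approximately) that
correlation times the planted species' own t. At 299 subjects chance
correlations of ~0.06–0.17 against the ~4 t-units the Bonferroni gate
requires leave *no* planted effect size that is both reliably detected
and reliably free of false positives. At 2,000 subjects chance
correlations shrink below 0.1 and a planted effect of 5e-5 per rank unit
(t ≈ 8) is comfortably detected while spurious t-values stay
sub-threshold; the seven planted species are recovered sign-exactly with
zero false positives in ≥90% of seeded replicates. The smaller study-
scale cohort is still exercised by the type-I and power checks, which do
not require joint zero-false-positive recovery.

**Null-calibration and recovery loops use 50–200 seeds** with fixed
per-seed problem sizes chosen so the full suite runs in about two
minutes and the acceptance script in under a minute on one CPU.

## Numerical choices and degenerate inputs

- OLS handles rank deficiency by pivoted column selection; aliased
  columns get NaN coefficients and a flag, mirroring R's `lm`.
- Zero residual degrees of freedom: coefficients returned, inference NaN.
- Constant rank vectors (species detected in all or no subjects at the
  same level) yield an undefined, flagged species effect.
- Constant peaks or responses are skipped in correlation grids, with the
  skip logged.
- Abundance tables auto-detect percent scale (row sums ≈ 100) and
  rescale to fractions; sub-unit row sums are allowed (sub-communities).
- Equal-frequency binning uses stable argsort, so ties resolve by input
  order deterministically.
- The Wilcoxon exact/asymptotic switch is combined n ≤ 20 and tie-free;
  the continuity correction is always applied on the asymptotic branch.

## Known limitations

- The pooled cytokine model's per-record independence is a modelling
  *choice*, not a fact; a subject-cluster bootstrap would be the natural
  diagnostic and is not part of the primary inference.
- PERMANOVA is one-factor only.
- The merge-height cluster-count rule is sensitive to the linkage method;
  average linkage is the default and configurable.
- Pathway tallies assume the annotation maps (pathway → compounds /
  enzymes) are given; no database retrieval is performed.
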