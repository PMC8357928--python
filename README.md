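# gradimmune

Statistical machinery for linking gut microbiome composition to ex vivo
cytokine responses and circulating plasma metabolites across an
urbanization gradient (rural and urban Tanzanian samples plus a
Western-European reference cohort).

The package is aimed at microbiome researchers who have species-level
relative-abundance profiles (MetaPhlAn-style), whole-blood cytokine
stimulation panels, untargeted plasma metabolomics, and HUMAnN-style
species-stratified pathway copy numbers, and who want to answer four
questions:

1. **Which species change monotonically along the gradient?**
   A "double Wilcoxon" screen: for each species, two two-sided rank-sum
   tests on consecutive group pairs under an ordering (e.g.
   rural→urban→external); the combined p-value is the **larger** of the
   two, so only species shifting in both steps survive, with BH-FDR per
   ordering and a prevalence > 20% filter.

2. **Which species modulate immune responses?**
   One pooled log-linear model per microbe *m* over all cytokine ×
   stimulus × subject records:

   ln *y*<sub>c,s,i</sub> = β₀ + β<sub>c,s</sub> + β<sub>a</sub>·age<sub>i</sub> + β<sub>s</sub>·sex<sub>i</sub> + β<sub>m</sub>·mic<sub>m,i</sub> + ε<sub>c,s,i</sub>

   where β<sub>c,s</sub> are cytokine-by-stimulus dummies and
   mic<sub>m,i</sub> is the species' relative abundance converted to
   zero-anchored ranks (undetected → rank 0, maximum → rank *n*−1).
   Species with Bonferroni-adjusted two-sided t-test *p* < 0.005 and
   prevalence > 20% are classified positive or negative by the sign of
   β<sub>m</sub>; everything else is neutral.

3. **Are metabolic pathways enriched in those species?**
   Per pathway *p*, species-stratified, length-normalized copy numbers
   are modelled as

   ln *y*<sub>p,m,i</sub> = β₀ + β<sub>d</sub>·dep<sub>i</sub> + β<sub>m</sub>·mic<sub>m,i</sub> + β<sub>e</sub>·eff<sub>m</sub> + ε<sub>p,m,i</sub>

   with dep<sub>i</sub> the natural log of sample read depth and
   eff<sub>m</sub> the positive/negative/neutral class (neutral as
   reference), so β<sub>e</sub> measures copy-number over- or
   under-representation in immunomodulatory species.

4. **Do those species reach the circulating metabolome?**
   Per species, the maximum |Spearman ρ| over all metabolite peaks with
   one global BH pass; one-sided rank-sum contrasts of these effect sizes
   between species classes; per-(peak, cytokine, stimulus) Spearman tests
   with pathway-level tallies; and k-means clustering of z-scored peaks
   with the cluster count selected by adjusted Rand index against
   molecular-class labels.

Supporting stages: Jensen-Shannon divergence distance matrices, a
merge-height rule for the community cluster count, one-factor PERMANOVA
(R² = explained compositional variance), and chi-square / Kruskal-Wallis
metadata screens. A seeded synthetic-cohort generator plants all of this
structure (gradient species, cytokine effects, pathway offsets,
species-metabolite couplings) so every stage can be validated against
known ground truth.

## Worked example

`examples/` holds one narrative script per capability. The cytokine
model example plants a positive and a negative species in a 300-subject
synthetic cohort and recovers them:

```text
$ python examples/03_cytokine_model.py
observations: 12408 of a possible 13500 (missing records dropped)
classification counts: {'positive': 1, 'negative': 1, 'neutral': 38}
  sp_005: beta_m=+9.97e-04/rank, p_Bonferroni=1.03e-20 -> positive
  sp_006: beta_m=-1.08e-03/rank, p_Bonferroni=4.02e-24 -> negative
```

The planted effects were ±1.0e-03 per rank unit: the pooled model
recovers both signs and magnitudes, and no unplanted species clears the
Bonferroni gate. The gradient screen example prints, for a cohort with
five planted monotone species among 100:

```text
$ python examples/02_gradient_screen.py
species tested (prevalence > 20%): 100
  RUN: 5 uncorrected, 5 FDR-significant
  URN: 0 uncorrected, 0 FDR-significant
  RNU: 0 uncorrected, 0 FDR-significant
FDR hits under rural->urban->external: ['sp_000', 'sp_001', 'sp_002', 'sp_003', 'sp_004']
```

— exactly the planted five under the true ordering and nothing under the
two alternatives.

## Command line

A thin CLI wraps the library for shell use:

```bash
gradimmune simulate --outdir demo --seed 4
gradimmune gradient --abundance demo/abundance.tsv --out demo/gradient.tsv
gradimmune immunomod --cytokines demo/cytokines.tsv --abundance demo/abundance.tsv \
    --metadata demo/metadata.tsv --out demo/effects.tsv
gradimmune run --config pipeline.yml     # full pipeline from one config
```

All inputs and outputs are plain TSV; `run` writes a JSON manifest with a
config hash, seed, and per-file checksums so identical configurations
reproduce byte-identical results.

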