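# dielprot

Analysis of diel (24 h light–dark) rhythms in label-free proteome and
phosphoproteome time courses, built for designs like the *Ostreococcus
tauri* study it implements: six Zeitgeber times (ZT 0, 4, 8, 12, 16, 20)
with five biological replicates, plus a dark-adaptation series (ZT 24–96 in
constant darkness) and partial ¹⁵N metabolic-labelling incorporation
courses.

It is aimed at proteomics groups who have quantified feature tables in hand
(from Progenesis/MaxQuant-style upstream software) and want the downstream
statistics: site-level phosphopeptide quantification, rhythmicity calls
with FDR control, equivalence ("confidently flat") calls, temporal pattern
analysis, a mechanistic model of light-stimulated translation, protein
turnover rates, and phase-specific kinase-consensus enrichment.

## What it computes

**Phosphopeptide-motif merging.** The same phosphorylation event is observed
as many technical species (charge states 2+–4+, missed cleavages,
oxidation/acetylation co-modifications). `merge_variants` sums these per
(protein locus, exact phospho-site set) — a *phosphopeptide motif* — after
optionally resolving ambiguous site localization by cross-referencing
alternative predictions keyed on (sequence, charge, modification count).
Total abundance is conserved to 1e-9.

**Rhythm statistics.** Per feature, OLS of arcsinh-transformed replicate
abundances on a cubic polynomial in ZT, `y ~ 1 + t + t² + t³`, F-tested
against the intercept-only model (df 3, n−4) — a cubic admits exactly one
peak and one trough inside the sampled cycle. Benjamini–Hochberg FDR across
features; a feature is *rhythmic* when q < 0.05 and its peak/trough fold
change (on normalized, untransformed means) exceeds 1.5. The complementary
equivalence call uses exhaustive pairwise TOST over all 15 ZT pairs with
margin ε = 0.3 on the transformed scale, reporting the worst pair p.

**Patterns.** Per-feature-centred PCA (SVD) of mean profiles; hierarchical
clustering (1 − Pearson r distance, Ward linkage) with a dynamic hybrid
tree cut (cut height 100, minimum cluster size 20); peak-phase histograms;
protein vs. phospho-motif peak pairing; Fisher-exact and KS-on-loadings
category enrichment.

**Light-gated translation model.** Protein dynamics

    dP/dt = ((k_syn − 1)·L(t) + 1)·m(t) − k_deg·P,   m(t) = cos(2π(t−φ)/24) + 1

with L = 1 in the light (12 h photoperiod), k_syn = 4 (light/dark synthesis
ratio), k_deg = 0.1 h⁻¹, integrated 240 h to periodic steady state for mRNA
phases φ on a 0.1 h grid. The model predicts how light-stimulated synthesis
concentrates protein peaks into the daytime regardless of mRNA phase.

**Turnover.** Per-protein degradation rates from partial ¹⁵N incorporation,
f(t) = E(1 − e^(−k·t)), with the global labelling efficiency E estimated as
the maximum labelled fraction + 0.01; Pearson correlation of k_deg with
dark-adaptation fold changes under an explicit, named outlier-exclusion
policy.

**Motif enrichment.** ±7-residue windows around phospho-sites; exact
binomial over/under-representation per (position, residue) against
background frequencies, displayed as signed −log10 p heights with the
Bonferroni line −log10(0.05/300) = 3.78; grouped-residue tests (e.g. D/E at
+1..+3); phase-specific enrichment of kinase-consensus classes
(proline-directed [pS/pT]P, CDK-like [pS/pT]PXX[K/R], acid-directed,
hydrophobic −5/+4) among rhythmic motifs per peak ZT.

A first-class synthetic-data module generates datasets with the study's
full statistical structure (cosine profiles, lognormal noise, technical
variant redundancy, a degraded outlier replicate, DA decay, labelling
courses), so every stage is testable end to end with no downloads.

## Worked example

```python
from dielprot import SimSpec, generate_ld_dataset, DielRhythmModel
from dielprot.preprocess import mean_normalize
from dielprot.translation import TranslationModel, TranslationParams

spec = SimSpec(n_features=855, frac_rhythmic=0.095, seed=1)
table, truth = generate_ld_dataset(spec)

model = DielRhythmModel(mean_normalize(table))
print(model.fit().summary())
print(model.equivalence(epsilon=0.3).summary())
print(TranslationModel(TranslationParams()).peak_time_distribution().summary())
```

prints

```
Diel rhythm analysis (cubic polynomial OLS, F-test vs intercept null)
  features tested     : 855
  FDR threshold (BH q): 0.05
  fold-change gate    : >1.5
  rhythmic            : 80 (9.4%)
  peak distribution   : ZT0: 15, ZT4: 10, ZT8: 18, ZT12: 13, ZT16: 13, ZT20: 11

Equivalence (pairwise TOST, eps=0.3, alpha=0.05)
  features tested : 855
  equivalent      : 703 (82.2%)

Light-gated translation simulation
  k_deg = 0.1 /h, k_syn = 4.0, photoperiod = 12.0 h
  mRNA phases  : 240 on a 0.1 h grid
  peak fraction: ZT0: 0.013, ZT4: 0.246, ZT8: 0.221, ZT12: 0.492, ZT16: 0.000, ZT20: 0.029
  daytime (ZT4-12) share of protein peaks: 95.8%
```

Of 855 simulated proteins with 9.5% planted rhythmic, 80 (9.4%) are called
rhythmic — the planted fraction is recovered at the joint q < 0.05 /
fold > 1.5 gate — while 82% of the (mostly flat) features are declared
statistically *equivalent* across all timepoint pairs, the stronger claim
that their abundance is demonstrably stable. The translation simulation
shows that with a 4-fold light/dark synthesis ratio, ~96% of protein peaks
land at the daytime timepoints ZT4–12 even though the driving mRNA phases
are uniform around the clock.

The command line mirrors the library: `dielprot demo` runs the whole
pipeline on synthetic data; `simulate`, `merge`, `preprocess`, `rhythm`,
`patterns`, `translate-sim`, `turnover`, `motifs` and `run` (YAML config)
operate on files.

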