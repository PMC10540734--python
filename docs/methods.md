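# Methods

This note documents the statistical models, parameter choices and numerical
conventions implemented in `dielprot`, and what the synthetic-data tests do
and do not establish about real data.

## Experimental design assumed

A diel (entrained light–dark, LD) time course sampled at Zeitgeber times
ZT 0, 4, 8, 12, 16, 20 with five biological replicates (labels A–E), where
ZT0 is harvested just before lights-on and ZT12 just before lights-off; an
optional dark-adaptation (DA) series at ZT 24, 48, 72, 96 in constant
darkness; and optional partial ¹⁵N incorporation courses. Sample columns
are named `<condition>_ZT<zt>_<replicate>`. Missing abundances are stored
as missing, never zero-filled: zero-filling would bias fold changes
downward at the trough, so all within-timepoint means use available
replicates only.

## Phosphopeptide-motif merging

The quantified unit is the *phosphopeptide motif*: all technical peptide
species sharing phosphorylation of the same residue set on a protein,
summed over charge states (2+–4+), missed cleavages and co-modifications.
Site positions are 1-based protein coordinates (so sites keep their familiar
names like pS10); peptide-local positions must be converted at parse time.
A multiply-phosphorylated site set is a distinct motif from its singly
phosphorylated subsets. Merging conserves total abundance exactly apart
from explicitly discarded variants (no phospho position; peptide shared
between loci, discarded to prevent double counting), is idempotent, and is
invariant to input order (groups are emitted sorted by locus, then site
key).

Ambiguous site assignments are resolved by cross-referencing alternative
most-probable-site predictions keyed on (peptide sequence, charge,
co-modification count). Where predictions disagree among themselves the
highest-confidence one wins, and ties break toward the original assignment
— the cross-referencing rule itself does not specify tie handling, so we
chose the conservative option. Variants with no matching prediction are
flagged `unconfirmed` and kept by default (`--ambiguous drop` discards
them); the two policies only differ when upstream localization is poor.

## Preprocessing

Sample columns are mean-normalized (each column scaled by grand mean /
column mean, computed over available values), and arcsinh-transformed,
x → ln(x + √(x²+1)), before any statistic that assumes normality — label-free
intensities are right-skewed and heteroscedastic, and arcsinh behaves like
log at high intensity while remaining defined at zero. The transform is
flag-guarded against double application because it is not idempotent.

Replicate quality is screened by correlating each sample's feature vector
with the per-timepoint median profile (features missing in any replicate of
the timepoint are skipped); a replicate with r² < 0.8 is removed, not
down-weighted. The correlation is computed on the arcsinh scale, which
stabilizes variance so a single very abundant feature cannot dominate r. A
PCA of replicate profiles accompanies the report for visual confirmation.

Protein rollup sums the unique (non-shared) peptides of each locus and
reports proteins quantified by at least `min_peptides` peptides (default 2;
the source protocols state the threshold both as "two or more" and "more
than two", so it is a parameter rather than a constant).

## Rhythm statistics

Each feature's transformed replicate observations are regressed on
`1 + t + t² + t³` with t the raw ZT hours 0–20 (no wrap-around and no
duplication of ZT0 at 24): a cubic over one cycle can represent exactly one
interior peak and one trough, which is the expected diel shape, while
avoiding the bias of periodic-regression methods against rising or falling
trends within a single sampled cycle. Significance is the F-test of the
cubic against the intercept-only null (df 3, n−4); an intercept null is the
default because the scientific null is "no change over time", but a
linear-trend null is available (`null="linear"`) for sensitivity analysis.
Zero-variance features return p = 1 by convention. P-values are BH-adjusted
across features.

Fold change is max/min of within-timepoint means on the normalized,
*untransformed* scale (p-values on the transformed scale, folds on the
natural scale — the transformed scale would compress folds); the peak
(trough) ZT is the timepoint with the maximum (minimum) mean, ties breaking
toward the earlier ZT for deterministic reporting. A feature is *rhythmic*
when q < 0.05 AND fold > 1.5.

Equivalence uses exhaustive pairwise TOST over the 15 ZT pairs with margin
ε = 0.3 on the transformed scale: each pair contributes the larger of its
two one-sided pooled-variance t-test p-values, and the feature's p is the
maximum over pairs, so equivalence is claimed only when *every* pair of
timepoints is demonstrably within ±ε. Welch variances are available behind
a flag. Note ε = 0.3 on the arcsinh scale corresponds to roughly a 1.35-fold
change at high intensity, so a feature cannot be simultaneously rhythmic
(fold > 1.5) and equivalent on the same data; the test suite checks this
consistency property.

Vectorization note: features with complete data share a single design
matrix, so all cubic fits are computed in one least-squares call; features
with missing cells fall back to per-feature fits on available observations
(minimum 5).

## Pattern analysis

PCA treats features as observations and ZT means as variables, centring
per feature; components come from SVD and each component's sign is fixed so
its largest-magnitude loading is positive, making outputs deterministic.

Clustering z-scales each mean profile, uses 1 − Pearson r distances and
Ward linkage, and divides the tree by a dynamic hybrid cut: a static cut at
`cut_height` (raw dendrogram height scale, default 100; a value above the
tree height leaves the whole tree eligible) combined with recursive
branch-wise evaluation. A join is split where its height stands clear of
the internal heights of both subbranches — max(child internal height) ≤
(1 − `split_gap`) × join height, default `split_gap` 0.5 — which is the
signature of two genuinely separated branches rather than smooth
within-cluster agglomeration. Branches smaller than `min_cluster_size`
(default 20) are left `unassigned`; there is no PAM-style reassignment of
unlabelled features. Cluster count is never hard-coded. Limitation: when
profiles form a phase *continuum* (uniformly distributed phases, as in the
default synthetic generator) there is no discrete cluster structure and the
criterion conservatively returns few or one cluster; discrete phase groups
are recovered exactly (planted-partition tests).

Category enrichment treats annotation terms as flat sets (no ontology
propagation): Fisher exact two-sided tests on the 2×2 partition for
cluster/peak/trough memberships, and two-sample KS tests on absolute PCA
loadings for component-wise enrichment, each BH-adjusted across terms.

## Light-gated translation model

    dP/dt = ((k_syn − 1)·L(t) + 1)·m(t) − k_deg·P(t)
    m(t)  = cos(2π(t − φ)/24) + 1,   L(t) = 1 for (t mod 24) < photoperiod

Defaults: k_deg = 0.1 h⁻¹ and k_syn = 4 (measured for this organism),
photoperiod 12 h, 240 h settling, φ on a 0.1 h grid over [0, 24). Growth
dilution is omitted by default (it averages ~0.01 h⁻¹, small against
k_deg); an optional constant `dilution` rate adds to the effective decay
for sensitivity analysis.

Because the right-hand side is linear in P with a piecewise-constant light
gate, the equation has an exact solution on each light/dark segment
(exponential relaxation toward the segment's sinusoidal particular
solution). The default integrator propagates this closed form between
switch times — machine precision, no discontinuity smoothing, and far
tighter than the 1e-8 relative tolerance the stiff numerical route
(`method="ode"`, LSODA at rtol 1e-9 per segment) achieves; the two agree to
1e-6 in tests. Trajectories over the final 24 h are sampled at 0.01 h and
peaks/troughs located on that grid. Steady state is verified by
|P(settle) − P(settle+24)| < 1e-6·max P.

"Daytime peaks" is operationalized as peaks whose *nearest sampled ZT*
(ties to the earlier ZT) is 4, 8 or 12, mirroring how the measured data are
summarized ("85% at ZT4–12" uses the sampled grid); a continuous
definition (peak ∈ (0, 12]) is available via `daytime="continuous"`. With
the defaults, 95.8% of simulated peaks are at daytime timepoints; in the
linear limit k_syn = 1 the peak uniformly lags φ by atan(ω/k_deg)/ω =
4.606 h (ω = 2π/24), which serves as the closed-form oracle.

## ¹⁵N turnover and dark adaptation

Labelled fraction f(t) = E(1 − e^(−k·t)) under the assumptions of constant,
protein-independent labelling efficiency and equal turnover of heavy and
light pools. E is chosen globally as max observed f + 0.01, capped at 1;
k is fitted per protein by bounded least squares over k ∈ [1e-5, 10] h⁻¹
(multi-start Brent on log k, 12 log-spaced brackets, xatol 1e-12 — the SSE
is unimodal for clean data but can develop shoulders under noise).
Noise-free recovery is exact to 1e-6; at 5% CV the median relative error is
below 10% (simulation tests).

DA fold change defaults to the ZT96/ZT24 endpoint ratio (max/min over DA
times behind `use_extremes`), with direction labels at the 1.5-fold gate.
"Changed more than average" is interpreted as |log2 fold| exceeding the
mean |log2 fold| across proteins. The k_deg vs. DA-fold correlation
(Pearson) reports the full set and any *named* exclusion subset —
exclusions are explicit inputs forming an audit trail, never automatic — and
an optional leave-one-out leverage report (Δr per point) helps users find
candidates worth naming.

## Motif enrichment

Windows are ±7 residues around the phospho-residue (length 15, `_`-padded
at termini; pads are excluded from every count). For each position except 0
(the phospho-residue is conditioned on, not tested) and each residue, exact
binomial tails against the background per-position frequency give
over-representation P(X ≥ k) and under-representation P(X ≤ k); heights are
−log10 p signed by direction, floored at p = 1e-300. The significance line
is Bonferroni for 20 residues × 15 positions at α = 0.05: −log10(0.05/300)
= 3.78. Grouped tests score "any residue of a set at any of a position
set" as a single binomial event.

Kinase-consensus classes are declarative approximations of consensus sets
that dedicated kinase-target predictors derive per site, and are labelled
as approximations in output: proline-directed ([pS/pT]P), CDK-like
([pS/pT]PXX[K/R]), acid-directed (D/E at any of +1..+3, CK2-like) and
hydrophobic-directed (hydrophobic at −5 and +4, SnRK/AMPK-like; the
hydrophobic set {A,I,L,M,F,V} is configurable since "hydrophobic" names a
property, not a fixed set). Phase-specific enrichment counts class matches
among rhythmic motifs per peak-ZT bin against the class rate in *all
detected* windows — the detected background guards against detection bias —
with BH adjustment across (ZT × class) cells.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of a specification plus seed (identical
inputs give byte-identical outputs). The LD generator draws baselines
log-uniformly over four decades (dynamic range), multiplies a cosine
profile 1 + A·cos(2π(t−φ)/24) — with A calibrated so the max/min over the
*sampled* ZT grid equals the requested fold exactly, giving a closed-form
construction oracle — by lognormal noise (CV default 0.1) and per-sample
loading factors (spread 0.05). Default sizes mirror the study: 855
protein-level features at 9.5% rhythmic, and 1472 motif-level features at
58% rhythmic with folds up to 20. Technical variants are a Dirichlet split
of motif abundance across 1–6 species (so merging recovers the motif
exactly); the outlier replicate is produced by permuting a sample's values
across features, which destroys feature-wise correlation while preserving
the intensity distribution; DA series decay exponentially from the ZT24
level at each protein's true k_deg (transcription and synthesis halted in
extended darkness); labelling courses follow the turnover model with
multiplicative noise clipped to [0, 1].

Not emulated: identification error, missing-value mechanisms that depend on
intensity, retention-time drift, peptide-level interference, and any
correlation between a protein's amplitude and its abundance. Passing tests
therefore demonstrate that the statistics are correct *under the stated
model*, not that the model captures every pathology of real LC-MS data;
the thresholds (q < 0.05, fold > 1.5, ε = 0.3, r² < 0.8) are the study's
conventions, not universal constants.

## Problem sizes used in tests

The test suite runs the calibration checks at 1000–2000 features and the
translation model on its full 240-phase grid; the end-to-end demo uses
300 proteins / 400 motifs. These sizes give stable binomial standard errors
for the rate checks while keeping the default suite fast.
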