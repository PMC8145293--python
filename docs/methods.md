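# Methods

`solvent_eval` benchmarks metabolite-extraction solvents for complex
microbial-community biomass using untargeted LC-MS feature tables.  It
implements the full evaluation chain — QC-based feature filtration,
internal-standard normalisation, accurate-mass annotation, pathway-recovery
scoring, per-solvent capacity/repeatability metrics, Bray–Curtis ordination
with multi-factor PERMANOVA, and per-feature differential abundance — and a
synthetic-data generator that emulates a two-reactor EBPR (enhanced
biological phosphorus removal) cycle study so every stage can be validated
against known ground truth.

## The emulated study design

Two laboratory sequencing-batch bioreactors enriched for
polyphosphate-accumulating organisms, sampled within one 6 h
anaerobic/aerobic cycle:

* **Reactor A** — 5 extraction solvents (pure methanol M; methanol:water
  mixtures MW1–MW3; methanol:chloroform:water MCW) × 4 cycle stages × 3
  technical replicates, intracellular metabolites only (60 biological
  samples per ionisation mode).
* **Reactor B** — 3 solvents × 2 stages × 2 compartments (intracellular /
  extracellular) × 3 replicates (36 samples).

Acquisition structure: one pooled-QC injection before the first sample run
and one after every 5 biological runs; a dilution-QC series derived from the
pooled QC at fractions 100, 80, 60, 40, 20, 10, 1 and 0 % with per-level
injection counts (10, 5, 3, 3, 5, 10, 10, 0) — 46 injections in total, the
0 % level being blank-equivalent and given no injections of its own — plus
blank injections.  Two isotope-labelled internal standards are spiked into
every non-blank sample.

## Synthetic intensity model

All biological variation is multiplicative (lognormal), the standard model
for LC-MS ion intensities; on the natural-log scale, for feature *f* in a
sample with solvent *s*, stage *t*, compartment *c*:

    log x = mu_f + log e(s) + gamma_f(c) + beta_f * 1[t in affected] + eps
    eps ~ Normal(0, sigma_bio^2 + sigma_ana(s)^2)

* `mu_f` — per-feature baseline, Normal(log 2200, 1.5²).  The location was
  chosen so the lower tail of the abundance distribution falls below the
  detection limit (500 intensity units): extraction efficiency then shows up
  in *detected-feature counts*, as in real per-solvent feature tables, and
  not only as a scale factor.
* `e(s)` — solvent extraction-efficiency multiplier.  Defaults (Reactor A:
  MW1 1.5, MW2 1.2, MW3 0.95, M 0.75, MCW 0.45) plant a full efficiency
  ordering with adjacent ratios ≥ 1.2, giving detected-count differences of
  the same order as those between published per-solvent counts.
* `gamma_f(c)` — per-feature compartment offset, Normal(0, 1²) for the
  extracellular compartment; intra- and extracellular profiles are strongly
  distinct, dominating the Reactor B ordination as in real data.
* `beta_f` — stage effect: a fraction `frac_differential` (default 0.10) of
  features carry ±`log_fold_change` (default 2, natural-log scale) in the
  aerobic (later) half of the stages.
* Noise defaults: `sigma_biological` 0.30, `sigma_analytical` 0.05 (pooled-QC
  RSD ≈ 100 σ ≈ 5 % for small σ, so filter behaviour is analytically
  predictable), `sigma_unstable` 0.50 (RSD ≈ 53 %, reliably above the 30 %
  cut-off).

QC structure: the pooled-QC level of a feature is the exponential of its
mean biological log intensity, measured with analytical noise; dilution-QC
intensity at fraction *d* is *d* × that level for genuine features and
*d*-independent for planted contaminants (default 5 % of features).  The
dilution series is modelled as prepared from the internal-standard-spiked QC
pool, so internal standards dilute proportionally and survive the linearity
filter.  Unstable features (default 10 %) carry `sigma_unstable` everywhere.
Intensities below the detection limit are stored as zero ("not detected").
Internal standards are spiked at 5·10⁵ with analytical noise only.

Compound masses are drawn uniformly on 80–900 Da with pairwise relative
spacing > 25 ppm, and noise features get masses ≥ 25 ppm away from every
database compound, so 10 ppm accurate-mass annotation is unambiguous by
construction.  One feature per compound per mode, m/z via the [M+H]⁺ /
[M−H]⁻ adduct rule with a proton mass of 1.007276 Da (electron mass
neglected: < 0.01 ppm here).

A single integer seed drives the whole generator through fixed-offset
sub-streams (design layout, feature properties, noise), so identical
configurations reproduce byte-identical outputs.

What the generator does **not** emulate: retention-time drift, batch
effects, isotopologue/adduct multiplicity, in-source fragmentation,
correlated features from shared pathways, or heteroscedastic
intensity-dependent noise.  Passing tests therefore demonstrate correctness
of the analysis chain under the stated model, not robustness to those
real-data phenomena.

## QC filtration and normalisation

Two rules, applied jointly (AND) to every feature:

* **Repeatability** — RSD% = 100·s/m over pooled-QC injections (sample SD,
  n−1), removal above 30 %.  A zero QC mean yields RSD = +∞ and removal.
* **Dilution linearity** — Pearson correlation of intensity against dilution
  fraction over the dilution-QC injections (each injection one point),
  removal below 0.8.  Undefined correlations (zero variance) fail the rule:
  such features carry no usable signal.

Both thresholds are configurable; the rules are order-independent and
idempotent.  Blanks contribute to no statistic and no blank subtraction is
performed.

Normalisation removes per-sample multiplicative scale using the internal
standards: the scale of sample *j* is the geometric mean over IS features of
x_ij / median_i(x), and all intensities in the sample are divided by it.
This estimator is scale-equivariant — multiplying any sample's column by a
constant leaves the normalised table unchanged exactly.  (Commercial
pipelines leave their normalisation algorithm unspecified; the
geometric-mean-of-ratios form is documented and testable.)

The log transform replaces zeros per feature with half the smallest positive
value of that feature (configurable); all-zero features are dropped with a
count in the report.

## Annotation and pathway recovery

Neutral mass = m/z ∓ proton; a feature is putatively annotated with every
database compound within 10 ppm (inclusive; ppm denominator = theoretical
mass), implemented as an interval search on the sorted mass array and
verified contract-equivalent to an exhaustive all-pairs scan.  Ambiguous
matches are all kept, sorted by |ppm error|; compound counts use the union
of unique ids.

Pathway coverage is presence-only: cell(group, pathway) = detected member
compounds / total members; a pathway is "recovered" when at least one member
is detected.  Recovered counts, the across-group shared set, and mean
coverage (over all or over recovered pathways) summarise the
biological-interpretation consequences of solvent choice.

## Per-solvent metrics

* **Capacity** — features detected per solvent (non-zero in ≥ 50 % of the
  solvent's biological samples), annotated compounds, and the annotation
  proportion 100·compounds/features, with mean/min/max across groups rounded
  half-up to one decimal for reporting.  Capacity is counted on the raw
  tables rather than after QC filtration: the shared pooled-QC series
  censors near the *mean* extraction level and would mask detection
  differences among efficient solvents (in the emulated study each solvent's
  dataset was processed with its own QC pool, which a single global series
  cannot reproduce).  All quantitative statistics (ordination, ANOVA)
  use the filtered, normalised tables.
* **Repeatability** — the pooled-QC RSD distribution per solvent (fractions
  below 5/10/20/30/50 %), restricted to retained features detected in that
  solvent; and, for ranking, the median within-cell replicate RSD, which is
  where solvent-specific analytical variance is expressible when the QC pool
  is shared.
* **Uniformity** — Shannon evenness H/ln(k) of feature occupancy over k = 20
  equal-width bins along the retention-time and m/z axes (affine-invariant;
  1 = uniform occupancy, → 0 as occupancy concentrates in one bin).  The
  published analysis assessed axis uniformity only visually; evenness is the
  quantitative proxy adopted here.

## Ordination and PERMANOVA

Bray–Curtis dissimilarity on square-root-transformed abundances (pairs of
all-zero samples defined as distance 0).  PCoA is the classical
eigendecomposition of the Gower-centred matrix −½ J D² J; coordinates are
reported for positive eigenvalues only and negative eigenvalues are reported
unchanged (no Lingoes/Cailliez correction).  PCoA on "column mean-centred
and scaled data" is incompatible with Bray–Curtis (which needs non-negative
input); the √-transform reading, consistent with the PERMANOVA input, is the
default, and Euclidean distance on centred/scaled data is available as an
explicit alternative via `bray_curtis(table, transform="none")` plus
standard preprocessing.

PERMANOVA partitions the total SS (Σ d²/n) among model terms as traces of
term projectors against the Gower matrix (McArdle–Anderson).  The engine
targets the two balanced designs in scope — terms enter sequentially (fixed
main effects, interactions, then the random replicate-within-stage term), so
the projectors are mutually orthogonal and the partition is exact
(|total − Σ terms − residual| / total < 1e−10 is a tested invariant).  For
Reactor A this yields DF 4 (solvent), 3 (stage), 12 (interaction), 8
(replicate nested in stage) and 32 (residual).  Every fixed term's pseudo-F
uses the residual mean square after the replicate term is removed.  (For the
Reactor B design the same accounting gives 20 residual DF from 36 samples;
published tables for an equivalent design report 7, which is not
reconstructible by standard DF accounting — the implementation follows the
stated design.)

Significance uses permutation of reduced-model residuals, 9999 permutations
by default, p = (#{F\* ≥ F} + 1)/(n_perm + 1).  Two schemes:

* **residual-basis (default)** — residuals are expressed in an orthonormal
  basis of the reduced model's orthocomplement and the basis coordinates are
  permuted.  Sample-level residuals of a rank-deficient reduced fit are
  correlated and have non-exchangeable joint structure; permuting them
  directly proved measurably conservative on these balanced designs
  (empirical type-I error ~1–3 % at nominal 5 %), while the basis
  coordinates are exchangeable under the null — for Euclidean responses the
  test is then exact, and simulation shows ~4–6 % empirical size for
  Bray–Curtis at the Reactor A design.
* **sample** — classic Freedman–Lane at the sample level
  (M = H_red + P(I − H_red) applied to the Gower matrix), with
  exchangeability blocks within stages for tests of within-stage terms.
  This scheme also serves exhaustive enumeration (`n_perm="exhaustive"`),
  where for a one-factor design it coincides exactly with enumeration of
  group labellings — the oracle used in the tests.

Post hoc pairwise comparisons run the two-level one-factor test per level
pair (optionally within a conditioning factor); pseudo-t = √pseudo-F.  When
fewer than 100 distinct relabellings exist, a Monte-Carlo p is added from a
gamma distribution fitted by moments to a 999-draw sample of the permuted
pseudo-F — a smooth stand-in for the coarse permutation distribution.

## Differential abundance

Classical per-feature one-way ANOVA on log abundances (vectorised sums of
squares, verified against `scipy.stats.f_oneway`), with stage as the factor
(stage × compartment combined into a single grouping for Reactor B).
Degenerate features: zero within- and between-group variance → p = 1; zero
within- with non-zero between-group variance → p = 0, flagged.
Benjamini–Hochberg step-up FDR (via `statsmodels.multipletests`, checked
against a hand-computed step-up oracle) at q < 0.05; significant features
and their annotated subset are counted per solvent.

## Numerical choices and degenerate inputs

* Projectors are built by SVD with a 1e−10 relative rank tolerance;
  eigenvalues within 1e−12 (relative) of zero are treated as zero in PCoA.
* Permutation F comparisons use a 1e−12 absolute tie tolerance with the ≥
  convention (conservative).
* Reported percentages round half-up (`Decimal`), matching conventional
  table formatting rather than IEEE round-half-even.
* Unbalanced designs, factors with < 2 levels, saturated models, < 2 pooled
  QCs and dilution series spanning < 2 fractions are rejected with explicit
  errors; the PERMANOVA engine is deliberately *not* a general unbalanced
  mixed-model tool.

## Problem sizes used in the checks

The test suite and acceptance script run the pipeline at reduced feature
counts (tens of compounds, ~60–360 features per mode) and the type-I-error
study at the Reactor-A-shaped null design (equal solvent efficiencies, 30
features, positive mode, 500 simulations × 499 permutations); these sizes
give stable Monte-Carlo estimates while keeping the whole suite fast.  The
filter sensitivity/specificity property is assessed with detection censoring
disabled so that it isolates the filters' discrimination of planted
contaminant/unstable features — with censoring on, features below the
quantifiable range correctly fail QC, which is the intended behaviour but a
different property.

## Known limitations

* One adduct per mode, no isotopes or in-source fragments; annotation
  accuracy on real data would be far below the synthetic 100 %.
* The global pooled-QC series cannot express per-solvent analytical
  variance; per-solvent repeatability ranking therefore uses biological
  replicate RSD.
* PERMANOVA p-values for Bray–Curtis remain mildly conservative (~4 % at
  nominal 5 %) even under the residual-basis scheme.
* No drift/batch correction and no missing-value imputation beyond the
  half-minimum zero policy.
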