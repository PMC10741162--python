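# Methods

## Study design emulated by the generator

`simulate.generate_study` lays out six pigs, each carrying four deep
partial-thickness (DPT) wounds — two treated with acellular fish-skin graft
(AFSG), two with fetal bovine dermis (FBD) — and six full-thickness (FT)
wounds — two AFSG, two cadaver skin (CS), two split-thickness "sandwich"
grafts. One biopsy per wound per day on days {7, 14, 21, 28, 60} gives
6 × 10 × 5 = 300 study injections, analyzed in random order with a pooled
QC at every injection position divisible by `qc_every` (default 7; 349
injections total). Wound level is the replication unit; pig identity is
carried in the metadata but not modeled as a random effect, matching the
plain two-way ANOVA downstream.

### Intensity model

Per feature *f* and injection *j*:

```
I_fj = B_f · 2^(s · z_f(day_j)) · 2^(δ_f · [day_j = 7 ∧ treatment_j = AFSG]) · d_f(o_j) · ε_fj
```

* `B_f` — baseline, log₁₀-uniform over [1e4, 1e6].
* `s` — trajectory effect size in log₂ units (`effect_size_log2`, default
  1.0, i.e. a two-fold swing per z-unit; a typical clearly-detectable
  metabolomics effect).
* `z_f(day)` — the feature's planted trajectory archetype (below), zero for
  non-responsive features (`frac_time_responsive`, default 0.25 ≈ the
  318/1367 and 248/1367 time-significant fractions such studies report).
* `δ_f` — a Day-7-only treatment effect of ±`effect_size_log2` on AFSG
  wounds for a `frac_day7_treatment_responsive` subset (default 0.3);
  later days carry no treatment signal by construction, so the per-day
  volcano stage has a known truth.
* `d_f(o)` — run-order drift: linear from 1 at the first injection to
  1 + `drift_amplitude` at the last (default 0.2), scaled per feature by a
  ±20% sensitivity jitter so drift is shared but not perfectly collinear
  across features and per-feature LOESS correction remains necessary.
* `ε_fj` — multiplicative log-normal noise with CV `noise_cv` (default
  0.1, a typical QC RSD for a well-behaved HILIC run); log-normality makes
  the CV independent of intensity, standard for LC-MS.

Pooled QCs carry the mean linear abundance of the study samples of that
feature, times drift and noise. Cells are deleted at `missing_rate`
(default 0.05). Everything is driven by one `numpy` generator seeded from
`SimConfig.seed`, so output is bit-identical per seed.

### Trajectory archetypes

Eight deterministic 5-point templates on the day grid, centered and scaled
to population sd 1 (interpolated in normalized time for other grids):
monotone rising U1/U2 (crossing their average by day 21 / day 28), monotone
falling D1/D2/D3 (below average by day 14 / day 28 / only by day 60) and
interior-peak P1/P2/P3 (Day-7 z above +0.3 / within ±0.3 / below −0.3,
peaks at days 14/21/28). The raw shapes were chosen so that within-letter
pairs are angularly well separated in cosine geometry (pairwise cosine
≲ 0.7); monotone shapes on five points are otherwise so strongly correlated
that no internal cluster index can tell planted trajectories apart. Two
cross-letter pairs (e.g. the late-falling D2 and early-peaking P1) remain
geometrically close (cosine ≈ 0.9); with all eight archetypes planted the
consensus may therefore split or merge clusters, which is why the
trajectory-recovery checks plant the six-archetype DPT-style mixture.

## Normalization

QC presence (default ≥ 0.80, boundary kept) precedes the QC RSD filter
(sample-sd/mean × 100 ≤ 25%, boundary kept; fewer than two QC values at
this stage is an error since the presence filter should have removed such
features). The filter direction is configurable because the source protocol
literally states the opposite direction, which contradicts universal QC
practice; the default removes imprecise features.

Drift correction regresses each feature's QC intensities on injection
order: LOESS with tricube weights, locally linear, span 0.75, no robustness
iterations, evaluated at every injection; with fewer than 7 QC points an
ordinary least-squares line is used instead (LOESS is unstable on very few
anchors). Corrected intensity is `raw × reference / fitted` with the
reference the median fitted value at QC positions, keeping values on the
original scale; scale equivariance holds exactly. A nonpositive fitted
trend anywhere the feature was measured drops the feature with a logged
count. Modes (positive/negative ionization) are processed independently
end-to-end — they come from separate acquisitions — and merged only for
reporting. The simulated run has a single batch; multi-batch stitching is
out of scope.

## Differential statistics

Per feature, a two-way fixed-effects ANOVA on log₂ intensities with factors
day and treatment plus interaction, Type-II sums of squares (robust to the
mild unbalance missingness creates), via statsmodels OLS/`anova_lm`.
Complete-case per feature; features with < 3 residual df or a collapsed
factor get NaN p-values and are excluded from the BH family. Time-significant
"features of interest" satisfy BH q ≤ 0.05 **and** raw p < 0.05 (the
conjunction of the two rules the protocol states). Per-day comparisons use
Student's (pooled-variance) t-tests on log₂ values, Bonferroni-scaled by the
number of features tested in that wound-type/mode family; the fold change is
the linear-scale ratio of arithmetic means with AFSG in the numerator.
Responders need p_bonf < 0.1 and FC > 1.5 or < 1/1.5. No imputation
anywhere: missing stays missing.

## Trajectory inference

Z-scores use the population sd per feature over the study samples of one
wound type on log₂ intensities; constant rows map to zero. Clustering is
complete-linkage agglomerative on cosine distance of the per-sample
z-vectors; missing z entries are treated as 0 (the z-scale mean) for
distance computation only, and zero vectors take distance 1 to everything
with a warning. The cluster count is chosen over k = 2…10 by mean rank
across silhouette (on cosine distance), Calinski–Harabasz and
Davies–Bouldin (both on the z-vectors in Euclidean geometry, where those
indices are defined); ties go to the smaller k. Rank consensus was chosen
over score normalization or majority vote as the simplest scale-free
aggregation; it is isolated in `consensus_from_metrics` and easily swapped.

Centroids (mean z per day) are lettered with a step tolerance of 0.2
z-units: U if no day-to-day step falls below −0.2 and the net change is
positive, D symmetrically, else P (valley-shaped centroids also map to P
via the largest absolute deviation, with a warning). Timing numerals: U/D
by the first day the centroid crosses zero, P by the Day-7 value against a
±0.3 band; numerals within a letter are made consecutive from 1, and a
fourth cluster of one letter continues the numbering with a warning. The
0.2 and 0.3 thresholds are verbal-rule formalizations, exposed as
parameters.

## Annotation

Monoisotopic atomic masses are hard-coded to ≥ 6 decimals for
{C,H,N,O,P,S,Na,K,Cl}; adduct shifts are derived from those constants with
the proton (not hydrogen-atom) mass, i.e. electron mass handled explicitly
— required to reproduce printed four-decimal ion masses. Five adducts are
supported ([M+H]⁺, [M+Na]⁺, [M+H−H₂O]⁺, [M−H]⁻, [M+Cl]⁻; configurable).
Level-3 hits are all polarity-compatible matches within 10 ppm, sorted by
ppm error with alphabetical tie-breaks. Fragment evidence uses greedy
one-to-one matching (closest pairs first, disjoint) at 0.01 Da; ≥ 5 shared
fragments give level 2, and level 1 additionally requires the database
record to be an authentic standard with retention time within 0.2 min of
the feature — an interpretation of the top identification tier, since
standard libraries differ in how they encode it. Isotopologue and
in-source-fragment matching (e.g. ammonia loss) are not modeled; published
tables occasionally print such ions, and they will not be mass-consistent
under the five-adduct model.

## Pathway analysis

Compound mapping is exact (case-insensitive) by name or KEGG id — no fuzzy
matching. Over-representation is the exact hypergeometric upper tail
P(X ≥ overlap) with counts restricted to the chosen universe; the default
universe is the set of compounds mappable from the annotated feature set,
standard ORA practice when the background is unstated. Impact is the sum of
relative betweenness centralities (pair-normalized, rescaled so the top
node is 1) of hit compounds divided by the pathway total, 0 for degenerate
graphs; an alternative convention (raw hit sum) is one line away in
`pathway_impact`. Disconnected components contribute within-component
shortest paths only. Multiple features mapping to one compound count once.
The bundled `data/*.tsv` fixtures are small toy graphs (arginine
biosynthesis, cysteine/methionine metabolism, arginine/proline metabolism)
assembled for demonstrations and tests; they are not curated KEGG exports.

## Problem sizes and numerical choices

The test and acceptance workloads use the full simulated design (300 study
samples) with 100–300 features, 5–10 seeds per stochastic check — sizes at
which every check completes in seconds to a couple of minutes while leaving
Monte-Carlo margins wide (e.g. planted-trajectory recovery succeeds 10/10
seeds with ARI 1.0 where 8/10 at ARI ≥ 0.9 is required). Tolerances: ANOVA
vs the projection oracle at 1e-10 absolute on p-values; betweenness vs
brute force at 1e-9; mass arithmetic asserted at the printed precision
(1e-4 m/z). Ties in consensus ranking resolve to smaller k; clustering is
deterministic given input order.

## What passing tests do and do not show

The generator produces idealized data: linear shared drift, a single batch,
log-normal noise with intensity-independent CV, missingness completely at
random, no correlation between features beyond the planted trajectories, no
isotopes/adduct multiplicity among features, and exactly aligned feature
tables (no peak-picking error). Passing recovery and error-control checks
therefore validates the statistical machinery, not its behavior under real
chromatographic pathologies (batch steps, intensity-dependent missingness,
correlated features, retention drift). Known limitations: BH q-values are
not idempotent under re-application (a property no step-up procedure has);
the ANOVA treats pig as a fixed blocking-free unit, so pig-level
correlation is ignored by design; consensus k-selection can over-split when
planted shapes are nearly collinear (see archetypes above).
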