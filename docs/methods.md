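# Methods

## The question and the estimand

If enzymes adapt to cold by increasing rate enhancement, then among orthologs
of one reaction assayed under comparable conditions, the variant from the
coldest-growing organism should tend to be faster. coldcomp operationalizes
this as the per-reaction **rate ratio** r = k_cold/k_warm and asks whether
the distribution of r across many reactions is shifted above 1 relative to a
temperature-free null.

A *reaction* is an (EC number, substrate) pair. Substrates are compared after
trimming and case-folding only; no chemical synonym resolution is attempted.
Within a reaction, each organism contributes one variant whose rate constant
is the **median** of its measurements (midpoint convention for even counts).
Only reactions with variants from ≥ 2 distinct organisms enter the analysis.
When several variants share the extreme T_Growth, the median of the tied
group is used for k_cold or k_warm; a reaction whose variants all share one
T_Growth has no ratio.

## Organism matching

Rate and stability records are joined to the growth-temperature table on a
normalized species name: trimmed, whitespace-collapsed, lower-cased. An
optional strain-stripping mode keeps only the first two tokens
(genus + species epithet); it is **off by default**, because collapsing
strains silently merges genuinely different thermal phenotypes, and the
correct granularity depends on how the temperature curation annotates
strains. Entries whose organism is absent from the table are dropped and
counted, never imputed. Every input row is accounted for exactly once across
{rejected at read, mutant, unmatched, single-organism reaction, retained}.

## The control distribution and its comparison

Rates vary across orthologs for many reasons unrelated to temperature. The
null is built from reactions with ≥ 2 variants sharing a single T_Growth:
per reaction the fold change k_max/k_min **and its reciprocal** enter a
flattened control multiset. When a reaction has several shared-temperature
groups, the largest group is used, ties broken toward the lowest temperature
(one fold-change pair per reaction either way). A reaction with both spread
and a shared-temperature group legitimately contributes to both samples —
the selection criteria are independent.

The data and control distributions are compared with a two-sided
Mann–Whitney U test: exact enumeration when n₁·n₂ ≤ 400 and the pooled
sample is tie-free, otherwise the normal approximation with midrank tie
handling and continuity correction (the regimes agree to well under 0.01 in
p where both apply). A fully tied pooled sample returns U = n₁n₂/2 and
p = 1 rather than a 0/0 z-score.

Medians of fold-change distributions are summarized with the **geometric
(log-space) median**: the ordinary sample median for odd n, the geometric
midpoint of the central pair for even n. Fold changes are ratio-scale data;
this convention is equivariant under reciprocals, so the reciprocal-closed
control multiset has median exactly 1 — with the arithmetic midpoint the
even-n median of a reciprocal-closed sample is (v + 1/v)/2, biased above 1.
Confidence intervals are 95% percentile bootstrap intervals (default 10 000
resamples), computed on the log scale and back-transformed; percentile
intervals commute with monotone transforms, so coverage is unaffected. The
percentile interval was chosen as the minimal fully reproducible choice; the
interval type, replicate count and seed are recorded in every summary.

**Known property — the comparison is conservative.** The control multiset
pairs every fold change with its reciprocal. These pairs are antithetic:
they occupy rank positions symmetric about the pooled median, which
stabilizes the control rank-sum and makes the true sampling variance of U
smaller than the Mann–Whitney null variance. Measured over 200 null
datasets, the two-sided test rejected at 0.05 in 0% of runs — type-I error
is controlled, but the test is *not* exactly calibrated, and small p-values
from it understate the evidence. Power is nonetheless high where it matters:
with a true slope of −0.02 log₁₀ units/°C, residual spread 0.3, and
reactions spanning > 20 °C, 500-reaction datasets reject in ~100% of runs.
The test suite asserts the conservative bound and the power floor.

## Slope screen

Per reaction with ≥ 3 variants and nonzero temperature variance, ordinary
least squares of log₁₀(k) on T_Growth yields m_rate (log₁₀ units per °C),
R², and a two-sided t-test of zero slope on n − 2 degrees of freedom.
Reactions with constant log₁₀(k) are reported as a perfect flat fit
(m_rate = 0, R² = 1, p = 1): the residuals vanish and R² = 1 − SSR/SST is
0/0. The screen threshold is Bonferroni, α/m over the m tested reactions.
Display clipping of ratios to [10⁻³, 10³] is presentation-only; every
statistic uses unclipped values.

## Stability mirror

Wild-type T_m records are matched to T_Growth with the same normalization;
repeated measurements per (protein, organism) collapse to their median
(switchable). T_m is regressed on T_Growth untransformed, both in °C. A
*protein family* is an exact protein-label group after trim/case-fold — no
sequence clustering, since label identity is the only grouping the source
schema supports. Families with members at ≥ 2 distinct T_Growth yield the
fold change T_m(cold)/T_m(warm), on Celsius values as plotted in the source
databases, with the same shared-extreme median rule; both temperatures must
be positive for the ratio to be defined.

## Michaelis–Menten fitting

v = k_cat·[E]·[S]/(K_M + [S]) is fitted by nonlinear least squares with
(k_cat, K_M) log-parameterized (positivity without constraints).
Initialization: k_cat from max(v)/[E], K_M from the concentration nearest
half-maximal velocity. Units are µM and µM/s so k_cat emerges in s⁻¹ and
K_M in µM; k_cat/K_M is reported in M⁻¹s⁻¹. A series needs ≥ 4 distinct
substrate concentrations; a fitted K_M more than 10³-fold below the smallest
assayed concentration flags the fit unconverged — saturating-only data carry
no K_M information and a silently plausible number would be worse than a
flag. Replicates aggregate to mean k_cat with sample (n−1) standard
deviation; a single replicate reports sd 0 with n = 1.

## Synthetic data generator

The generator emulates a literature-scale kinetic extract with a known
generating process, per reaction r and variant v:

log₁₀(k_v) = μ_r + β·T_v + ε,  μ_r ~ N(0, σ_reaction), ε ~ N(0, σ_noise)

Defaults are the study-scale conditions: 2223 reactions; variants per
reaction heavily weighted to 2 with a long tail (mean ≈ 3, ~43% of reactions
with > 2 variants); T_Growth spanning 1–83 °C; β = 0 (the no-compensation
null); σ_reaction = 1.2 and σ_noise = 1.0 log₁₀ units, giving between- and
within-reaction rate spreads of a few orders of magnitude as in curated
k_cat collections; 15% of variants replicated; mutant rows and
unmatched-organism rows injected *on top of* the core design (rates 0.5 and
0.3) so the curated output still equals the ground truth exactly.

T_Growth values are drawn on a whole-degree grid with half the mass on
common culture temperatures (25/28/30/37 °C). Curated growth-temperature
tables are reported at about integer precision and concentrate heavily at
standard culture temperatures; these coincidences are what give distinct
organisms identical T_Growth, and with them the same-temperature control
arises at a realistic rate (~20% of reactions). A continuous draw would
produce no ties and an empty control. Organisms are reused across reactions
at rate 0.5 to exercise the matching paths. Assay temperatures are annotated
(25/30/37 °C or missing) but do not affect generated rates: the generator
models variation *across* variants at a common assay condition, not the
Arrhenius dependence of a single enzyme on assay temperature — so
assay-temperature subsets change sample composition, never the underlying
effect. That, the unit-clean values, and the absence of duplicated-literature
and typo structure are the main ways the synthetic tables are easier than
real extracts: passing tests demonstrate the statistical machinery, not
robustness to BRENDA's full error structure.

The stability generator draws T_m = a + b·T_Growth + N(0, σ) with defaults
n = 433 records, 43 two-member families (cold member from the lower ~third,
warm from the upper ~third of the range — the spans literature family pairs
cover), b = 0.35 °C/°C, a = 45 °C, σ = 10 °C; with the realized
Var(T_Growth) this puts the expected R² = b²Var(T)/(b²Var(T)+σ²) near 0.45
and ~90% of family fold changes below 1. One seed governs everything through
fixed named substreams, so adding a generator never perturbs existing
streams, and the ground-truth record suffices to recompute every generated
value.

## Problem sizes and numerical choices

The acceptance script runs the full pipeline at the default study scale
(2223 reactions, ~13 000 rows — about a minute end to end) and uses 200
replicate datasets of 400–500 reactions for the calibration and power
measurements; the test suite uses the same designs at these or smaller
sizes. Bootstrap resampling is chunked (2000 resamples at a time) to bound
memory. Exact Mann–Whitney enumeration is capped at n₁·n₂ ≤ 400.
Temperatures outside −5…120 °C warn but load; BRENDA-style value ranges
("1.2–3.4") are rejected rather than guessed, as are rows with units no
conversion is defined for (known conversions: min⁻¹/h⁻¹ to s⁻¹; mM⁻¹s⁻¹ and
µM⁻¹s⁻¹ to M⁻¹s⁻¹).

## Limitations

- Organism matching is purely lexical; synonyms and reclassified taxa will
  fail to match and are only counted, not resolved.
- The control comparison's conservativeness (above) means its p-values
  cannot be read as exactly calibrated; the partition of ratios about 1 and
  the median CIs carry the descriptive weight.
- The 1142 + 1082 vs n = 2223 style of bookkeeping question (ratios exactly
  equal to 1) is resolved here by always reporting the three-way partition
  >1 / <1 / =1.
- No phylogenetic non-independence correction: orthologs of related
  organisms are treated as independent draws, as in the underlying analysis
  design.
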