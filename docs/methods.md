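# Methods

This note documents the statistical models, the numerical choices and the
scope of what the synthetic validation does and does not establish.

## Data model and preprocessing

A *case* is one safety report: demographics (DEMO row), one or more drug
records with role codes (PS primary suspect, SS secondary suspect, C
concomitant, I interacting), one or more MedDRA preferred terms (PTs),
optional seriousness outcomes, indications and therapy episodes. Dates are
stored as (raw string, precision) pairs with precision day/month/year/
invalid; no imputation is ever performed — each downstream operation
declares the precisions it accepts.

**Deduplication.** Spontaneous databases carry several versions of a case.
Per CASEID the version with the latest FDA receipt date is kept, ties
broken by the numerically largest PRIMARYID. If any version of a case has
an unparseable receipt date the whole case falls back to PRIMARYID-only
comparison (logged). The operation is idempotent and order-stable.

**Cohort.** A case enters the study cohort iff at least one drug record has
role PS and a name that matches the drug dictionary exactly after
uppercasing, trimming and whitespace collapsing. Exact matching was chosen
over fuzzy matching: reproducibility of the cohort from the dictionary
file alone outweighs recall, and misspelling recovery belongs in a
curation step, not in the statistics. All non-matching cases form the
comparator ("rest of database").

**Age bins.** Ages are normalized to years (YR×1, MON÷12, WK÷52.14,
DY÷365.25, HR÷8766, DEC×10). The baseline-table bins are `<18`,
`18–65` (18 ≤ a ≤ 65), `65–85` (65 < a ≤ 85), `>85`, `Unknown`; exactly 65
is assigned to 18–65 since the printed bins are ambiguous at the boundary.
Subgroup analyses use the coarser `<18` / `18–65` / `>65` preset.
Percentages are rounded half-up to one decimal, matching the usual
printed style of baseline tables.

## Contingency construction

The counting unit is the unique (report, event term) pair: a report
mentioning a PT twice counts once, and at SOC level a report counts once
per distinct organ class. This makes the grand total N well defined and
the margins additive — `a+b` is the cohort's pair count for every term and
`Σ_terms (a+c) = N` — which is what the four estimators assume. Counting
*reports* instead of pairs is available (`count_unit="reports"`), since
published studies rarely state which convention they used. Each PT maps
to a single primary SOC through a user-supplied two-column table; a PT
missing from the map is a hard error listing the offending terms.

## Disproportionality estimators

**ROR and PRR.** `ROR = ad/(bc)` with the Wald interval
`exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`; `PRR = [a/(a+b)]/[c/(c+d)]` with
the Pearson χ² statistic without continuity correction. When any cell is
zero all four cells receive +0.5 (Haldane–Anscombe) and the row is flagged
`corrected`. The identity ad > bc ⇔ a/(a+b) > c/(c+d) guarantees ROR and
PRR always agree in direction; this is asserted as a property test.

**BCPNN information component.** IC = log2 p11/(p1·p2) with independent
posteriors p11 ~ Beta(a+1, N−a+γ−1), p1 ~ Beta(a+b+1, N−a−b+1),
p2 ~ Beta(a+c+1, N−a−c+1), where γ = (N+2)²/((a+b+1)(a+c+1)) ties the
joint prior to the margins so that E[IC] ≈ 0 under independence. The
reported IC is the *exact* posterior mean, computed with digamma
functions, and IC025 = E[IC] − 1.96·√V[IC] with V[IC] from trigamma
functions. The familiar log-of-count-ratio closed form is the large-count
limit of this expectation; the two agree to printed precision for the
counts that appear in published signal tables, but the digamma form is
the one that matches a Monte-Carlo posterior sample (the test oracle) at
small a, where the log-of-ratio approximation is off by ≈ 1/(2(a+1)·ln 2)
bits.

**MGPS / EBGM.** Cell counts are modelled as a ~ Poisson(λE) with
λ ~ P·Γ(α₁, β₁) + (1−P)·Γ(α₂, β₂) (shape/rate). The five hyperparameters
are fitted by maximizing the marginal likelihood — a two-component
negative-binomial mixture — with L-BFGS-B on transformed parameters (log
shapes/rates, logit weight), started at (0.2, 0.1, 2.0, 4.0, 1/3) and
boxed to [e⁻⁹, e⁹] on each positive parameter to keep the optimizer out of
the degenerate point-mass corner; a Nelder-Mead polish runs if L-BFGS-B
reports failure, and a fit that does not reach at least the starting
likelihood raises an error carrying the best-found parameters. By default
only cells with a ≥ 1 enter the objective, because real extracts do not
enumerate empty cells; `include_zeros=True` gives the clean MLE when the
cell grid is fully enumerated (as in simulations — fitting an untruncated
likelihood on a zero-censored sample is biased, so parameter-recovery
studies use the full grid). The posterior is the conjugate mixture
Q·Γ(α₁+a, β₁+E) + (1−Q)·Γ(α₂+a, β₂+E); EBGM = exp(E[ln λ]) via digamma,
and EBGM05 is found by bisection on the mixture CDF to |ΔCDF| < 1e-9. An
independent test oracle integrates the unnormalized posterior on a log
grid (no conjugate algebra) and agrees to 1e-6 *relative* — relative
rather than absolute, because posterior quantiles reach the hundreds when
E is small and a large.

**Thresholds.** ROR: a ≥ 3 and CI lower > 1; PRR: a ≥ 3, PRR ≥ 2, χ² ≥ 4;
BCPNN: IC025 > 0; MGPS: EBGM05 > 2; `any_signal` is their disjunction.
These are the field-standard values; no multiplicity adjustment is
applied, matching standard practice for hypothesis-generating
disproportionality screens.

## Time to onset

TTO = event onset date − earliest day-precision PS therapy start, in days;
eligible iff both dates have day precision and the interval is positive
(zero is excluded because the Weibull log-likelihood is unbounded at t=0
for β < 1). The event anchor is configurable (`anchor="receipt"` uses the
FDA receipt date) since databases differ in which date is reliably
populated. Quantiles use linear interpolation (type 7). The Weibull MLE
comes from `scipy.stats.weibull_min.fit` with location fixed at zero; 95%
CIs are normal approximations on (ln α, ln β) using the observed Fisher
information (central finite differences, step 1e-5), exponentiated so both
bounds stay positive. Classification: shape CI entirely below 1 → early
failure; containing 1 → random; above 1 → wear-out. Likelihood-ratio CIs
and censoring-aware models are out of scope. A recovery study (100
replicates of n = 683 at α = 198.63, β = 0.63) shows 100% early-failure
classification and ~95% CI coverage for both parameters.

## Subgroups and sensitivity

Subgroup analysis restricts cohort *and* comparator to the stratum before
rebuilding tables, so N and (unless a prior is passed in) the MGPS prior
are recomputed within the stratum; an empty stratum on either side is an
error naming the stratum. Sensitivity analysis removes any case listing an
excluded drug name in *any* role — the conservative reading when a study
says "reports involving" a co-medication — and reports retained case and
(case, PT) pair counts.

## Synthetic databases

The generator's defaults describe the study conditions rather than being
tuning knobs:

* demographic marginals shaped like a real biologic's baseline table
  (sex 29.2/32.8/38.0% M/F/unknown; 77.9% missing age; 85.2% US; 52.2%
  consumer reporters; a 2019–2025 reporting-year ramp peaking at 49.2% in
  2024; indication mix 36.9/21.5/10.6% across three autoimmune conditions);
* per-term baseline reporting rates follow a power law (exponent 0.8)
  scaled to two events per case — spontaneous reporting is heavy-tailed;
* onset times Weibull(α = 198.63 d, β = 0.63), the early-failure reference
  values; therapy start = onset − TTO, receipt = onset + a 0–60-day lag;
* 30% of therapy starts are degraded to month precision (driving realistic
  TTO attrition), 10% of cases are emitted in 2–4 versions with perturbed
  receipt dates to exercise deduplication;
* planted signals multiply one (drug, PT) baseline rate by a chosen
  relative rate, optionally within one sex.

Where a published study did not state a value (the expected-count
distribution for hyperparameter recovery, the co-medication rate, the
reporting lag), a single realistic choice was made and is listed above;
none of these were revisited after seeing test results. Events are
assigned independently given the PS drug, so the generator does not
emulate co-reporting correlation between PTs, masking/competition bias,
reporter-dependent term choice or name misspellings — passing tests
therefore demonstrate correctness of the *computation*, not robustness to
those real-data pathologies. Reports drawn with no event get one backfilled
from the baseline distribution (every analyzable report must carry a
reaction), which perturbs the smallest rates negligibly.

All draws flow from one `numpy` PRNG seeded by the config, so a fixed seed
reproduces the file set byte for byte. The separate 9,090-case baseline
fixture is fully deterministic: each demographic dimension is filled
sequentially to the published counts, with arbitrary joint structure —
it pins down marginal tabulation and rounding, nothing more.

## Problem sizes used in validation

The validation suite runs at sizes chosen to make sampling error small
relative to the tolerances while staying desk-scale: 1,000-table oracle
sweeps for ROR/PRR/χ²; the 51×3 (a, E) grid for EBGM; 50 tables × 1e5
draws for the BCPNN Monte-Carlo comparison (MC standard error ≈ 0.002
bits against a 0.05-bit tolerance); 5×10⁴ cells for hyperparameter
recovery (observed worst-case relative error ≈ 4% against a 20% bound);
100 replicates of n = 683 for Weibull recovery; and a 10⁵-case database
for planted-signal recovery (expected a ≈ 50 at rr = 10) plus five
20,000-case null databases for specificity calibration.

## Known limitations

* Single primary SOC per PT; no multiaxial MedDRA hierarchy, HLT/HLGT or
  standardized queries (MedDRA licensing).
* No drug-name normalization to ingredients (RxNorm etc.); the dictionary
  is exact-match.
* No confounding adjustment, masking correction or duplicate detection
  beyond the regulatory version rule.
* One pooled TTO fit; no per-PT onset models, no censoring.
* The χ² uses no continuity correction and EBGM05 is the one-sided 5th
  percentile; both are the common conventions but other software varies —
  each statistic is isolated behind one function so variants can be
  swapped.
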