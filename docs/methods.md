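# Methods

## The problem and the estimand

Routine mortality statistics count each death once, under its underlying
cause of death (UCOD) — the single condition selected, by ICD-10 rules,
as having initiated the chain of events in Part I of the death
certificate. Part II of the certificate lists other significant
conditions that contributed to death without being part of that chain.
When causes compete for the UCOD slot — most visibly during the COVID-19
pandemic, when certification rules required COVID-19 to be selected as the
UCOD whenever present — single-cause statistics can systematically
understate the mortality burden of chronic conditions such as diabetes
mellitus (DM) and circulatory diseases (CVD).

This package implements a weighted multiple-cause-of-death (MCOD)
attribution that keeps each decedent as the unit of analysis. Every
certificate carries total weight 1, split across the causes it mentions:

* **UCOD** — weight 1 on the underlying cause (the classical statistic);
* **MCOD_HALF** (primary) — weight 1/2 on the UCOD and 1/2 shared equally
  among the k Part II causes (all weight on the UCOD when k = 0), so a
  certificate with UCOD g and Part II causes c₁…c_k contributes
  ½ to g and ½k⁻¹ to each cᵢ;
* **MCOD_EQUAL** (sensitivity) — weight 1/(k+1) on each of the k+1
  mentioned causes.

Because each decedent's weights sum to exactly 1, additional reported
causes *redistribute* weight rather than inflate counts: summing weighted
deaths over all cause groups always returns the number of analyzed
certificates, under every scheme, and this conservation propagates through
standardization (the all-group ASMR total is scheme-invariant).

Weighted counts are converted to age-specific rates per 100,000
person-years and directly standardized onto the WHO world standard
population (2000–2025). The discrepancy between attributions is summarized
by the standardized rate difference rd = ASMR_MCOD − ASMR_UCOD and rate
ratio rr = ASMR_MCOD / ASMR_UCOD, whose null values (0 and 1) mean the
multiple-cause view adds nothing beyond the single-cause one.

## Cause grouping

ICD-10 codes are normalized (dots stripped, upper-cased, pattern letter +
two digits + optional alphanumeric) and mapped to seven groups: neoplasms
(C00–D48), circulatory diseases (I00–I99), diabetes mellitus (E10–E14),
communicable diseases (A00–B99 ∪ J00–J22, *excluding* COVID-19), COVID-19
(U071/U072), ill-defined causes (chapter XVIII, R00–R99), and a residual.
The condensed cause lists used by mortality surveillance in the Americas
admit more than one defensible reading for some chapters, so the map is not
hard-coded: it ships as an ordered CSV of inclusive code-prefix intervals
(first match wins, which is how the COVID-19 carve-out from the
communicable chapter is expressed), and alternative groupings are drop-in
files. Matching uses 3-character prefixes, with 4-character refinement
only where a range bound has 4 characters (the COVID-19 codes).

Certificates whose UCOD is ill-defined are excluded from every numerator —
they carry no cause information and cannot enter a weighting — and
ill-defined Part II mentions are dropped before weights are computed.
Exclusion counts are reported (input = analyzed + excluded + parse-
rejected); no redistribution of ill-defined deaths is attempted.
Part II codes that duplicate each other or the UCOD are kept and weighted
individually (weights then accumulate within a group); a certificate with
UCOD I21 and Part II [I10] contributes 0.75 to CVD under MCOD_HALF.

## Missing demographics

Sex and age are missing at registry-like fractions (order 0.01–0.25%).
They are completed by *single* imputation conditional on the observed
record covariates (year, month, UCOD cause group, number of cleaned
Part II mentions, and the other demographic): sex by a draw from a fitted
logistic regression (drawing, not modal assignment, preserves the
conditional sex distribution); age either by predictive mean matching
(linear predictor; each missing record copies the age of one of its 5
nearest donors by predicted mean — the conventional donor-pool size) or by
a multinomial logit over 5-year bands followed by a uniform draw of single
years within the band. Sex is imputed first (with observed age and a
missingness indicator as predictors), then age given completed sex.
Degenerate fits fall back to marginal draws with a logged warning.

Single imputation means downstream variances ignore imputation
uncertainty. At these missingness fractions that is negligible: the test
suite verifies that imputed-data ASMRs sit within 0.5% (relative) of
complete-data ASMRs across 10 replicate registries.

## Rates, variances, intervals

Age-specific rate: 100,000 × weighted deaths / person-years, on 5-year
bands 0–4 … 80–84, 85+ (the bands on which the packaged WHO standard
weights are defined; weights are normalized to sum to 1 on load). Monthly
analyses divide each annual population by 12, ignoring month length and
leap years — a deliberate simplification, stated rather than hidden.

The variance of a weighted count has no single canonical form. The
default ("poisson") treats the weighted count as a Poisson mean, which
reduces exactly to the classical rate variance under the UCOD scheme
(all weights 1). The alternative ("weighted") uses the sum of squared
weights in the numerator; since weights are ≤ 1 it is never larger, and
the two coincide for UCOD. Both are carried through standardization
(asmr_var = Σ w_a² var_a).

ASMR confidence intervals default to the Fay–Feuer gamma method, the
standard choice for directly standardized rates and well-behaved at low
counts (for a zero rate the lower bound is 0 and the upper bound comes
from the largest single-death increment); a symmetric normal interval is
available for cross-checks and agrees with the gamma interval within 2%
relative when all cells carry > 100 events.

## Contrast intervals: why the bootstrap is the default

The MCOD and UCOD ASMRs for a stratum are computed from the *same*
decedents and are strongly positively correlated (the MCOD count for a
group contains at least half of that group's UCOD count). An interval for
rd or rr built on the independence approximation
(var(rd) ≈ var_M + var_U) is therefore badly conservative: in simulation
its empirical coverage is essentially 100% rather than 95%. The package
keeps the analytic route (`rate_contrast`, log-normal interval for rr)
because it needs only the two ASMR tables, but the pipeline's default is a
record-resampling bootstrap: certificates are resampled within each
(period, sex) cell via Poisson(1) multiplier weights, both ASMRs are
recomputed per replicate from per-record contribution matrices (the ASMR
is linear in the per-record weights, so this is exact and fast), and
percentile intervals are taken. Measured coverage for rd and rr is
92–97% at stratum sizes of a few hundred deaths. When Part II is empty
for every certificate the two schemes coincide record by record and both
routes return degenerate intervals at the null exactly.

## The synthetic registry

The generator emulates the structure the analysis assumes, with every
ingredient parametric so expected results exist in closed form:

* **Deaths.** Per (year, sex, 5-year age band, cause group):
  Poisson(hazard × population / 10⁵), hazards Gompertz-like in age with
  per-group baselines and sex ratios; an optional per-(year, group)
  multiplier expresses COVID-19's absence in 2019, peak in 2021, and
  recession in 2022.
* **Certificates.** UCOD codes drawn uniformly from small per-group code
  lists (realistic-looking files, simple truth bookkeeping); Part II
  mention counts from a zero-inflated Poisson truncated at 6 (certificate
  line limits), with the empty-Part-II probability falling over calendar
  years (from 66.7% in 2019 to 53.6% in 2022 in the default
  configuration) and the non-empty mean rising — the completeness drift
  observed in real registries; Part II cause groups from a per-UCOD-group
  comorbidity profile that includes a 5% ill-defined share (exercising
  the cleaning rules).
* **Cause competition.** In configured pandemic months (March 2020 –
  December 2021 by default), a decedent with a chronic CVD/DM UCOD has,
  with probability 0.25, COVID-19 recorded as the UCOD and the chronic
  cause demoted to Part II. Total deaths are unchanged; only attribution
  moves. Because the competition draw uses its own named RNG stream,
  raising the probability relabels a superset of the same deaths, making
  the effect on the CVD rate difference monotone by coupling.
* **Missingness.** MCAR gaps in sex (0.03%) and age (0.15%), inside the
  ranges reported by national registries.
* **Scale.** The default population is a static Colombia-like pyramid of
  51 million (≈ 330,000 deaths/year); a scale factor shrinks population
  and counts without changing any rate.

The closed-form truth (`true_asmr`) enumerates the Part II count k
(0…6), binomially thins it for ill-defined survival, and computes the
expected weight each UCOD group sends to each cause group per scheme —
e.g. under MCOD_HALF a non-competed death with UCOD g sends
P(j=0) + 0.5·P(j≥1) to g and 0.5·P(j≥1)·q(g→h) to each other group h,
where j is the cleaned mention count and q the (ill-defined-excluded)
profile. A conservative Monte-Carlo standard error accompanies the truth
(per-record contributions lie in (0, 1], so a stratum's weighted-count
variance is at most its mean).

What the generator does **not** emulate: demographic change (fertility,
migration, population trends), spatial structure, cause-specific
seasonality, non-MCAR missingness, certification-quality differences
across regions, and Part I chain-of-events structure (the UCOD is given,
not re-derived). Passing recovery tests therefore demonstrates that the
estimator chain is correct under the stated generative assumptions — not
that real registries satisfy those assumptions.

## Validation problem sizes

The test suite validates at sizes chosen to give tight Monte-Carlo
resolution while keeping a default run on one CPU comfortable:
conservation and oracle-equivalence checks on ~10⁴ certificates;
closed-form ASMR recovery on three years at 10⁶ person-years per
year-sex stratum (all 7 groups × 3 schemes × sexes × years, within 3
conservative Monte-Carlo SEs, with exact equality where the truth is
identically zero); interval coverage on 500 replicate registries with
≥ 200 expected deaths in every checked stratum; competition monotonicity
across probabilities {0, 0.2, 0.4} on coupled streams; and imputation
robustness across 10 replicates at the upper end of registry missingness.
The acceptance script analyzes a half-scale default registry
(~650,000–730,000 certificates).

## Known limitations

* The cause map ships one reading of the condensed cause list; results
  for the communicable-diseases group in particular depend on that
  reading (alternative maps are drop-in CSV files).
* The "poisson" variance treats fractional counts as Poisson means; it is
  exact for UCOD and conservative relative to the Σw² option for MCOD.
* Analytic contrast intervals ignore the MCOD–UCOD correlation (use the
  bootstrap default when record-level data are available).
* Monthly denominators are population/12 regardless of month length.
* Imputation is single, so rate intervals ignore imputation uncertainty
  (negligible at registry missingness fractions, by measurement).
* Ill-defined deaths are excluded, not redistributed; where ill-defined
  certification is common, all cause-specific rates are understated.
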