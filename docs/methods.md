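# Methods

This note documents the models, conventions and numerical choices behind
burdenkit, and what the synthetic-data tests do and do not demonstrate.

## Cause list and code mapping

ICD-10-style codes are stored dot-stripped, upper-cased and truncated to at
most 4 characters; a cause's ranges are inclusive intervals at that
truncation length (so `I21–I25` contains `I25.9`). Range disjointness across
causes is enforced at load time by converting each inclusive endpoint to an
exclusive string bound and sweeping the sorted intervals, which makes lookup
a single binary search and code mapping a total, deterministic function.
Codes matching no range map to the reserved cause `_unmapped`, which is
carried through tabulations rather than dropped so that weight totals always
reconcile.

Ages are integer years 0–100 internally; banding to age groups happens only
at output, because YLL needs an exact-age life-table lookup. Sex is a
two-level code (`F`/`M`), matching the reporting dimensions of national
burden studies.

## Redistribution

Each death carries a fractional weight (1.0 on ingest). Redistribution
replaces a source-coded record by one record per target with weight
`w × p`, never by resampling, so conservation is exact up to float error and
results are reproducible without a seed. An optional stochastic mode (off by
default) samples a single target per record under an explicit seed; it
conserves weight per record and is byte-reproducible.

Method-specific choices:

* **Indirect MCOD eligibility.** The tally over deaths mentioning the target
  as an associated cause excludes records whose own underlying cause maps to
  any redistribution source or to `_unmapped`. This prevents ill-defined →
  ill-defined transfer and keeps the pattern interpretable; with disjoint
  specific causes it matches a naive double-loop count exactly (tested).
* **Empty pattern fallback.** If no record mentions the source, the weight
  falls back to proportional redistribution over the specific causes of the
  source's disease group (or over all specific causes when the group has
  none), using the current underlying-cause distribution as base, with a
  logged warning. An all-zero base falls back to a uniform split.
* **Cascades.** Direct-evidence tables may target other sources (unspecified
  cancer site → unknown primary → specific sites). Sources are processed in
  a topological order of the table-target graph; a cycle is a configuration
  error, not something iterated to a fixpoint, because an auditable pipeline
  needs a finite, explainable order.
* **Retention and the `settled` flag.** A direct table may keep a fraction on
  the source itself (the 'true' cancer-of-unknown-primary share). Retained
  records keep their original code and are marked `settled`: their
  certification has been reviewed and accepted, and they are exempt from any
  further redistribution. This is what makes the orchestrator idempotent —
  re-running on its own output moves no weight — while still leaving
  explicitly-retained weight on a source cause. The flag round-trips through
  the deaths CSV.
* **Representative codes.** A reassigned record receives the first code of
  the target cause's first ICD range; downstream stages only use the mapped
  cause id.
* **Audit report.** `redistributed_fraction` counts weight whose final cause
  class differs from its original class (so retained weight does not count,
  and weight moved twice through a cascade counts once);
  `within_group_fraction` is the share of that moved weight whose destination
  stays in the source's disease group; `method_shares` apportions the
  processed source weight across methods, counting a combination rule once
  under `combination`. Shares are by weight, the clearest single convention
  for a mixed count/weight notion.
* Proportional base distributions use the *current* (partially redistributed)
  underlying-cause weights at the time the rule runs; the processing order is
  deterministic, so so are the results.

## Burden accounting

YLL uses a single reference life table for both sexes with linear
interpolation between tabulated ages; ages beyond the table are errors, not
extrapolations. No age weighting, no discounting. YLD is prevalence-based:
prevalent persons × severity-level proportion × disability weight, summed
over each disease's sequelae; a prevalence row whose sequela belongs to no
model (or to two) is a configuration error. DALY = YLL + YLD is derived, not
stored, so additivity holds by construction; explicitly supplied DALY values
are validated against it at 1e-9 relative tolerance. No comorbidity
adjustment is applied across diseases.

HALE uses the Sullivan construction: `HALE(x) = Σ_{a≥x} nL_a (1 − r_a) / l_x`
with `r_a` the per-person morbidity (YLD per capita) at age `a`, taken from a
period life table (`lx`, `nLx`). Two identities pin the implementation down:
zero morbidity gives HALE = LE exactly, and constant morbidity d gives
HALE = (1 − d) × LE.

## Risk attribution

Exposures are categorical; continuous exposures are discretised by the
caller. RR must equal 1 at the theoretical-minimum category, which makes the
PAF denominator `Σ p·RR` directly comparable to the counterfactual value 1.
Negative (protective) PAFs are computed and warned about but excluded from
attributable totals; an optional floor can clip them. A configured
`direct_fraction` short-circuits the modelled PAF (direct evidence), but
scenario PIFs always use the exposure-response model, since a direct
fraction carries no counterfactual structure. Joint effects across risk
factors are out of scope.

## Quality index

Letters are encoded A=1…E=5 and combined by contribution-weighted mean with
half-up rounding (ties go to the worse letter) — the simplest monotone scheme
consistent with contribution weighting; worsening any source never improves
the combined letter, and the scheme is scale-free in contributions.
"Unable to be assigned" methods ratings are excluded from the mean with
weights renormalised; an entity with no assigned source stays unassigned and
is reported as its own band. Summary percentages are rounded half-up at one
decimal (the `decimal` module, not float rounding).

## Synthetic data

The generator emulates a national multiple-causes-of-death extract. Each
death draws a true cause (default scale: 10.5% of deaths garbled to an
ill-defined code, matching the order of magnitude a national study
redistributes), an age from a truncated normal (mean 78, sd 13, clipped to
0–100 — deaths in a high-income population cluster at old age), and a sex
(50/50). The multiple-cause structure is the modelling assumption that makes
the indirect MCOD method work and is stated explicitly: a death involving an
ill-defined condition is certified either with that condition underlying
(probability `garble_fraction`, the true cause surviving as an associated
mention with probability `assoc_mention_prob` = 0.9) or with the true cause
underlying and the condition mentioned as associated (probability
`source_mention_prob` = 0.25, independent of the true cause). Because the
mention probability is independent of cause, the underlying-cause pattern
among mentioners is an unbiased estimate of the garbled deaths' true-cause
distribution, and recovery succeeds to within multinomial sampling noise
(tested at n = 100,000 over 5 seeds, 3-standard-error band).

What this does **not** show about real data: real certification garbling is
not independent of cause, age or sex; real associated-cause mentions are
cause-correlated; prevalence draws (log-normal around configured medians)
have no age gradient or sex structure; and the shipped ~20-cause list and
demo disability weights are illustrative, not a published set. Passing tests
demonstrate the machinery is correct under its stated assumptions, not that
any particular national estimate is right.

The built-in life tables are synthetic and deterministic: a reference table
declining from 92 years remaining at birth to 2 at age 100 (the shape of the
aspirational standard tables burden studies use), and a period table from a
Gompertz hazard `μ(a) = 3e-5·e^{0.095a}` giving a life expectancy at birth of
about 79 years.

The quality-index fixture contains 194 single-source disease entities and 18
risk-factor entities whose band counts reproduce a published-style summary
table exactly; with single sources at contribution 1.0 the combined rating
equals the source rating, so the fixture pins down the summary and rendering
paths rather than the combination arithmetic (which its own tests cover).

## Problem sizes and tolerances

Closed-form checks assert at 1e-9 relative; conservation at 1e-9 relative;
oracle equivalence at 1e-12 on 200 random fixtures of up to 10,000 records;
parameter recovery at n = 100,000 × 5 seeds. The demo pipeline and the
results script use 20,000 deaths for burden accounting and 100,000 for the
recovery experiment — large enough that sampling noise is far inside the
asserted bands, small enough that the whole suite runs in well under a
minute on one core.

## Known limitations

* No uncertainty intervals anywhere; the quality index is the only
  reliability signal, by design.
* No DisMod-style internal-consistency modelling; prevalence is taken as
  given (or generated).
* The indirect MCOD tally is unstratified by age/sex by default; a
  stratified variant would need denser data than the demo scale provides.
* Age banding must tile 0–100 exactly; open-ended bands other than the
  terminal `N+` are not supported.
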