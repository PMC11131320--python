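# Methods

This note documents the models, rules and numerical choices behind
`pncattr`, in the order the pipeline applies them.

## Episode construction

A pregnancy episode is anchored on a delivery record. With gestational age
`g` months (input field, default 9 from `CodeConfig.default_gestation_months`),
the claim window is `[delivery_month − (g − 1), delivery_month]`, inclusive on
both ends, at **month granularity**. Claims data frequently release service
and delivery dates at month precision only, so month arithmetic is the native
resolution; day-precision dates are accepted, and month-precision input gets
day 15 with a recorded `day_imputed` flag so that within-window sequencing
operates on a total order. Whether delivery-day services in the delivery
month are themselves prenatal care is undecidable at month precision; the
window includes the delivery month and the question is left to the code
lists.

Episodes stay in the analytic cohort only when (a) the member's enrollment
spans cover every month of the window (adjacent spans union; a coverage gap
would masquerade as a care gap) and (b) at least one prenatal claim survives
the filters. Excluded episodes carry a reason code (`not_enrolled`,
`no_pnc`), and stage counts are written to the run manifest so cohort
attrition is auditable. When one member has overlapping windows, the later
delivery keeps the contested months (the earlier window is truncated, with a
warning); this situation is rare at realistic inter-birth intervals and any
rule here is a convention.

Estimating the month of birth itself (from delivery-associated diagnosis
codes) is out of scope: the pipeline starts from a dated delivery record.

## Prenatal-visit identification

A claim in the window is prenatal care iff its procedure code is in the
configured procedure list **or** its primary diagnosis starts with a
configured prefix, **and** its provider specialty is in the included
universe. The default specialty universe and grouping are: midwife (06),
primary care (12, 14, 19, 78), OB-GYN (16, 26, 27), organization — FQHC/RHC
(50, 97), nurse practitioner (86), other (02, 10, 40, 48, 57, 94, 95, PA),
plus a `missing` sentinel for blank specialties. The low-volume specialties
and PA are included by default (they can substitute for traditional prenatal
providers where access is limited) and a config switch can exclude or
regroup them. The diagnosis/procedure defaults (pregnancy-supervision
prefixes Z34/O09/V22/V23; global-obstetric, antepartum and prenatal-visit
procedure codes) are **documented placeholders**: every production study
should supply its own lists via the YAML config.

Providers are keyed by the specialty-specified provider identifier (SSPI),
`provider_id | specialty_code`, because a billing identifier may be shared
by professionals of different specialties.

Claims collapse to visits on `(SSPI, service_date)`: billing routinely
splits one encounter into several lines, so same-provider same-day lines are
one visit. Whether several same-month claims to one provider are one visit
or several cannot be resolved at month precision; at day precision distinct
dates count as distinct visits. Visits are ordered by `(date, SSPI)` with
dense sequence indices; when several providers share the earliest (or
latest) date, **all** of them carry the first (last) flag, and resolution is
deferred to the pattern tie-breaks.

## Classification

Definitions (per episode, `n` visits, provider `i` with `nᵢ` visits,
fraction `fᵢ = nᵢ/n`): Only (sole provider), Majority (`fᵢ > 1/2`, ≥ 2
providers), Plurality (unique maximum, `fᵢ ≤ 1/2`), MultPlur (≥ 2 providers
tied at the maximum), Other (below the maximum). Majority requires
*strictly* more than half: two providers at exactly one half each are
MultPlur, not Majority. MultPlur subtypes come from the endpoint flags:
InitialFinal ≻ Initial ≻ Final ≻ Neither; for rollup reporting the
InitialFinal episodes count inside the Initial column, since an InitialFinal
provider holds the first visit — this is also the only convention under
which the cumulative pattern percentages are additive.

Continuity of care uses the Bice–Boxerman index
`COC = (Σ nᵢ² − n)/(n(n − 1))`, defined as 1 when `n = 1`. The index is 0
exactly when every visit is with a different provider; that *dispersal* case
(`n_providers = n ≥ 2`) is flagged, and no predominant provider is attributed
to it under any pattern — its first/last visits carry no meaningful sequence
information.

Patterns 1–6 select the predominant provider cumulatively: Only; +Majority;
+Plurality; +MultPlur with the first visit; +MultPlur with the last visit;
+MultPlur with first or last, first-visit holder preferred (prenatal-care
adequacy measurement weights initiation, hence the Initial priority).
Residual ties — e.g. two tied-maximum providers both seen on the first day —
are broken deterministically by earliest visit date, then lexicographic
SSPI, and logged; they only arise with sub-month date detail.

By construction the identified sets are nested (1 ⊆ 2 ⊆ 3 ⊆ 4 ⊆ 6 and
3 ⊆ 5 ⊆ 6) and at most one provider is returned per episode and pattern.

## Summary tables and tests

Visit-count strata are `=1`, `2–8`, `9–14`, `>14` (cut points 1, 8, 14,
configurable), reflecting expected prenatal schedules. The reporting surface
comprises: visit-count N/mean/SD and stratum percentages at the pregnancy
and pregnancy-provider levels; the category percentage table with MultPlur
subtype shares and the distribution of the number of tied-maximum providers;
a stratum × category crosstab of episode percentages under pattern-6
attribution (cells are mutually exclusive — Only, Majority, Plurality,
MultPlur_Initial, MultPlur_Final, MultPlur_InitialFinal, Dispersal,
NoPredominant — and sum to 100); and the cumulative pattern rollup
`p1 = Only`, `p2 = p1 + Majority`, `p3 = p2 + Plurality`,
`p4 = p3 + Initial`, `p5 = p3 + Final`, `p6 = p3 + Initial + Final` (with
Initial including InitialFinal). Note that under these definitional rules
`p5 = p3 + Final` — the pattern-5 figure published for the motivating cohort
(88.40) is not additive from its own category row (81.44 + 3.06 = 84.50);
the package implements the definition and does not attempt to
reverse-engineer that figure. The published category row itself shows small
internal inconsistencies (MultPlur_Final printed as 3.05 in one table and
3.06 in another; subtype subtotals that do not sum to the MultPlur total);
where a single value is needed this package's worked example uses 3.06, the
value under which the pattern-4/6 rollups are exactly additive.

Chi-square screens compare each category against the Majority reference:
the 2×2 table crosses category-vs-Majority with one stratum vs the rest,
Pearson statistic without continuity correction, df = 1 (computed via
`scipy.stats.chi2_contingency`; the suite cross-checks it against the
textbook closed form `N(ad − bc)²/((a+b)(c+d)(a+c)(b+d))` to 1e−9). This
2×2 construction is one plausible reading of "given the total number of
visits"; others exist, so the significance stars are reported but not
treated as a validation surface. No multiple-testing adjustment is applied.
The paired t utility returns the mean difference, 95% t-interval, t, df and
two-sided p; zero-variance inputs are flagged degenerate (t = 0 when the
mean is also 0).

Percentages are rounded only at report serialization, never internally.

## Travel distance

Distances are zip-centroid to zip-centroid great-circle (haversine) miles
with mean Earth radius 3958.8 mi. Same-zip pairs use the equal-area radius
`r = √(area/π)` from the gazetteer's land area — zero would understate
within-zip travel, especially in large rural zips. Great-circle distance
systematically undershoots road distance; it preserves ordering and the sign
of the nearest-vs-predominant difference, which is the quantity of interest.
Zip-to-ZCTA harmonization is assumed done upstream; an `in_state` flag on
the gazetteer supports restricting the comparison to in-state residences and
providers.

The nearest provider is defined under two scopes, because "nearest" is
ambiguous: `visited` (the episode's own providers — the default) and
`all_cohort_providers` (every provider billing at least one prenatal visit
in the cohort). With the `visited` scope the predominant provider is in the
candidate set, so nearest ≤ predominant for every included episode and the
paired mean difference is non-positive by construction; the all-providers
scope can only move the nearest closer. Episodes without an identified
predominant provider (or with unknown/out-of-state zips when filtering) are
excluded and counted.

## Synthetic cohort generator

The generator plants each episode into one of eight regimes and builds a
visit layout that *guarantees* the intended classification: `only` (one
provider), `majority` (one provider with ⌊n/2⌋+1 visits), `plurality`
(unique maximum at ≤ n/2), `multplur_initial` / `multplur_final` /
`multplur_initialfinal` (two providers tied at `m = clamp(n/3, 2, ·)` visits
with the labelled one holding the required endpoints; for the `final` regime
a single-visit filler takes the first date so no tied provider holds it),
`dispersal` (n providers, n visits), and `other_dominant` (two tied
providers holding neither endpoint — no predominant identifiable even with
sequence information). Ground-truth labels (regime, expected pattern-6
SSPI, visit and provider counts, enrollment status) make the generator an
exact oracle for the classifier.

Defaults encode the composition reported for a large state Medicaid
pregnancy cohort: regime mix 28.40% only, 19.55% majority, 33.49% plurality,
5.89% / 3.05% / 1.42% tied-plurality initial/final/both, 7.12% dispersal,
1.08% other-dominant (the exclusive-category decomposition of the published
percentages), and visit-stratum weights 6.18 / 48.99 / 40.22 / 4.62% for
=1 / 2–8 / 9–14 / >14 visits. Visit counts are uniform within a stratum,
clipped below by each regime's feasibility floor (a majority layout needs
≥ 3 visits, a no-predominant layout ≥ 6, etc.); infeasible combinations of
regime and strata raise a configuration error. Specialties, zip centroids
(a southeastern-US coordinate box with a few out-of-state entries),
land areas (log-normal, ≈ 20 sq mi median) and residence zips are drawn
from configurable mixes; the enrollment-gap rate (default 0.1) punches
one-month coverage holes to exercise the funnel.

Randomness is hierarchical — a global stream for the provider pool and
gazetteer, one child stream per episode keyed by `(seed, episode index)` —
so enlarging a cohort never reshuffles existing episodes, and equal seeds
give byte-identical outputs.

A noise stage adds only *filterable* perturbations (duplicate claim lines,
out-of-window claims, non-prenatal claims with blank or excluded
specialties) so planted labels remain valid; this is deliberate, as the
point is to test the filters, not to model miscoding. What the generator
does **not** emulate: real billing-code distributions, within-month visit
clustering, provider referral networks, multi-payer churn, or genuinely
ambiguous episodes whose true predominant provider is unknowable — passing
recovery tests therefore demonstrates algorithmic correctness on separable
cases, not measurement validity on real claims.

## Problem sizes

The bundled verification surface uses a 5,000-episode cohort for exact
planted-label recovery, 10,000 random episodes (≤ 6 providers, ≤ 20 visits)
for brute-force category-oracle agreement, 50 random scenario mixes of 60
episodes for the nesting property, all visit-count partitions up to n = 8
for the continuity/dispersal equivalence, and 100-case random batches for
the statistic oracles — sizes at which the checks are exhaustive or the
binomial error is far below the thresholds being verified.

## Known limitations

* Month-precision inputs make the first/last visit partially conventional;
  all date ties are flagged rather than resolved silently.
* The prenatal code lists are placeholders; results on real data are only
  as good as the configured lists.
* Professionals sharing one billing identifier *and* specialty cannot be
  separated — attribution rates on such data are upper bounds.
* Great-circle distances understate road travel; only ordering and sign
  should be interpreted.
* The dispersal group (no attributable provider) is excluded by design;
  alternative rules for it are an open research question.
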