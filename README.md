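# pncattr

**Predominant prenatal-care provider attribution from insurance-claims data.**

Knowing which provider is a pregnant person's *predominant* source of prenatal
care (PNC) is a prerequisite for studying access, travel burden, continuity of
care and outcomes — but claims data never state it. Classic claims algorithms
attribute the provider with the most visits (*plurality*) or more than half of
them (*majority*), and fail whenever several providers tie at the top.
`pncattr` implements an attribution algorithm for prenatal care that breaks
those ties with **visit-sequence information** — who gave the first and the
last prenatal visit — which matters in this setting because adequacy indices
for prenatal care weight the timing of initiation heavily.

The package is aimed at health-services researchers working with Medicaid or
commercial claims: it builds pregnancy episodes, identifies prenatal visits,
attributes a predominant provider under six nested identification patterns,
reproduces the standard cohort summary tables and significance screens, and
compares travel distance to the predominant versus the nearest provider.
A fully labelled synthetic-claims generator makes every stage testable without
access to restricted claims data.

## The algorithm

For one pregnancy with `n` prenatal visits, provider *i* with `nᵢ` visits has
fraction `fᵢ = nᵢ / n`. Providers are categorized:

| Category | Definition |
|---|---|
| Only | the sole provider (`fᵢ = 1`) |
| Majority | `fᵢ > 1/2`, ≥ 2 providers |
| Plurality | unique largest fraction, `fᵢ ≤ 1/2` |
| MultPlur | ≥ 2 providers tied at the largest fraction |
| Other | any provider below the maximum |

A MultPlur provider is subtyped *Initial* / *Final* / *InitialFinal* by
whether it gave the episode's first visit, last visit, or both. Visit
concentration is the Bice–Boxerman continuity-of-care index
`COC = (Σ nᵢ² − n) / (n (n − 1))`; `COC = 0` exactly when every visit is with
a different provider (*dispersal*), in which case first/last visits carry no
signal and no predominant provider is attributed.

Six nested patterns select the predominant provider:

1. Only; 2. + Majority; 3. + Plurality; 4. + MultPlur_Initial;
5. + MultPlur_Final; 6. + MultPlur holding first **or** last visit, with
priority to the first-visit holder.

Providers are keyed by the **specialty-specified provider identifier (SSPI)**
— billing identifier ⊕ specialty code — because one billing identifier can be
shared by professionals of different specialties.

## Worked example

```python
from pncattr import ScenarioConfig, generate_cohort, run_cohort, compare_distances
from pncattr.stats import frequency_crosstab, crosstab_to_percent_row, pattern_rollup

cohort = generate_cohort(ScenarioConfig(n_episodes=2000, seed=1))
result = run_cohort(cohort.claims, cohort.enrollment, cohort.deliveries)
print(result.stage_counts)

xtab = frequency_crosstab(result.classifications, result.profiles_by_episode)
rollup = pattern_rollup(crosstab_to_percent_row(xtab))
print({k: round(v, 2) for k, v in rollup.as_dict().items()})

cmp_ = compare_distances(result.classifications, result.visited_sspis(),
                         cohort.provider_zips, cohort.residence_zips, cohort.gazetteer)
print(f"nearest {cmp_.mean_nearest:.1f} mi vs predominant {cmp_.mean_predominant:.1f} mi "
      f"(diff {cmp_.test.mean_diff:.1f}, p={cmp_.test.p:.3g})")
```

Output:

```
{'claims_total': 17046, 'claims_in_window': 17046, 'claims_pnc': 17046,
 'pnc_visits': 15247, 'episodes_total': 2000, 'episodes_kept': 1789}
{1: 27.22, 2: 46.62, 3: 79.82, 4: 88.93, 5: 82.95, 6: 92.06}
nearest 86.8 mi vs predominant 117.9 mi (diff -31.1, p=9.23e-126)
```

Reading this: of 2,000 simulated pregnancies, 1,789 survive the
continuous-enrollment filter. Frequency information alone attributes a
predominant provider to 79.8% of them (patterns 1–3); adding sequence
information raises that to 92.1% (pattern 6) — the gain the algorithm
exists for. The remainder are dispersal episodes plus a small residue of
tied-plurality episodes whose tied providers hold neither endpoint. The mean
travel distance to the nearest *visited* provider is necessarily no larger
than to the predominant one, so the paired difference is negative.

The same pipeline runs from the shell:

```bash
pncattr all --out-dir out --seed 1 --n-episodes 2000
pncattr distance --out-dir out --pattern 6 --scope visited
```

Stage subcommands (`simulate`, `episodes`, `identify`, `classify`,
`summarize`, `distance`) read and write delimited text tables in `--out-dir`,
and a JSON manifest records the config digest, seed and the cohort attrition
funnel.

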