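# fgmc

Indirect estimation of female genital mutilation/cutting (FGM/C) prevalence
and risk in a diaspora population, from population-register data and
origin-country survey rates.

## What it does and for whom

Health planners need to know how many women in a host country have already
been subjected to FGM/C (and how many to its severest form, infibulation),
and child-protection agencies need to know how many girls are at risk.
Neither can be surveyed directly. This package implements the standard
indirect alternative used by register-based national studies in Europe: it
classifies every first- and second-generation female immigrant from the 29
countries where FGM/C is concentrated into analysis groups — by generation,
age at arrival relative to the origin country's customary cutting-age
window, and age at a reference date — and extrapolates the origin country's
DHS/MICS prevalence onto the matching groups.

The core quantities, per origin country with counts `N_1a` (arrived past the
customary window), `N_1b`, `N_1c` (arrived at/below it, still minors),
`N_2a` (second generation, under 18), and prevalences `p49`/`p19` for the
15–49 and 15–19 survey cohorts:

```
undergone            = N_1a × p49
potentially at risk  = N_1b + N_1c + N_2a          (no prevalence applied)
at risk (factor f)   = (N_1b + N_1c + (1−f)·N_2a) × p19
```

`f` is the migration-and-acculturation impact factor for the second
generation: `f = 1` gives the low-risk scenario, `f = 0` the high-risk
scenario, and any value between is accepted for sensitivity analysis.
Type-III (infibulation) splits apply the cohort-matched survey shares.
Published output is disclosure-safe: cells of 1–9 are suppressed and
countries with fewer than 20 residents are pooled, while totals stay exact.

Because register microdata is confidential, the package includes a seeded
synthetic-register generator whose marginal mode constructs birth and
arrival dates such that classification reproduces requested per-country
group counts *exactly* — so the full microdata pipeline can be exercised,
tested and demonstrated without any real data. See `docs/methods.md` for
the model's assumptions and limitations.

## Worked example

The packaged data (`fgmc/data/`) carries the survey reference table for the
29 countries and the published 2013 register group counts for Norway
(suppressed cells reconstructed from the printed margins; see the file
headers). Running the whole pipeline on it:

```
$ fgmc run-all --counts-input src/fgmc/data/group_counts_2013.csv --out-dir reports
{
  "population": 44472,
  "undergone_total": 17283,
  "undergone_share": 0.3886265515380464,
  "undergone_share_pct": "38.9 %",
  "undergone_type3_total": 9129,
  "type3_share_of_undergone": 0.5282069085228259,
  "type3_share_of_undergone_pct": "52.8 %",
  "potentially_at_risk_total": 15543,
  "risk_low_total": 3006,
  "risk_high_total": 7932,
  "risk_low_type3_total": 1841,
  "risk_high_type3_total": 4812,
  "type3_share_of_risk_low": 0.6124417831004657,
  "type3_share_of_risk_high": 0.6066565809379728
}
```

Reading: of 44,472 resident women and girls originating in the 29 countries,
about 17,300 (38.9 %) are estimated to have undergone FGM/C before
migration, roughly half of them (9,129) infibulated — the population in
potential need of specialised care. 15,543 girls are potentially at risk and
should be covered by universal preventive measures; of these, between about
3,000 (low scenario) and 7,900 (high scenario) are estimated to be actually
at risk, around 61 % of them at risk of infibulation.

`reports/` then contains the six disclosure-safe tables
(`group_counts.csv`, `undergone.csv`, `undergone_types.csv`,
`potentially_at_risk.csv`, `risk_scenarios.csv`, `risk_types.csv`), e.g.:

```
$ head -6 reports/undergone.csv
country;undergone
Cameroon;:
Côte d'Ivoire;38
Djibouti;28
Egypt;197
Eritrea;3999
```

plus `summary.json` and a `manifest.json` recording configuration and input
digests. The same analysis is available as a library
(`fgmc.estimate_all`, `fgmc.national_summary`, `fgmc.run_pipeline`), and the
microdata path as `fgmc generate` → `fgmc classify` → `fgmc report`.

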