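# Methods

## The estimation problem

Direct, survey-based measurement of female genital mutilation/cutting
(FGM/C) in a diaspora population is rarely feasible: the affected groups are
minorities, sampling them is expensive, and asking is ethically fraught. The
standard indirect approach — implemented here — extrapolates origin-country
survey rates (DHS/MICS) onto the resident immigrant population recorded in a
national population register. The package computes, for a register of
first- and second-generation female immigrants from the 29 countries where
FGM/C is concentrated:

1. how many have most likely already undergone FGM/C (a health-care planning
   quantity),
2. how many girls are *potentially at risk* (the target of universal
   preventive measures), and
3. how many girls are *at risk* under a low and a high migration scenario,

each with a type-III (infibulation) split, since infibulation carries the
heaviest health-care needs.

## Cohort classification

Classification uses three quantities per person: completed years at arrival
`a_arr`, completed years at the reference date `a_ref`, and the origin
country's customary cutting-age window `[c_min, c_max]`. The upper margin of
the window is the cut-off. First generation:

| group | rule | role |
|-------|------|------|
| 1a | `a_arr > c_max` | assumed cut in proportion to the 15–49 prevalence |
| 1c | `a_arr ≤ c_max` and `a_ref ≤ c_max` | potentially at risk |
| 1b | `a_arr ≤ c_max` and `c_max < a_ref < 18` | potentially at risk |
| 1x | `a_arr ≤ c_max` and `a_ref ≥ 18` | residual: assumed uncut, not at risk |

Second generation (both parents from listed countries; mixed-listed parents
attribute to the mother's country): `2a` if `a_ref < 18`, else `2b`. Girls
with fewer than two parents from listed countries, and first-generation
women from unlisted countries, are excluded from every table but reported as
an excluded bucket.

The model's key behavioural assumption is **no cutting after migration**:
group 1x and the second generation contribute nothing to the undergone
estimate. The residual group 1x is carried explicitly rather than silently
merged; `GroupCounts.fold_g1x_into_g1a()` exists for compatibility with
five-group published layouts, but folding is never the default because 1x
women are assumed *uncut*, unlike 1a.

Ages are birthday-based completed years (the anniversary day counts as
attained; "under 18" means the 18th birthday has not occurred). A
calendar-year mode (`age = reference_year − birth_year`) is available via
`age_mode="calendar"` because register statistics sometimes publish
year-resolution ages; it is not the default.

A structural corner: when a window reaches 17 or 18 (Sierra Leone, Uganda),
no age is simultaneously past the window and under 18, so group 1b is empty
by construction under the strict rule. Published tables that show 1b counts
for such countries must have used a looser rule; all estimates here depend
on 1b and 1c only through their sum, so the ambiguity does not propagate to
any reported quantity.

## Estimators

With per-country counts `N_1a, N_1b, N_1c, N_2a` and prevalences
`p49, p19`:

* undergone: `N_1a × p49`;
* potentially at risk: `N_1b + N_1c + N_2a` (no prevalence — identification
  of individuals is impossible, so prevention must target the whole group);
* at risk with second-generation migration-and-acculturation impact factor
  `f ∈ [0,1]`: `(N_1b + N_1c + (1−f)·N_2a) × p19`. `f = 1` is the low
  scenario (migration eliminates second-generation risk), `f = 0` the high
  scenario (risk as in the origin country). The binary factor is the
  established convention; the implementation accepts any value in `[0,1]`
  as a continuous sensitivity dial (`ScenarioConfig.scenarios`).

Type-III splits multiply the *unrounded* base by the cohort-matched
infibulation share (15–49 for undergone, 15–19 for risk). Four countries
(Iraq, Liberia, Uganda, Yemen) lack typology data; their share is stored as
0 with an `assumed_zero` flag so tables can distinguish assumed from
measured zeros.

### Rounding and split conventions

Per-country estimates are rounded half-away-from-zero (half-even is
available; exact .5 ties do not occur with three-decimal prevalences, so the
choice is cosmetic on real inputs). National totals are sums of the rounded
per-country values.

Two split conventions are deliberate and distinct:

* **undergone split (complement)** — type III is rounded from the unrounded
  base and "other" is the rounded total minus type III, so the pair sums
  exactly to the published total;
* **risk split (independent)** — both halves are rounded independently from
  the unrounded base, so the pair may miss the rounded scenario total by
  one.

These mirror the arithmetic observable in the published tables this package
reproduces; both are fixed defaults rather than knobs because changing them
silently changes cell-level reproducibility.

## Disclosure control

Counts between 1 and 9 inclusive are suppressed (marker `:`; zero is
information-free and printed). Totals are computed before suppression and
printed exactly, so visible cells intentionally do not sum to totals.
Countries with fewer than 20 residents in total are pooled into an "Other
countries" row; pool membership is decided on counts, but estimates are
computed per constituent with its own prevalence and then summed, so pooling
never changes a national total.

## Packaged reference data

`country_reference.csv` transcribes the survey inputs for the 29 countries
(prevalence 15–49 and 15–19, customary window, type-III shares, source
survey). `group_counts_2013.csv` carries the published 2013 register group
counts. The published counts table suppresses small cells; most are uniquely
recoverable from its printed row and column margins and are restored
exactly. The remaining few (three countries' 1b:1c splits, and the
per-country breakdown of the pooled small-country row) are synthetic
allocations chosen once to satisfy the printed margins — the file header
says so. The printed margins are themselves not perfectly mutually
consistent (they disagree by 12 persons spread over suppressed cells of the
2b column and the pooled row); the reconstruction preserves the four margins
that drive every estimate (1a, 1b, 1c, 2a) exactly, leaving the grand total
44,472 rather than the published 44,467 (0.01%, invisible at one-decimal
percent precision).

## Synthetic register generation

The register microdata itself is confidential, so `synthetic_register`
emulates it. In marginal mode the generator inverts the classifier: for each
requested (country, group, count) it draws target ages inside the interval
that defines the group, then constructs birth and arrival dates attaining
exactly those completed-years ages at the reference date (dates are
validated by recomputation, so leap-day arithmetic cannot leak a record
across a group boundary). Classifying the output therefore reproduces the
requested counts exactly, for any seed — this round trip is used as an
oracle throughout the test suite. In rates mode, group counts are multinomial
draws over caller-supplied probabilities, then constructed the same way.

What the generator does *not* emulate: realistic arrival-cohort waves,
family structure, within-family correlation, or mixed-origin parents beyond
what a test constructs explicitly. Passing tests therefore demonstrate the
correctness of classification and estimation arithmetic on
structurally-valid registers, not the demographic realism of any synthetic
population.

## Problem sizes and numerics

The full national analysis is 29 countries × 6 groups — estimation is
instantaneous. Property tests run the generator→classifier round trip on
randomized specs of a few dozen records per country and a 10,000-record
partition check; the whole suite completes in a few seconds. All arithmetic
is double-precision; the only rounding is the deliberate person-count
rounding described above.

## Known limitations

* National prevalence obscures ethnic/regional heterogeneity (e.g. a
  country's national rate may be several times lower than that of the
  sub-population actually represented in the diaspora); no region
  re-weighting is attempted.
* Migrant selection (younger, wealthier, more educated migrants have lower
  FGM/C prevalence) is not adjusted for.
* Point estimates only: the survey inputs carry sampling error the model
  does not propagate, and typology data are known to under-report
  infibulation.
* The binary impact factor brackets, rather than models, post-migration
  attitude change; the continuous factor is exposed precisely so sensitivity
  to this assumption can be explored.
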