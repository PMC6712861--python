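# Methods

## The data model

A `TrialRecord` types the fields of a CTRI registration that the audit
reads: the registration number and date; the *Type of Study* (stored by
CTRI as an undelimited concatenation of ticked category labels); the *Type
of Trial* (Observational / Interventional / PMS / BA/BE); the *Phase*
(Phase 1 … Phase 4, the split phases, N/A, PMS); the *Countries of
Recruitment*; the global/India recruitment-status, first-enrollment-date
and sample-size field pairs; the principal investigator (PI), primary
sponsor name and classification; the trial sites (institution, city,
state, country); and the ethics committees (name, affiliation, address).
Fields the audit does not read are carried verbatim in an `extras` map.

Two representational rules matter throughout:

* **Inconsistency is data.** An Interventional trial whose Phase is PMS is
  stored exactly as such; the parser never "fixes" records, because the
  contradictions are what the audit measures.
* **Missing is a token list, not just NULL.** The default missing tokens
  are the empty/whitespace string and case-insensitive
  `nil`, `na`, `n/a`, `not available`. `"Not applicable"` is *not* missing
  for the two recruitment-status fields — it is meaningful there (it is one
  leg of the truly-foreign test) — and for Phase, `N/A` is an explicit
  enumeration value distinct from an absent entry.

**Type of Study tokenization.** Because CTRI stores multi-selections as
run-on concatenations (`DrugAyurveda`, `DrugSurgical/Anesthesia`), the raw
string is decomposed by longest-match, left-to-right scanning against the
18-category vocabulary; each maximal unmatched run becomes a single
`Other:<residue>` token. The vocabulary ships with the package (the
registry's own category list is not public in machine-readable form; the
bundled list contains every category the audited deficiency classes rely
on) and is configurable. A trial is a *drug trial* iff its token list is
exactly `["Drug"]` — combinations that merely include Drug are their own
categories.

**Dates** parse permissively (ISO and day-first dialects via dateutil);
unparseable non-missing text is kept as missing with a logged warning.

## Scope classification and the unambiguity filter

The country list alone fixes the scope class:

| countries                 | scope          |
|---------------------------|----------------|
| exactly {India}           | Indian         |
| India plus ≥1 other       | Multinational  |
| non-empty, no India       | Foreign        |
| empty                     | Unclassifiable |

Three further field pairs must corroborate the class. For an Indian record
the flags are: India recruitment status missing or "Not applicable"
(`IN-STATUS`); India first-enrollment date missing (`IN-DATE`); India
sample size missing or zero (`IN-SIZE`); total ≠ India sample size
(`IN-SIZE-MISMATCH`); a global first-enrollment date present and different
from the India date (`IN-GDATE` — an *equal* global date is tolerated).
For a Multinational record: global or India status missing/"Not
applicable" (`MN-GSTATUS`, `MN-ISTATUS`); global date missing
(`MN-GDATE`); total sample size missing or zero (`MN-GSIZE`); India sample
size exceeding the total (`MN-ISIZE-EXCESS`). A record is **unambiguous**
iff it raises no flag. `MN-IDATE` (India enrollment date missing for a
Multinational record) is computed but excluded from the default verdict —
a missing India date alone does not contradict a multinational scope — and
can be enabled via `AuditConfig(include_mn_idate=True)`.

This flag catalogue is this package's normative definition of the filter;
it is deliberately expressed as independent, literal field comparisons so
it can be re-derived by inspection (and is, in the test-suite oracle).

A Foreign-listed record is **truly foreign** iff all three hold: the
global recruitment status is real data while the India status is "Not
applicable"; a global first-enrollment date exists while the India date
does not; and the total sample size is positive while the India sample
size is nil or zero.

## The deficiency rules

All rules are pure functions of one record; the dispatcher's output is the
union of the individual rules, sorted by rule id.

* `R-SCOPE` — an Indian/Multinational record raising ≥1 ambiguity flag.
* `R-INT-PMSPHASE` — Interventional type with Phase PMS.
* `R-PMS-PH4` — PMS type with Phase 4. (CTRI defines postmarketing
  surveillance and Phase 4 as mutually exclusive study descriptions.)
* `R-BABE-PHASE` — BA/BE (bioavailability/bioequivalence) type carrying
  any numbered phase (1, 1/2, 2, 2/3, 3, 3/4, 4).
* `R-TOSNA-PHASE` — Type of Study absent but a numbered phase listed.
* `R-PI-NIL`, `R-SPONSOR-NIL` — PI or sponsor name is a missing token.
* `R-STATE-NIL` — some site lacks its state.
* `R-CITY` — some site city is structurally invalid: missing, shorter than
  two characters, or containing digits. Registries never publish a
  definition of an "incorrectly listed" city, so the default check is the
  dataset-independent structural subset; matching against the bundled
  Indian city gazetteer is opt-in (`strict_city`). With different
  criteria, absolute city-error rates are expected to differ.
* `R-EC-EXCESS` — more ethics committees than sites.
* `R-EC-FOREIGN` — a committee whose name/affiliation/address contains a
  non-India country token (whole-word, case-insensitive, against the
  bundled country lexicon; ambiguous tokens such as "Georgia" sit on a
  configurable denylist).
* `R-EC-UNIDENT` — a committee with neither affiliation nor address.
  Reported as a finding but excluded from the quantified rate series: it
  flags an identification problem rather than a countable error, and no
  reference rates exist for it.

## Cohorts and the temporal series

Registration dates fall into four bins — 2007–2009, 2010–2012, 2013–2015
and 2016–2018 with the last bin ending 2018-04-04 (exclusive), the
snapshot date the audit is modelled on. Records outside the bins (or with
no registration date) are counted in an out-of-range remainder, never
silently dropped.

Cohort denominators follow the data-processing funnel:

* `R-SCOPE` series: all Indian (resp. Multinational) drug trials.
* Type/phase and completeness series: the unambiguous Interventional
  cohort of the respective scope (drug trials → scope → unambiguous →
  Interventional).
* Redefined cohorts replace the final type filter: the redefined PMS
  cohort is the PMS branch of the unambiguous Indian drug funnel; the
  redefined BA/BE and Type-of-Study-missing cohorts start from **all**
  records (a record without a Type of Study cannot pass the Drug filter),
  then apply the scope and unambiguity filters and the alternative type
  filter.

Each cell reports `(numerator, denominator, rate)` with
`rate = 100·num/den` rounded **half-up** to one decimal (`Decimal`
arithmetic, so rendered values re-parse exactly); zero-denominator bins
are empty cells, never division errors. Printed shares ("85% of 2070")
round half-up to whole percent, and rendered rates strip a trailing `.0`
("3", "0.9").

**Category explosion.** Two complementary series quantify the growth of
Type of Study categories: `category_ratio_series` (distinct raw strings in
a bin as a percentage of the bin's records) and
`category_first_appearance_series` (the share of all distinct categories
first appearing in each bin; the four shares sum to ~100). The second is
the one reported by the acceptance script, since it is the reading under
which a category list can grow several-fold across periods without ever
exceeding its own total.

Every rate is a binomial proportion, so `AuditResults` attaches Wilson
score intervals (via statsmodels) rather than Wald intervals: several
cells have small numerators, where Wald intervals collapse.

## The name-variant matching ladder

Normalization case-folds, removes punctuation, splits run-on tokens at
lower→upper camel boundaries (`DrRameshB` → `dr`, `ramesh`, `b`; known
mixed-case degree abbreviations like `PhD` stay atomic), and strips —
but records — leading honorifics (`dr`, `prof`, `mr`, …) and trailing
degree suffixes (`md`, `phd`, `mbbs`, …). Two normalized names are judged
same-person by the first rung that accepts them:

1. identical token sequences → surface categories (CAPITALS / SPACING /
   EXTRANEOUS) attributed from what normalization removed;
2. identical once spaces are removed → SPACING;
3. identical token multiset → ORDERING;
4. positionally aligned with token↔initial matches → ABBREVIATION; with
   one *interior* token absent → MIDDLE_NAME. The absent token must be
   interior: a missing "middle name" is never the leading given name or
   the trailing surname, and dropping surnames would conflate distinct
   people (`Meena B Qureshi` vs `Meena Bhattacharya`);
5. per-token or whole-string restricted Damerau–Levenshtein distance
   ≤ `max_edit` (default 2) → SPELLING;

otherwise DISTINCT. The relation is symmetric; clusters are its connected
components, with the longest member as representative. The ladder is a
deliberate design choice over a single string-similarity score: each rung
maps one-to-one onto an observed variation category, so every merge is
explainable.

Sponsor names go through the same ladder after corporate-suffix stripping
(trailing runs of `pvt`, `ltd`, `limited`, `inc`, `corp`, `india`,
`private`, …), and a classification conflict is reported for every
cluster whose member records carry ≥2 distinct sponsor classifications.

Known limitation: two individuals genuinely sharing a name are merged.
Registry data cannot resolve this without persistent person identifiers
(ORCID-style); it is an acknowledged false-positive mode, not a bug.

The restricted Damerau–Levenshtein implementation is local
(`_strdist.py`): the matcher needs adjacent-transposition support, which
the installed edit-distance libraries (plain Levenshtein) do not provide.

## The synthetic registry

`generate_registry(SyntheticConfig(...))` builds records in two stages:

1. **Clean templates.** Each record is internally consistent for its kind:
   Indian records carry the India-side status/date/size triple with the
   total mirroring the India sample size and the global pair inactive;
   Multinational records populate both sides with India ≤ total; Foreign
   records satisfy the truly-foreign triple; a no-country kind emulates the
   record with an empty country list. Sites are Indian institutions with
   gazetteer cities and states; each site brings exactly one ethics
   committee with affiliation and address. PIs are drawn from a pool of
   distinct identities and rendered either canonically or as one of a few
   precomputed variant spellings; sponsors likewise, with an optional
   alternate classification.
2. **Error injection.** Independently per record and rule, with
   probabilities configurable per rule, per scope and per bin
   (`"R-PI-NIL/Indian": {"P1": 0.103, ...}`). Injection independence makes
   the binomial oracle exact: the audited rate of a rule over its cohort
   is a binomial proportion around the injected probability, with the
   caveat that scope-ambiguity injection shrinks downstream cohort
   denominators (rates remain unbiased; counts do not). A positive
   injection probability with no applicable records (e.g. `R-PMS-PH4`
   in a registry with no PMS-type trials) is a configuration error.

Identical config + seed yields identical output (a single `random.Random`
stream in fixed generation order).

**Default study conditions.** The defaults reproduce the April-2018
snapshot this audit is modelled on: 12,673 records over bins
350/2800/3500/6023 (a reconstruction of the registry's growth curve);
drug fraction 2732/12,673; scope mix 2070/640/21/1 among drug trials;
Interventional fractions 1655/1764 (Indian) and 606/609 (Multinational);
and the observed per-bin deficiency rates as injection probabilities.
Record counts are apportioned deterministically (largest remainder):
exact kind totals first, then each kind spread over bins by its weight
profile. Drug cohorts are skewed toward the early bins
(`kind_bin_weights`), the unique shape under which the per-bin ambiguity
rates integrate to the overall unambiguity counts — early CTRI
registrations were dominated by drug trials.

**PI identity sampling.** Synthetic PI identities draw surnames without
replacement from a bundled list that is pairwise at edit distance ≥ 3
(property-tested), so no two generated identities can be conflated by any
rung at `max_edit = 2`. The generator therefore measures the matcher's
recovery of *distinguishable* people; the shared-name limitation above is
out of its scope by construction.

**What the generator does not emulate.** Medical content (conditions,
interventions, realistic titles); the live registry's HTML layout (the
fixture dialect is this package's own, round-trip-tested); free-text chaos
beyond the injected classes (e.g. city names misspelled rather than
structurally invalid); Foreign-listed records that hide India recruitment;
correlated errors (real registrant mistakes likely cluster by submitter,
which would widen rate variances relative to the binomial model). Passing
tests on synthetic data therefore demonstrate that the pipeline measures
what it claims under the stated error model — not that real-registry error
rates will match any particular value.

## Numerical and testing choices

* Rounding is half-up everywhere a rate or share is printed, via
  `decimal.Decimal`; float formatting never feeds back into computation.
* Rate-recovery tests compare an audited cell against its injected rate
  within `3·sqrt(p(1-p)/n)·100` percentage points, where `n` is the
  cell's realized denominator — the exact binomial three-sigma band under
  the injection model.
* Test problem sizes: registries of 600–4000 records for unit/property
  tests, 12,673 for the snapshot funnel, 20 seeds × 4000 records per
  injection level for rate recovery, 100 seeds × 100 names for
  name-recovery — sizes at which binomial bands are tight enough to be
  informative while the full suite runs in about a minute.
* The rule engine and scope filter are verified against independent
  brute-force oracles written as literal field comparisons; clustering is
  verified against Floyd–Warshall transitive closure.
* Degenerate inputs: empty registries yield structurally complete reports
  with empty cells; records with missing registration dates are counted
  out-of-range; `cluster_names` of an empty list is a contract violation
  (callers gate on missing-name findings first).
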