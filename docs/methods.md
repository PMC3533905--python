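# Methods

## Scope

`perilink` models the linkage of a statutory birth-registration stream
(one record per infant born, carrying both maternal and infant
identifiers and pregnancy variables) to a hospital discharge stream (the
mother's delivery admission and the infant's birth admission), in the
style of an Australian state linkage unit: blocked candidate generation,
clue-based maximum-entropy scoring, dual decision thresholds with a
clerical review band, one-to-one assignment, admission identification
from ICD-10-AM/ACHI codes, six linkage groups, and rate/quality
reporting. Everything runs on synthetic cohorts with complete ground
truth; no real or confidential data is used or reproduced.

## Synthetic cohort

Each delivery draws a mother (name, maiden-name alias with probability
0.30, date of birth from an age-band mix of 18.5% under 25 / 61% 26–34 /
20.5% 35+, address, country of birth ~71.5% Australia, hospital, 7-digit
MRN) and one or more infants. Default rates, chosen to sit near
contemporary Australian perinatal statistics:

| parameter | default | meaning |
|---|---|---|
| `multiple_pregnancy_rate` | 0.016 | deliveries that are twins/triplets (97% twins) |
| `stillbirth_rate` | 0.006 | per-birth stillbirth probability (cohort-level) |
| `private_hospital_rate` | 0.25 | deliveries in private hospitals |
| `maternal_nonadmission_rate` | 0.002 | deliveries with no maternal admission record |
| `stillbirth_misclassification_rate` | 0.015 | stillbirths that nonetheless yield an infant admission |
| `code_missing_rate` | 0.002 | admissions lacking outcome/plurality codes |
| `period_days` | 730 | birth-date window (controls same-day collisions) |

Gestational age (completed weeks 20–42) follows a distribution peaked at
39–40 weeks with ~5% below 37; the stillbirth probability is tilted
toward low gestation (`exp(-0.35·(weeks−20))`) with the tilt scale solved
by bisection so the cohort-level expectation equals `stillbirth_rate`
exactly. Birthweight is drawn from a mean/SD-per-gestation-week table
(350±70 g at 20 weeks to 3,650±450 g at 42; multiples −10% mean), so
gestation- and birthweight-stratified linkage reports are exercisable.
Maternal/infant characteristics (smoking 14.5%, diabetes 5.2%,
hypertension 7.5%, caesarean 27%, parity, SEIFA quintile, SCN/NICU,
Apgar, …) are planted as independent Bernoulli draws: enough to populate
characteristic tables, deliberately without a comorbidity correlation
structure.

Admissions are coded the way the identification rules expect: maternal
records get a Z37 outcome code matching the delivery's plurality and
stillbirth outcome, a delivery code (O80/O81/O82 or O84 for multiples), a
delivery procedure (16520 caesarean / 90465 induction / 90467 otherwise)
and condition codes (O24.4, O13, O44.1, O45.9, O60.1, O90.1) per the
planted variables; infant records get Z38 by place/plurality, P07.2/P07.3
by gestation and P20.1 for low Apgar, an age of 0–1 days, a recorded
birthweight (1% missing) and a born-in-hospital source of referral (1%
born before arrival).

### Error model

Every emitted record's identifiers are corrupted independently:
character typos (substitution or adjacent transposition) at 0.02 per
field; name blanking at 0.02 (public) / 0.35 (private) per hospital
record — private hospitals collect names at their discretion, and this is
the main driver of linkage failure; adjacent-digit transposition in the
date of birth at 0.005; surname/alias swap at 0.03; address change
between collections at 0.05. An all-zero error model is the oracle
configuration: an exact-match join then recovers ground truth perfectly,
which the tests exploit.

What the generator does **not** emulate: demographically calibrated
microdata, within-family identifier correlation beyond shared maternal
fields, seasonal birth patterns, hospital-specific coding practice, or
longitudinal (across-pregnancy) structure. Passing tests therefore show
the machinery is correct and well-calibrated under this error model, not
that the same quality would be achieved on any particular real
collection.

## Linkage

**Standardization.** Names are uppercased, transliterated to ASCII,
punctuation-stripped and whitespace-collapsed (idempotent); American
Soundex (vowels reset, H/W transparent) and untruncated NYSIIS codes are
attached; empty input encodes to a sentinel treated as missing.

**Blocking.** Candidate pairs are the union, over derived keys, of
within-key cross pairs: full date of birth; surname Soundex + birth year;
MRN + hospital. Records missing a key component do not enter that key's
blocks. A block whose pair count exceeds 1,000 is split by the key's
secondary field (hospital code); a block still oversized is kept and
flagged, never silently dropped. On error-free data every true pair
shares at least one key by construction (the generator and default keys
are co-designed); under the error model a true pair escapes blocking only
if its date of birth, surname code *and* MRN are all corrupted, and any
such loss shows up in the measured missed-link rate rather than being
ignored.

**Clues and scoring.** Each clue compares one standardized field and
returns agree / disagree / missing; missing is the zero-contribution
reference level, so a blank field never contributes a disagree weight.
The default set: names exact + Soundex + NYSIIS, alias cross-match, date
of birth full and by component, sex, address, country of birth, MRN,
hospital, an admission-window clue (infant: admission within ±1 day of
birth; mother: birth date inside the admission interval), and birth order
for the infant linkage. Outcomes are encoded as paired agree/disagree
indicators and weighted by a binary logistic model — the dual of the
maximum-entropy model with indicator features — fitted by L-BFGS with
tolerance 1e-8 and a small absolute L2 penalty (1e-4) that keeps the
optimum unique and the fit reproducible while vanishing relative to the
likelihood; probabilities are strictly inside (0, 1).

**Thresholds.** `match` if p ≥ upper, `non_match` if p ≤ lower (boundary
inclusive on both sides, a documented convention), otherwise review.
Defaults 0.25/0.75. `tune_thresholds` grid-searches the observed score
values: because the missed rate depends only on the lower cut and the
false-positive rate only on the upper cut, the review band is minimized
by the largest feasible lower and smallest feasible upper; perfectly
separated scores collapse the band to empty, and an infeasible target is
reported explicitly rather than silently relaxed.

**Assignment.** Within each stream, accepted pairs (auto-matches plus,
in synthetic mode, review-band pairs confirmed by the ground-truth oracle
— emulating clerical review; a blind run rejects the band) are resolved
greedily by descending probability with stable id tie-breaks into a
one-to-one map. Greedy selection equals the lexicographically greatest
achievable pick sequence, which the tests verify against exhaustive
enumeration. Singleton and multiple pregnancies are linked in separate
passes and never compete for an assignment.

**Mother linkage is per delivery.** The birth records of one multiple
delivery carry identical maternal identifiers and truly correspond to the
same maternal admission, so the mother-side registration stream is
deduplicated to one record per delivery before linkage and the resulting
link propagated to each infant's birth record. A per-birth-record
one-to-one constraint would otherwise forbid legitimate links.

## Training and evaluation

Clue weights and thresholds are fitted on an independent labelled cohort
(2,000 deliveries, seed offset from the study seed by a fixed constant)
under the same error model, with tuning targets of 1 missed per 1,000
true pairs and 2 false per 1,000 declared links, then applied unchanged
to the study cohort (10,000 deliveries in the default study
configuration; sizes are package defaults chosen to make sampling error
in per-1,000 rates small while keeping runs interactive). Quality is
measured against ground truth with integer counts before rate
conversion: missed = true pairs absent from the declared map per 1,000
true pairs; false = declared links that are not true pairs per 1,000
declared. `scripts/acceptance.py` reports the missed rate averaged over
three seeds.

## Admission rules and groups

Code lists live in `vocab/tables.yml`; entries are hierarchical prefixes
(O24 matches O24.1) or dotted/numeric ranges expanded at load. The
vocabulary's duration-of-pregnancy row is labelled "< 25 weeks" in its
source table while the variable list and output tables use "< 26 weeks";
both labels are preserved rather than reconciled. Plurality/stillbirth
classification returns an explicit `unclassifiable` for absent or
conflicting evidence (both singleton and multiple codes present), and a
record flagged as an infant birth admission is never simultaneously
maternal. When several admissions of one mother qualify as the delivery
admission, the one whose interval contains the birth date is preferred —
enforced here through the admission-window clue rather than a separate
resolution step. Group assignment is per birth record, so one multiple
delivery may contribute records to different groups; stratification keeps
an explicit `unknown` stratum for records of undetermined plurality or
outcome instead of folding them away.

## Numerical conventions

Percentages round half-up to one decimal and always recompute from their
own count and column N. Dates are ISO-8601 calendar dates; day arithmetic
uses ordinals. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical outputs.
Degenerate inputs fail loudly (empty rate tables, zero denominators,
single-class training labels, malformed code ranges) or are explicit
values (`unknown` stratum, `unclassifiable`, missing-sentinel phonetic
codes), never silent defaults.

## Known limitations

- The review-band oracle emulates perfect clerical review; real review
  has its own error rate, so blind-mode (`reject`) quality is the more
  conservative figure.
- The logistic weights are fitted per error model; a linkage against data
  with a different corruption profile needs retraining.
- Address comparison is exact after normalization; no token-set or
  edit-distance similarity, so a single address typo reads as disagree.
- The ICD/ACHI vocabulary covers only the listed birth-admission and
  variable code sets, not the full classifications.
- Characteristic tables report descriptive counts only; no inferential
  statistics.
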