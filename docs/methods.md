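# Methods

## The case-finding model

The pipeline operationalises consensus DLB diagnostics over free text.
Six elementary concepts are mined: visual hallucinations,
fluctuations, tremor, bradykinesia, bad dreams, nightmares. A patient
has a core feature if at least one *positive* mention of a
corresponding concept occurs anywhere in their record — whole-record
ascertainment with no time window and no frequency threshold, which is
the natural reading of "symptom ever documented". Compound features
use the diagnostic conventions parkinsonism = tremor OR bradykinesia
and RBD = bad dreams OR nightmares (bad dreams/nightmares are a proxy:
true dream-enactment is rarely documented without a bed partner, so
record-based RBD is "possible RBD"). The core-feature count 0–4 maps
to criteria categories: 0 none, 1 possible-DLB threshold, ≥2
probable-DLB profile; AD-diagnosed patients with ≥2 features form the
AD2CS stratum flagged for diagnostic review. Non-positive mentions
never veto positive ones: a negation is an unwanted text mention, not
evidence of lifetime absence.

## Mention detection

Candidates are found by case-insensitive stem matching on word
boundaries: `fluctuat*`, `tremor*`, `bradykines*`, `nightmare*`, the
bigram `bad dream*`, where `*` is any run of word characters. Visual
hallucinations use a proximity rule instead — the exact token `visual`
and the stem `hallucinat*` in the same sentence with at most 5
intervening tokens (configurable), in either order; the candidate span
runs from the first to the last matched token. Overlapping matches of
one concept merge into a single maximal candidate, so candidate spans
never overlap. Sentences end at `./!/?`/newline followed by
whitespace; the abbreviation list is deliberately minimal and the
splitter is a documented dialect knob.

## Positive vs non-positive classification

The shipped classifier is deterministic and rule-based (NegEx-style).
Cue classes: negation (*no, not, denied, denies, without, nil, never,
absent, none, free of, …*), uncertainty/hypothetical (*monitoring to
see if, likely to, possible, query, ?-prefix, whether, …*), and
wrong-experiencer (*mother, father, husband, …*), loaded from a YAML
cue file that can be overridden by path. A cue scopes over a candidate
in the same sentence within 6 tokens on either side (negative
formulations in clinical notes are short-range); the nearest cue wins,
with ties broken conservatively towards non-positive and the class
order negated > unknown > irrelevant. The three non-positive sublabels
are all coded non-positive downstream, mirroring the convention of
folding negations and other unwanted mentions into one rejected class.

An optional trainable classifier (bag-of-words unigrams+bigrams over
the candidate's sentence, logistic regression, fixed random state) can
replace the rules at extraction time. It exists to demonstrate the
annotate-train-apply workflow used at register scale; it is off by
default because no real training corpus ships with the package. A
single-class training set triggers an explicit fallback to rules with
a warning. When the model rejects a mention the sublabel is taken from
the rule path when available, else `unknown`.

## The synthetic corpus

The generator emulates the study population the pipeline targets: a
memory-services cohort of 13,712 AD and 617 DLB patients.

**Symptoms.** Per patient, the six elementary symptoms are independent
Bernoulli draws. Group-level core-feature prevalences are planted at
the published values (DLB: VH 83.1%, fluctuations 74.7%, parkinsonism
62.1%, RBD 26.6%; AD: 16.7%, 30.3%, 19.7%, 9.3%). A compound target
`q` is split symmetrically into two elementary rates `1 − √(1−q)`,
which recombine to exactly `q` under independence. Only marginal
prevalences are calibrated; no symptom correlation structure is
asserted (there is no published joint distribution to match), so the
symptom-count distribution is an emergent property, not a calibrated
one.

**Demographics.** Age at first referral is Gaussian per group (DLB
76.9 ± 10.2, AD 80.6 ± 8.5 years). Age at diagnosis adds an
exponential waiting time with mean 1 year for AD and 2 years for DLB
and for AD patients whose planted profile has ≥2 core features,
reflecting the longer route to diagnosis in those strata; the
exponential keeps diagnosis age ≥ referral age by construction.
Female/non-white/married-or-cohabiting are Bernoulli at the published
group rates (49.0/26.4/42.6% DLB, 64.0/27.9/34.8% AD). Ages are
rounded to two decimals so files round-trip exactly.

**Notes.** Each patient gets 1–5 documents (uniform). Every true
elementary symptom is planted as one positive template sentence in a
random document; independently, per concept, a negated mention is
planted with probability 0.30 and an uncertain one with probability
0.15 (both configurable, zero in the noise-free setting), so the
classifier sees non-positive contexts for symptoms the patient may or
may not have. Documents are padded with 1–3 keyword-free distractor
sentences and sentence order is shuffled. Templates are fixed
prefix/keyword/suffix triples, so gold spans are exact by
construction, covering precisely the keyword region. The template bank
is intentionally small and cue-consistent; it exercises span
arithmetic, negation scoping, proximity windows and aggregation — it
does **not** model spelling errors, long-range negation, coreference,
or clinician documentation bias, so perfect extraction scores on this
corpus demonstrate pipeline correctness, not expected performance on
real clinical text (published register extractors score
precision/recall in the 83–100% range, which this corpus makes no
attempt to reproduce).

**Seeding.** One master seed is split per patient via
`SeedSequence(seed, spawn_key=(group, index, stream))`, so regenerating
with a larger cohort leaves earlier patients unchanged, and a fixed
seed regenerates byte-identical files.

## Statistics

Continuous variables are compared with Welch's unequal-variance t-test
(Satterthwaite degrees of freedom; the equal-variance pooled test is
available behind a flag) and categorical variables with Pearson's
chi-squared without continuity correction (Yates correction behind a
flag) — robust defaults for a large two-group design. p < 0.05 is the
significance convention and no multiple-testing adjustment is applied.
Table output renders p < 10⁻³ as `<0.001`; exact values go to a JSON
sidecar. Percentages are computed in decimal arithmetic with half-up
rounding to one decimal, matching printed-table conventions, and
full-cohort percentages equal n-weighted means of group percentages by
construction. Degenerate inputs are flagged rather than raised where a
table cell is still meaningful (empty group, zero variance in both
arms); structurally invalid input (zero margins, negative SD) raises
with the offending row/column named.

Test oracles are independent of the implementation path: t and χ²
tail probabilities are checked against direct numerical quadrature of
the densities (10⁻⁸ agreement), and the chi-squared p-value against
exact enumeration of the permutation (hypergeometric) null of the
Pearson statistic. The permutation comparison uses the mid-p tie
convention and a table of total n = 200: a discrete permutation null
differs from any continuous reference by O(1/σ) continuity terms, so
on very small tables (total ≤ 30) the asymptotic test and the exact
permutation tail genuinely disagree by 0.01–0.03 — a property of the
statistics, documented here rather than hidden by a loose tolerance.

## Evaluation

Precision = TP/(TP+FP) over retrieved positive mentions; recall =
TP/(TP+FN) over gold positive mentions; gold negated/uncertain
annotations are non-entities. Matching is greedy one-to-one per
document and concept with any-character-overlap by default (entities,
not offsets, are judged); exact-span mode is a flag. Undefined ratios
are reported as missing, never as silent zeros. Document-level
(presence/absence) metrics are provided alongside mention-level ones,
since a "100-document test set" evaluation unit can be read either
way; mention-level is the default. A seeded uniform
without-replacement document sampler supports fixed-size test sets.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on 60+60-patient corpora (and 120+120 for
the noise-free oracle); calibration checks use 800 patients per group;
the acceptance-grade recovery checks regenerate the full 617 + 13,712
cohort (~43k documents), which the pipeline processes in seconds.
Planted-prevalence recovery is asserted against exact binomial 99%
intervals at the planted rates.

## Known limitations

- Template-generated language: no lexical variation beyond the bank,
  no misspellings, no cross-sentence phenomena; extraction perfection
  on this corpus is an upper bound, not a performance claim.
- Independence of elementary symptoms within patient; real core
  features co-occur.
- The trainable classifier is a workflow stand-in, not a replication
  of any production register model (feature sets and training data of
  those models are not public).
- The criteria categories label symptom-profile compatibility with
  possible/probable DLB; they do not assert a diagnosis change.
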