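# Methods

## Input model

An FHH-section entry is one per-relative assertion: coded condition,
coded relative, integer age of onset (any of which may be null) and a
free-text comment. The pipeline never interprets the comment in
isolation: all four fields are concatenated — order condition, comment,
relative, onset, joined by single spaces — with coded values wrapped in
double curly brackets so downstream rules can distinguish coded from
narrative text. A null coded value renders as an empty `{{}}` marker so
every field position is represented. Offsets are 0-based half-open over
the concatenated string, which keeps slicing unambiguous and maps
directly onto Brat standoff spans.

Sentence segmentation splits after `.` + space, `;` and newlines, never
inside a marked region, after a short list of telegraphic clinical
abbreviations (dx., ca., yr., …) or inside a decimal. Comments are
telegraphic; aggressive splitting severs relations, so the splitter is
deliberately conservative.

## Extraction

Entity extraction is exact lexicon matching (case-insensitive, longest
match wins, leftmost breaks ties) plus small pattern grammars:

- **Conditions** — cancer sites with synonyms (including
  ENDOMETRIAL/UTERINE, needed by the colorectal criteria), hereditary
  syndromes (Lynch/HNPCC, Cowden, Li-Fraumeni, FAP, polyposis variants)
  and genes (BRCA1/2, CHEK2, ATM, PALB2, TP53, PTEN, CDH1, MLH1, MSH2,
  PMS2, MSH6, EPCAM, MYH/MUTYH, APC). Aggregated categories
  (gynecologic/gastrointestinal/genitourinary) are representable in the
  schema but excluded from extraction: they inflate false positives
  against site-specific criteria.
- **Relatives** — codes with sex, inherent family side
  (mother → maternal lineage, father → paternal, full siblings and
  descendants → both) and degree (1: parent/sibling/child; 2:
  grandparent/aunt/uncle/niece/nephew/half-sibling/grandchild; 3:
  great-grand generation and cousins).
- **Onsets** — four subtypes: exact AGE (`52`, `dx at age of 52`), RANGE
  from decade phrases (`early 50s` → [50, 54], `late 50s` → [55, 59],
  bare `50s` → [50, 59], `mid 50s` → [53, 56]), PERIOD for calendar years,
  STRING for the rest; plus DECEASED_AGE (`deceased at age 60 years`).
  PERIOD and STRING yield no age bounds because no birth year is
  available to convert them.
- **Multiplicity** — `2×`/`2 x`/`x2` affixes and number words up to ten
  fold into the family-member span; an explicit zero is logged and
  treated as one.

Context rules mark entities inside `{{ }}` as `is_structural`, ignore
family members mentioned after exclusion triggers ("lives with her
daughter"), and flag condition entities with uncertainty when a hedge
(possible, probably, maybe, `?`, unsure, suspected, …) occurs in the same
segment — the segment is the hedge's scope because the comments are too
short to support anything finer. Side-only phrases ("father side") and
negating override terms ("no cancer", "precancer", "benign", "cyst") are
reserved before term matching so they never spawn spurious family-member
or condition entities. There is no fuzzy matching: data-entry typos
("bladdler") are an accepted error mode, and an optional curated typo
list can be supplied through the lexicon.

A generic coded `CANCER` whose entry comment names a site is retired in
favor of the site entity, so "{{CANCER}} Breast" contributes exactly one
condition.

## Reconciliation

Eight ordered heuristics (R1–R8) resolve structured-vs-comment conflicts;
all status changes are monotone (ACTIVE → IGNORED only), which makes the
operation idempotent, and losers are retained for audit. Order matters
only in that condition and onset conflicts (R1–R5) are settled before
family-member resolution (R6–R8). Additions beyond the core eight, both
needed for exact behavior on degenerate comments: a comment exact age
overrides a coded age (the comment is taken as the correction, by analogy
with R2), and within one segment at most one comment onset stays active
(range > age > period/string, leftmost wins).

R5 infers an onset RANGE [0, deceased_age] — onset is strictly before
death, and nothing bounds it from below. Whether such a wide range should
satisfy age thresholds is genuinely open; by default it participates
under the optimistic range policy, and a config switch
(`inferred_range_participates`) turns it off.

R6 counts any lexicon relative term as "specific"; side-only phrases are
the "nonspecific" case (R7). The conjunction exception recognizes
"and"/"also"/"&"/"+" immediately before the comment relative.

## Linking

Scope is the sentence segment, with one asymmetry: structured-field
entities are entry-global (they are fields, not narrative), so a segment
whose narrative names no relative inherits the entry's coded relative,
and the coded condition/onset are visible from every segment. Every
active family member in scope links to every active condition in scope
and to the scope's single active onset. Multiplicity expansion produces
clone instances that each carry their own relations — relation counts,
not distinct persons, are what the criteria tally — and
`to_assertions` folds clones back into one normalized assertion with a
count. A condition with no family member anywhere in scope is reported
as an orphan, not an error. When one sentence lists several relatives
and conditions, all pairs in the segment are linked; nearest-relative
disambiguation is not attempted because the generated and observed
comment styles do not require it.

## Criteria engine

Both cohorts are evaluated from the same normalized assertions.
Age-threshold criteria (BO1 ≤ 45; C2/C3 ≤ 50) accept an exact age ≤ T,
and a RANGE under the configured policy: OPTIMISTIC (default, lower
bound ≤ T — a screening tool should surface "dx in 30s" against a
45-year threshold) or STRICT (upper bound ≤ T). Same-side counting
(BO5/C4) is multiplicity-weighted, treats BOTH-side relatives as
counting toward each side, and drops UNKNOWN-side assertions
(conservative; configurable). Degree-3 relatives only satisfy
any-relative criteria (BO4, BO6, BO7, C1). The colon definition for
C2/C4 includes rectal cancer by default (colorectal guideline scope;
configurable). BO6 requires the patient-level Ashkenazi flag and never
fires when it is null. Comment-derived syndrome assertions qualify for
C1 by default (`comment_syndromes_qualify=False` restricts C1 to coded
findings). BO4 accepts any degree since the criterion names "a male
relative" without restriction.

The structured-only mode builds assertions from the coded fields alone;
the NLP-augmented mode runs the full pipeline first. Both apply the same
relevance filter (coded condition maps to a cancer/syndrome/gene, or the
comment mentions a condition term) and the same uncertainty policy
(EXCLUDE drops hedged assertions before evaluation). Because every
criterion is monotone in evidence and EXCLUDE only removes assertions,
the include-uncertainty eligible set always contains the exclude set,
and on supplement-only corpora the augmented set contains the
structured set.

## Synthetic corpus

The generator draws each entry from one of 18 phrase templates, one per
comment phenomenon (fully structured, site/onset supplements, relative
correction, conjunction, side-only, multiplicity, uncertainty, condition
override, period red herring, deceased age, syndrome override, gene
mention, two cancers in one relative, one cancer in two relatives,
exclusion context, non-cancer noise). Default weights put roughly 40% of
entries in the fully-structured or site-supplement classes and spread
the conflict phenomena over the rest, reflecting that true
contradictions are the minority in FHH comments. Entries per patient are
1 + Poisson(mean − 1), capped (default mean 2, cap 5).

Gold is constructive: the generator records the intended relations (in
the same canonical signature space the pipeline emits) and normalized
assertions per entry; gold eligibility is the criteria engine evaluated
over a patient's gold assertions. Requested per-cohort eligibility
proportions are honored by planting one guaranteed-eligible entry
(breast ≤ 44 in a close relative, an onset-range variant, ovarian, colon
≤ 50, Lynch, or a mismatch-repair gene) for the selected patients; filler
entries can also turn out eligible, so the realized proportion is at
least the requested one. Typo perturbation duplicates an interior
character of a comment condition term ("bladder" → "bladdler") at a
seeded selection of entries and leaves gold unchanged — typos model
noise the extractor is expected to miss, so recall can only drop.

What the corpus does **not** model: real code-list diversity and
institution-specific coding habits, misspellings beyond the single edit
rule, free-text negation beyond the override list, cross-entry
references to the same relative, and real demographic structure.
Passing the recovery suites therefore shows the pipeline is internally
consistent and complete over the modeled phenomena, not that it attains
any particular accuracy on real EHR text.

## Evaluation

A true-positive relation requires the relation type, both linked
entities and all feature values to match; per-entry matching is multiset
intersection over canonical signature tuples. Micro-averages are
computed from summed confusion counts. Metrics with zero denominators
are reported as unavailable rather than zero. Confidence intervals use
the percentile bootstrap (default B = 1000), resampling entries for
relation metrics and patients for eligibility metrics — the resampling
unit is recorded with the output. Types supported by fewer than five
units with any counts get no interval, matching how CIs for very rare
syndrome/gene relations cannot be estimated. Reported rates are rounded
to two decimals, half-up.

## Problem sizes and determinism

All randomness flows through seeded numpy generators; identical seeds
give byte-identical corpora and CI outputs. The test suite exercises
recovery on corpora of up to ~2,000 entries (1,000 patients) and the
acceptance script on ~1,000 entries (500 patients), sizes at which the
full pipeline runs in seconds on one CPU.

## Known limitations

- The lexicon is a curated reconstruction of a typical EHR code list,
  not a licensed terminology; it is deliberately user-editable
  (`load_lexicon_file`).
- Exclusion contexts and uncertainty cues are trigger lists, not a
  general negation/hedging engine; unseen phrasings pass through.
- PERIOD onsets could be converted to ages with a birth year; entries do
  not carry one, so they never satisfy thresholds.
- No cross-entry deduplication: the same relative recorded twice counts
  twice, consistent with relation-based counting.
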