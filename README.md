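# fhhkit

Rule-based extraction of family health history (FHH) from the dedicated
FHH section of an electronic health record, and screening of the result
against NCCN family-history criteria for hereditary breast/ovarian and
colorectal cancer genetic testing.

## The problem

EHR systems capture family history as per-relative assertions with coded
fields — a condition (e.g. `CANCER`), a relative (`AUNT`), an integer age
of onset — plus a free-text comment. Clinicians put exactly the
information that does not fit the picklists into that comment: the cancer
site ("Breast"), a corrected relative ("great-aunt"), an approximate
onset ("dx in her 30s"), multiplicities ("2× sisters"), hedges
("possible"), and outright contradictions ("precancer"). Screening
algorithms that read only the coded fields miss or mis-assess these
patients; reading the comment requires resolving its interplay with the
coded fields, because neither can be interpreted alone.

`fhhkit` implements that interplay as a deterministic pipeline:

1. **Concatenation** — the coded values and the comment are joined into a
   single string, coded values wrapped in `{{ }}` markers:
   `{{CANCER}} Breast, great-aunt, dx at age of 52 {{AUNT}} {{}}`.
2. **Entity extraction** — longest-match lexicon and pattern matching
   over sentence segments yields typed entities (cancer sites, syndromes,
   gene variants, family members, four onset subtypes, deceased ages)
   with features: `is_structural`, uncertainty, side, sex, multiplicity.
3. **Entity reconciliation** — eight ordered heuristics resolve
   structured-vs-comment conflicts (a comment onset range overrides a
   coded age; a specific comment relative overrides the coded one unless
   a conjunction keeps both; "2× sisters" expands to two instances; ...).
   Losers are marked `IGNORED`, never deleted.
4. **Relation identification** — each active family member is linked to
   the active conditions and onset in its scope (`FX_CANCER`,
   `FX_SYNDROME`, `FX_GENE_MUT`, `FX_ONSET`). Relations, not distinct
   relatives, are what the criteria count: a grandmother with "ovarian
   and stomach cancer" contributes two relations.
5. **Criteria engine** — normalized per-relative assertions are evaluated
   against the two cohorts' criteria (BO1–BO7, C1–C4), in a
   structured-only or NLP-augmented mode and under an include- or
   exclude-uncertainty policy.

Because real FHH-section data cannot be redistributed, the package ships
a synthetic-corpus generator (`fhhkit.simulate`) that emulates the entry
structure and comment phenomena with constructive gold annotations, plus
an evaluation module (`fhhkit.evaluate`) computing per-type and
micro-averaged precision/recall/F1 with percentile-bootstrap confidence
intervals.

## Worked example

```python
from fhhkit import FHHEntry, process_entry

entry = FHHEntry("P1", "E1", condition_code="CANCER", relative_code="AUNT",
                 onset_age=None, comment="Breast, great-aunt, dx at age of 52")
ann = process_entry(entry)
for e in ann.active_entities:
    print(e.label.value, repr(e.surface))
for r in ann.relations:
    print(r.type.value, r.source.surface, "->", r.target.surface)
```

prints

```
BREAST 'Breast'
FAMILYMEMBER 'great-aunt'
ONSET_AGE '52'
FX_CANCER great-aunt -> Breast
FX_ONSET great-aunt -> 52
```

Three entities survive reconciliation — the comment's site, relative and
onset — while the coded generic `CANCER` and `AUNT` are retired as
corrected duplicates; two relations link the great-aunt to her breast
cancer and age of onset. The resulting assertion (`GREAT_AUNT`, degree 3,
`BREAST`, onset 52) fires no criterion on its own, but the same pipeline
on `{{CANCER}} breast ca, dx in 30s {{AUNT}} {{}}` makes the patient
eligible via BO1 (first-/second-degree relative with breast cancer at
≤ 45) where a structured-only read finds nothing — see
`examples/03_screening.py`.

The `examples/` directory has one short script per capability: the worked
entry, the reconciliation heuristics, two-mode screening, and
synthetic-corpus evaluation with bootstrap CIs. A thin CLI wires the same
stages end to end: `fhhkit extract`, `fhhkit screen`, `fhhkit simulate`,
`fhhkit evaluate`.

## Layout

- `src/fhhkit/` — `core` (types), `io` (tables, Brat standoff, JSONL
  annotations, FamilyMemberHistory export), `lexicon`, `preprocess`,
  `extract`, `reconcile`, `link`, `criteria`, `simulate`, `evaluate`,
  `pipeline`, `cli`.
- `docs/methods.md` — models, heuristics, parameters and limitations.
- `tests/` — unit, property and acceptance suites.
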