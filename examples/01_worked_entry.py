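"""Process a single FHH entry whose comment corrects the coded fields.

The coded fields say "CANCER" in an "AUNT" with no age of onset; the
comment narrows the site to breast, corrects the relative to a great-aunt,
and supplies the age.  The pipeline keeps the comment-derived entities,
retires the contradicted coded ones, and links the relations.
"""

from fhhkit import FHHEntry, combine_fields, process_entry

entry = FHHEntry(
    patient_id="P1",
    entry_id="E1",
    condition_code="CANCER",
    relative_code="AUNT",
    onset_age=None,
    comment="Breast, great-aunt, dx at age of 52",
)

print("marked text:", combine_fields(entry).text)
ann = process_entry(entry)

print("\nentities (status / label / surface):")
for e in ann.entities:
    tag = "structural" if e.is_structural else "comment"
    print(f"  {e.status.value:<8} {e.label.value:<14} {e.surface!r} ({tag})")

print("\nrelations:")
for r in ann.relations:
    print(f"  {r.type.value}: {r.source.surface!r} -> {r.target.surface!r}")

print("\nnormalized assertion(s):")
for a in ann.assertions:
    onset = f"{a.onset.kind.value} {a.onset.lower}" if a.onset else "unknown"
    print(f"  {a.relative_code} (degree {a.degree}): {a.condition}, onset {onset}")

# The three ACTIVE entities and two relations show the comment winning the
# reconciliation: the coded AUNT is ignored in favor of the great-aunt, so
# the assertion carries degree 3 and an exact onset of 52.
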