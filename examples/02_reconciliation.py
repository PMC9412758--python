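"""Tour of the eight reconciliation heuristics on conflict cases.

Each entry pairs a coded value with a comment that supplements or
contradicts it; the printout shows which mention survives.
"""

from fhhkit import FHHEntry, process_entry

CASES = [
    ("syndrome beats coded colon", dict(condition_code="CANCER, COLON",
                                        relative_code="AUNT", comment="Lynch syndrome")),
    ("comment decade beats coded age", dict(condition_code="CANCER, BREAST",
                                            relative_code="SISTER", onset_age=50,
                                            comment="The late 50s")),
    ("calendar year loses to coded age", dict(condition_code="CANCER, BREAST",
                                              relative_code="SISTER", onset_age=50,
                                              comment="In 1985")),
    ("deceased age bounds the onset", dict(condition_code="CANCER, STOMACH",
                                           relative_code="GRANDMOTHER",
                                           comment="Deceased at age 60 years")),
    ("specific relative wins", dict(condition_code="CANCER, BREAST",
                                    relative_code="AUNT", comment="Great-aunt")),
    ("conjunction keeps both", dict(condition_code="CANCER, BREAST",
                                    relative_code="MOTHER", comment="And grandmother")),
    ("side-only phrase becomes a feature", dict(condition_code="CANCER, OVARIAN",
                                                relative_code="AUNT", comment="Father side")),
    ("multiplicity expands instances", dict(condition_code="CANCER, BREAST",
                                            comment="2× sisters")),
]

for title, fields in CASES:
    ann = process_entry(FHHEntry("P", "E", **fields))
    active = ", ".join(
        f"{e.label.value}:{e.code or e.surface}"
        + (f"[{e.side.value}]" if e.side.value not in ("UNKNOWN",) else "")
        for e in ann.active_entities
    )
    print(f"{title:<38} -> {active}")

# Losing mentions are never deleted, only marked IGNORED, so the full
# audit trail stays available in ann.entities.
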